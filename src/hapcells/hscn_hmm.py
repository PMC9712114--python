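"""Haplotype-specific copy number (HSCN) inference.

Population-level phasing of haplotype blocks followed by a per-cell,
per-chromosome hidden Markov model with Beta-Binomial emissions conditioned
on the cell's total integer copy number.

Model
-----
Given a cell's total copy state ``t_i`` in bin ``i``, the hidden state is a
pair ``(a, b)`` with ``a + b = t_i`` (``a`` copies of homologue A, ``b`` of
homologue B).  Aggregated phased allele counts ``(b_i, n_i)`` in the bin are
emitted as

    b_i ~ BetaBinomial(n_i, mu * s, (1 - mu) * s),   mu = b / (a + b)

with ``mu`` shrunk into ``[eps, 1 - eps]`` so pure-allele states retain
non-zero likelihood under sequencing error.  Between adjacent bins the
phase-preserving successor (the state in the next bin's space with B-allele
fraction closest to the current one; ties to the smaller ``b``) receives the
self-transition probability ``e``; the remaining mass is uniform over the
other states.  The most probable path is found by Viterbi decoding per
chromosome.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import betabinom

from .core_io import BinGrid, BlockAlleleCounts, CellCNMatrix

logger = logging.getLogger(__name__)


@dataclass
class HMMParams:
    """Tunable parameters of the haplotype HMM.

    e
        Self-transition probability; 0.95 by default, 0.999 recommended for
        noisy samples.
    s
        Beta-Binomial concentration (precision) of the allele-count emission.
    eps
        Shrinkage of the emission mean away from {0, 1}.
    t_max
        Cap on the total copy number used to build the state space; higher
        totals keep their BAF grid but on the capped total.
    max_phase_iters
        Maximum rounds of block re-phasing during population inference.
    """

    e: float = 0.95
    s: float = 50.0
    eps: float = 0.01
    t_max: int = 12
    max_phase_iters: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.e < 1:
            raise ValueError("self-transition probability must be in (0, 1)")
        if self.s <= 0:
            raise ValueError("concentration must be positive")
        if not 0 < self.eps < 0.5:
            raise ValueError("eps must be in (0, 0.5)")


@dataclass
class HSCNMatrix:
    """Cells x bins homologue-specific states.

    ``a`` and ``b`` hold copies of each homologue (``a + b`` equals the input
    total state clamped at ``t_max``), ``baf`` the observed bin-level B-allele
    frequency (NaN where no informative reads), ``posterior`` the marginal
    posterior probability of the assigned state.
    """

    grid: BinGrid
    cells: list[str]
    a: np.ndarray
    b: np.ndarray
    baf: np.ndarray
    posterior: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(self.grid.n_bins, dtype=bool)

    @property
    def total(self) -> np.ndarray:
        return self.a + self.b

    def to_long_df(self):
        import pandas as pd

        g = self.grid.bins
        n_cells, n_bins = self.a.shape
        return pd.DataFrame(
            {
                "cell_id": np.repeat(self.cells, n_bins),
                "chrom": np.tile(g["chrom"].to_numpy(), n_cells),
                "start": np.tile(g["start"].to_numpy(), n_cells),
                "end": np.tile(g["end"].to_numpy(), n_cells),
                "state": (self.a + self.b).ravel(),
                "a": self.a.ravel(),
                "b": self.b.ravel(),
                "baf": self.baf.ravel(),
                "posterior": self.posterior.ravel(),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_long_df().to_csv(path, sep="\t", index=False)


def compute_baf(b, t):
    """B-allele frequency ``b / t``; NaN where ``t == 0``."""
    b = np.asarray(b, dtype=float)
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(t > 0, b / np.where(t > 0, t, 1), np.nan)
    return out


# ---------------------------------------------------------------------------
# Phasing
# ---------------------------------------------------------------------------


def phase_blocks(counts: BlockAlleleCounts) -> BlockAlleleCounts:
    """Orient blocks so each block's population-aggregate BAF is <= 0.5.

    Aggregate B then is the chromosome-level minor allele.  Blocks with zero
    total counts across all cells are dropped with a warning.  Deterministic:
    an aggregate BAF of exactly 0.5 keeps the current orientation.
    """
    b_tot = counts.oriented_b().sum(axis=0).astype(float)
    t_tot = counts.t.sum(axis=0).astype(float)
    empty = t_tot == 0
    if empty.any():
        logger.warning("dropping %d blocks with zero total counts", int(empty.sum()))
    flip = np.zeros(counts.n_blocks, dtype=bool)
    nz = ~empty
    flip[nz] = b_tot[nz] / t_tot[nz] > 0.5
    orientation = np.where(flip, -counts.orientation, counts.orientation)
    keep = nz
    return BlockAlleleCounts(
        blocks=counts.blocks.loc[keep].reset_index(drop=True),
        cells=counts.cells,
        b=counts.b[:, keep],
        t=counts.t[:, keep],
        orientation=orientation[keep],
    )


def correct_switch_errors(
    counts: BlockAlleleCounts, z_threshold: float = 2.0, window: int = 4
) -> BlockAlleleCounts:
    """Fix local phase-switch errors by local covariance chaining.

    The population-aggregate BAF orients blocks poorly where most cells are
    allelically balanced and only small cell subsets carry imbalance.  Cells'
    BAF deviations from 0.5 in nearby blocks of the same chromosome must
    correlate positively when the blocks are consistently oriented; walking
    each chromosome, each block is compared against the per-cell mean
    deviation of up to ``window`` preceding (already corrected) blocks, and is
    flipped when the covariance is significantly negative (z below
    ``-z_threshold``).  Links without significant signal keep the aggregate
    orientation.
    """
    orientation = counts.orientation.copy()
    t = counts.t

    def _dev(col):
        with np.errstate(divide="ignore", invalid="ignore"):
            baf = np.where(t[:, col] > 0, counts.b[:, col] / np.maximum(t[:, col], 1), np.nan)
        if orientation[col] < 0:
            baf = 1.0 - baf
        return baf - 0.5

    for chrom in pd.unique(counts.blocks["chrom"]):
        idx = np.flatnonzero(counts.blocks["chrom"].to_numpy() == chrom)
        idx = idx[np.argsort(counts.blocks["start"].to_numpy()[idx], kind="stable")]
        if len(idx) < 2:
            continue
        for pos in range(1, len(idx)):
            k = idx[pos]
            prev = idx[max(0, pos - window) : pos]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                ref = np.nanmean(np.column_stack([_dev(j) for j in prev]), axis=1)
            dk = _dev(k)
            x = ref * dk
            x = x[np.isfinite(x)]
            if len(x) == 0:
                continue
            s = x.sum()
            sd = np.sqrt((x**2).sum())
            if sd > 0 and s / sd < -z_threshold:
                orientation[k] = -orientation[k]
    return BlockAlleleCounts(
        blocks=counts.blocks,
        cells=counts.cells,
        b=counts.b,
        t=counts.t,
        orientation=orientation,
    )


def aggregate_to_bins(
    counts: BlockAlleleCounts, grid: BinGrid
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sum oriented block counts into grid bins (block midpoint rule).

    Returns ``(b_bins, t_bins, block_bin)`` where ``block_bin[j]`` is the bin
    index of block ``j`` (-1 if off-grid).
    """
    mids = (counts.blocks["start"].to_numpy() + counts.blocks["end"].to_numpy()) // 2
    chroms = counts.blocks["chrom"].to_numpy()
    block_bin = np.full(counts.n_blocks, -1, dtype=np.int64)
    gstart = grid.bins["start"].to_numpy()
    gend = grid.bins["end"].to_numpy()
    for chrom in np.unique(chroms):
        if chrom not in grid._chrom_index:
            continue
        gi = grid.chrom_bins(chrom)
        sel = np.flatnonzero(chroms == chrom)
        pos = np.searchsorted(gstart[gi], mids[sel], side="right") - 1
        ok = (pos >= 0) & (mids[sel] <= gend[gi][np.clip(pos, 0, len(gi) - 1)])
        block_bin[sel[ok]] = gi[pos[ok]]
    b_or = counts.oriented_b()
    n_cells = len(counts.cells)
    b_bins = np.zeros((n_cells, grid.n_bins), dtype=np.int64)
    t_bins = np.zeros_like(b_bins)
    on = block_bin >= 0
    for j in np.flatnonzero(on):
        b_bins[:, block_bin[j]] += b_or[:, j]
        t_bins[:, block_bin[j]] += counts.t[:, j]
    return b_bins, t_bins, block_bin


# ---------------------------------------------------------------------------
# Per-cell HMM
# ---------------------------------------------------------------------------


@lru_cache(maxsize=4096)
def _transition(t_from: int, t_to: int, e: float) -> np.ndarray:
    """Log transition matrix between the state spaces of two totals.

    State spaces are ordered by ``b`` ascending.  Each state routes mass ``e``
    to its phase-preserving successor (nearest BAF, ties to smaller ``b``) and
    the remainder uniformly over the other states.
    """
    n_from = t_from + 1
    n_to = t_to + 1
    mu_from = (
        np.arange(n_from) / t_from if t_from > 0 else np.array([0.5])
    )
    mu_to = np.arange(n_to) / t_to if t_to > 0 else np.array([0.5])
    P = np.zeros((n_from, n_to))
    for j in range(n_from):
        succ = int(np.argmin(np.abs(mu_to - mu_from[j])))  # argmin -> smallest b on tie
        if n_to == 1:
            P[j, 0] = 1.0
        else:
            P[j, :] = (1.0 - e) / (n_to - 1)
            P[j, succ] = e
    with np.errstate(divide="ignore"):
        return np.log(P)


def _emission_loglik(
    total: int, b_count: float, t_count: float, params: HMMParams
) -> np.ndarray:
    """Log-likelihood of the bin's counts under each state of one total."""
    n_states = total + 1
    if t_count <= 0:
        return np.zeros(n_states)
    if total == 0:
        return np.zeros(1)
    mu = np.clip(np.arange(n_states) / total, params.eps, 1.0 - params.eps)
    return betabinom.logpmf(b_count, t_count, mu * params.s, (1.0 - mu) * params.s)


def infer_cell_hscn(
    totals: np.ndarray,
    b_counts: np.ndarray,
    t_counts: np.ndarray,
    params: HMMParams | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Viterbi decoding of one chromosome of one cell.

    Parameters are bin-ordered arrays: total integer states and aggregated
    oriented allele counts.  Returns ``(a, b, posterior)`` per bin.  Totals
    above ``t_max`` are capped for the state space; bins with total 0 carry
    the single state (0, 0) (counts observed there are discordant and
    ignored); bins without counts are uninformative.
    """
    params = params or HMMParams()
    totals = np.minimum(np.asarray(totals, dtype=np.int64), params.t_max)
    n = len(totals)
    if n == 0:
        return np.zeros(0, dtype=int), np.zeros(0, dtype=int), np.zeros(0)
    emis = [
        _emission_loglik(int(totals[i]), b_counts[i], t_counts[i], params)
        for i in range(n)
    ]
    # Viterbi
    delta = emis[0] - np.log(totals[0] + 1)
    back: list[np.ndarray] = []
    for i in range(1, n):
        logA = _transition(int(totals[i - 1]), int(totals[i]), params.e)
        scores = delta[:, None] + logA
        back.append(np.argmax(scores, axis=0))
        delta = scores.max(axis=0) + emis[i]
    path = np.zeros(n, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for i in range(n - 2, -1, -1):
        path[i] = back[i][path[i + 1]]
    b = path
    a = totals - b
    posterior = _posterior_of_path(totals, emis, path, params)
    return a, b, posterior


def _posterior_of_path(totals, emis, path, params: HMMParams) -> np.ndarray:
    """Forward-backward marginal posterior of the decoded state per bin."""
    n = len(totals)
    fwd = [emis[0] - np.log(totals[0] + 1)]
    for i in range(1, n):
        logA = _transition(int(totals[i - 1]), int(totals[i]), params.e)
        fwd.append(_logsumexp_cols(fwd[-1][:, None] + logA) + emis[i])
    bwd = [np.zeros(totals[-1] + 1)]
    for i in range(n - 1, 0, -1):
        logA = _transition(int(totals[i - 1]), int(totals[i]), params.e)
        bwd.append(_logsumexp_cols((logA + emis[i] + bwd[-1]).T))
    bwd.reverse()
    post = np.zeros(n)
    for i in range(n):
        joint = fwd[i] + bwd[i]
        joint -= joint.max()
        p = np.exp(joint)
        post[i] = p[path[i]] / p.sum()
    return post


def _logsumexp_cols(M: np.ndarray) -> np.ndarray:
    m = M.max(axis=0)
    with np.errstate(invalid="ignore"):
        out = m + np.log(np.exp(M - m).sum(axis=0))
    return np.where(np.isfinite(m), out, m)


# ---------------------------------------------------------------------------
# Population inference
# ---------------------------------------------------------------------------


def infer_population_hscn(
    cn: CellCNMatrix,
    counts: BlockAlleleCounts,
    params: HMMParams | None = None,
) -> HSCNMatrix:
    """Phase blocks, run the per-cell HMM and iteratively re-phase.

    Block orientations are initialized from the population-aggregate BAF,
    then refined by majority vote of cells' assigned allelic imbalances
    (damped: a block flips only when >60% of informative cells disagree with
    its current orientation).  On convergence the A/B labels are canonicalized
    per chromosome so the aggregate BAF of allele B is <= 0.5.
    """
    params = params or HMMParams()
    if cn.n_cells == 0:
        raise ValueError("no cells to infer")
    counts = correct_switch_errors(phase_blocks(counts))
    grid = cn.grid
    n_cells = cn.n_cells
    a = np.zeros_like(cn.state)
    b = np.zeros_like(cn.state)
    post = np.zeros(cn.state.shape)
    b_bins = t_bins = block_bin = None
    for _ in range(params.max_phase_iters):
        b_bins, t_bins, block_bin = aggregate_to_bins(counts, grid)
        for ci in range(n_cells):
            for chrom in grid.chroms:
                gi = grid.chrom_bins(chrom)
                a_c, b_c, p_c = infer_cell_hscn(
                    cn.state[ci, gi], b_bins[ci, gi], t_bins[ci, gi], params
                )
                a[ci, gi], b[ci, gi], post[ci, gi] = a_c, b_c, p_c
        flips = _vote_flips(counts, block_bin, a, b)
        if not flips.any():
            break
        counts = replace(
            counts, orientation=np.where(flips, -counts.orientation, counts.orientation)
        )
    # canonicalize: per chromosome, aggregate BAF of B <= 0.5
    assert b_bins is not None and t_bins is not None and block_bin is not None
    for chrom in grid.chroms:
        gi = grid.chrom_bins(chrom)
        tt = t_bins[:, gi].sum()
        if tt > 0 and b_bins[:, gi].sum() / tt > 0.5:
            a[:, gi], b[:, gi] = b[:, gi].copy(), a[:, gi].copy()
            on_chrom = np.isin(block_bin, gi)
            counts.orientation[on_chrom] *= -1
            b_bins[:, gi] = t_bins[:, gi] - b_bins[:, gi]
    baf = compute_baf(b_bins, t_bins)
    return HSCNMatrix(
        grid=grid, cells=list(cn.cells), a=a, b=b, baf=baf, posterior=post, mask=cn.mask
    )


def _regional_signs(mu: np.ndarray) -> np.ndarray:
    """Per cell per bin: sign of the cell's allelic imbalance over the
    contiguous imbalanced run containing the bin (0 where balanced).

    Using the run-level majority sign rather than the bin-level state breaks
    the stuck equilibrium in which a consistently mis-oriented sub-run of
    blocks mirrors the decoded path: the run majority defines one reference
    sign per cell against which every block in the run is judged.
    """
    n_cells, n_bins = mu.shape
    signs = np.zeros((n_cells, n_bins), dtype=np.int8)
    imbal = np.isfinite(mu) & (mu != 0.5)
    for ci in range(n_cells):
        row = imbal[ci]
        start = None
        for i in range(n_bins + 1):
            inside = i < n_bins and row[i]
            if inside and start is None:
                start = i
            elif not inside and start is not None:
                seg = mu[ci, start:i]
                signs[ci, start:i] = 1 if seg.mean() > 0.5 else -1
                start = None
    return signs


def _vote_flips(
    counts: BlockAlleleCounts,
    block_bin: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    z_threshold: float = 2.0,
) -> np.ndarray:
    """Re-orient blocks against the cells' regional imbalance signs.

    For each block, cells whose decoded path is imbalanced around the block's
    bin contribute a signed count deviation (positive when the observed B
    excess agrees with the cell's regional sign); a significantly negative
    total (z below ``-z_threshold``) flips the block.
    """
    b_or = counts.oriented_b()
    flips = np.zeros(counts.n_blocks, dtype=bool)
    total = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(total > 0, b / np.where(total > 0, total, 1), np.nan)
    signs = _regional_signs(mu)
    for j in range(counts.n_blocks):
        bin_j = block_bin[j]
        if bin_j < 0:
            continue
        t_j = counts.t[:, j]
        voters = (t_j > 0) & (signs[:, bin_j] != 0)
        if not voters.any():
            continue
        s = signs[voters, bin_j].astype(float)
        x = (s * (b_or[voters, j] - t_j[voters] / 2.0)).sum()
        sd = np.sqrt((t_j[voters] / 4.0).sum())
        if sd > 0 and x / sd < -z_threshold:
            flips[j] = True
    return flips
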