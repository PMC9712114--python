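"""Per-cell and per-clone copy-number statistics.

Ploidy, pseudobulk consensus profiles, chromosome missegregation, gain/loss
segments, high-level amplification (HLAMP) detection and variance, disjoint
segment genotyping and HLAMP locus feature vectors.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import BinGrid, CellCNMatrix
from .hscn_hmm import HSCNMatrix

logger = logging.getLogger(__name__)

MIN_SEGMENT_SPAN = 1_500_000  # gain/loss runs spanning <= this are noise
HLAMP_COPY = 10.0
HLAMP_MIN_CELLS = 10
MISSEG_COVERAGE = 0.75
AMPLITUDE_RATIO_MIN = 2.0
HLAMP_WINDOW = 15_000_000


def _mode_int(values: np.ndarray) -> int:
    """Mode of non-negative integers; ties resolve to the smaller value."""
    counts = np.bincount(values)
    return int(np.argmax(counts))


def round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def cell_ploidy(states: np.ndarray, mask: np.ndarray) -> int:
    """Modal copy number state over unmasked bins (tie -> smaller state)."""
    if not mask.any():
        raise ValueError("all bins masked; ploidy undefined")
    return _mode_int(np.asarray(states)[mask])


def cell_ploidies(cn: CellCNMatrix) -> np.ndarray:
    return np.array([cell_ploidy(cn.state[i], cn.mask) for i in range(cn.n_cells)])


# ---------------------------------------------------------------------------
# Consensus / pseudobulk
# ---------------------------------------------------------------------------


@dataclass
class ConsensusProfile:
    """Pseudobulk profile per group: modal state, median copy, median BAF and
    modal haplotype-specific state over the group's cells."""

    groups: list[str]
    sizes: dict[str, int]
    state: np.ndarray  # (n_groups, n_bins) modal total state
    copy: np.ndarray  # median raw copy
    baf: np.ndarray  # median BAF
    a: np.ndarray  # modal haplotype state
    b: np.ndarray
    mask: np.ndarray

    def group_index(self, label: str) -> int:
        return self.groups.index(label)

    def ploidy(self, label: str) -> int:
        """Clone ploidy: modal consensus state over unmasked bins."""
        return _mode_int(self.state[self.group_index(label)][self.mask])


def consensus_profile(
    cn: CellCNMatrix,
    clones: dict[str, str] | pd.Series,
    hscn: HSCNMatrix | None = None,
) -> ConsensusProfile:
    """Group cells by clone label and compute per-bin consensus values.

    Modal ties resolve to the smaller value ((a, b) ties to the
    lexicographically smaller pair); medians of real-valued fields use the
    arithmetic mean of the middle pair.  Empty groups are dropped with a
    warning.
    """
    clones = dict(clones)
    labels = sorted({clones[c] for c in cn.cells if c in clones})
    groups: list[str] = []
    sizes: dict[str, int] = {}
    n_bins = cn.grid.n_bins
    rows_state, rows_copy, rows_baf, rows_a, rows_b = [], [], [], [], []
    for lab in labels:
        idx = [i for i, c in enumerate(cn.cells) if clones.get(c) == lab]
        if not idx:
            logger.warning("clone %s has no cells; dropped", lab)
            continue
        groups.append(lab)
        sizes[lab] = len(idx)
        st = cn.state[idx]
        rows_state.append([_mode_int(st[:, j]) for j in range(n_bins)])
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rows_copy.append(np.nanmedian(cn.raw_copy[idx], axis=0))
        if hscn is not None:
            width = int(hscn.a[idx].max() + hscn.b[idx].max() + 2)
            enc = hscn.a[idx] * width + hscn.b[idx]
            mode_enc = [_mode_int(enc[:, j]) for j in range(n_bins)]
            rows_a.append([m // width for m in mode_enc])
            rows_b.append([m % width for m in mode_enc])
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                rows_baf.append(np.nanmedian(hscn.baf[idx], axis=0))
        else:
            rows_a.append(np.zeros(n_bins, dtype=int))
            rows_b.append(np.zeros(n_bins, dtype=int))
            rows_baf.append(np.full(n_bins, np.nan))
    if not groups:
        raise ValueError("no non-empty groups")
    return ConsensusProfile(
        groups=groups,
        sizes=sizes,
        state=np.array(rows_state, dtype=np.int64),
        copy=np.array(rows_copy, dtype=float),
        baf=np.array(rows_baf, dtype=float),
        a=np.array(rows_a, dtype=np.int64),
        b=np.array(rows_b, dtype=np.int64),
        mask=cn.mask,
    )


# ---------------------------------------------------------------------------
# Missegregation
# ---------------------------------------------------------------------------


def detect_missegregations(
    cn: CellCNMatrix,
    clones: dict[str, str],
    consensus: ConsensusProfile,
    coverage: float = MISSEG_COVERAGE,
) -> pd.DataFrame:
    """Whole-chromosome missegregation events.

    Cells whose ploidy differs from their clone's consensus ploidy are
    rescaled (state * clone_ploidy / cell_ploidy, rounded half away from
    zero).  A chromosome is flagged with offset ``k != 0`` when bins with that
    exact offset against the clone consensus cover >= 75% of the chromosome's
    unmasked bins.
    """
    grid = cn.grid
    records = []
    ploidies = cell_ploidies(cn)
    for ci, cell in enumerate(cn.cells):
        clone = clones.get(cell)
        if clone is None or clone not in consensus.groups:
            continue
        gi_clone = consensus.group_index(clone)
        clone_ploidy = consensus.ploidy(clone)
        cp = ploidies[ci]
        if cp != clone_ploidy:
            norm = round_half_away(cn.state[ci].astype(float) * clone_ploidy / cp)
        else:
            norm = cn.state[ci].astype(float)
        offset = norm - consensus.state[gi_clone]
        for chrom in grid.chroms:
            bins = grid.chrom_bins(chrom)
            um = bins[cn.mask[bins]]
            if len(um) == 0:
                continue
            off = offset[um]
            vals, counts = np.unique(off, return_counts=True)
            for k, cnt in zip(vals, counts):
                if k != 0 and cnt / len(um) >= coverage:
                    records.append((cell, chrom, int(k), cnt / len(um)))
    return pd.DataFrame(records, columns=["cell_id", "chrom", "offset", "coverage"])


# ---------------------------------------------------------------------------
# Gain/loss segments
# ---------------------------------------------------------------------------


def call_gain_loss_segments(
    states: np.ndarray,
    ploidy: int,
    grid: BinGrid,
    mask: np.ndarray,
    min_span: float = MIN_SEGMENT_SPAN,
) -> pd.DataFrame:
    """Maximal runs of consecutive unmasked bins above (gain) or below (loss)
    the cell's ploidy.  Runs whose genomic span (summed unmasked bin lengths)
    is <= 1.5 Mbp are discarded as noise.  Masked bins neither break nor
    extend a run."""
    lengths = grid.bin_lengths
    rows = []
    for chrom in grid.chroms:
        bins = grid.chrom_bins(chrom)
        um = bins[mask[bins]]
        if len(um) == 0:
            continue
        lab = np.sign(states[um].astype(int) - ploidy)
        start = 0
        for i in range(1, len(um) + 1):
            if i == len(um) or lab[i] != lab[start]:
                if lab[start] != 0:
                    run = um[start:i]
                    span = int(lengths[run].sum())
                    if span > min_span:
                        rows.append(
                            (
                                chrom,
                                int(grid.bins["start"].iloc[run[0]]),
                                int(grid.bins["end"].iloc[run[-1]]),
                                "gain" if lab[start] > 0 else "loss",
                                len(run),
                                span,
                            )
                        )
                start = i
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "label", "n_bins", "span"]
    )


def gain_loss_ratio(segments: pd.DataFrame) -> tuple[float, int, int]:
    """(#gain segments / #loss segments, n_gain, n_loss); inf when losses are
    absent, NaN when both are."""
    n_gain = int((segments["label"] == "gain").sum()) if len(segments) else 0
    n_loss = int((segments["label"] == "loss").sum()) if len(segments) else 0
    if n_loss == 0:
        ratio = math.nan if n_gain == 0 else math.inf
    else:
        ratio = n_gain / n_loss
    return ratio, n_gain, n_loss


# ---------------------------------------------------------------------------
# HLAMP
# ---------------------------------------------------------------------------


def detect_hlamp_bins(
    cn: CellCNMatrix,
    min_copy: float = HLAMP_COPY,
    min_cells: int = HLAMP_MIN_CELLS,
) -> np.ndarray:
    """Bins where at least ``min_cells`` cells have raw copy >= ``min_copy``."""
    with np.errstate(invalid="ignore"):
        n_high = (cn.raw_copy >= min_copy).sum(axis=0)
    return (n_high >= min_cells) & cn.mask


def hlamp_copy_variance(
    cn: CellCNMatrix,
    ploidies: np.ndarray,
    clones: dict[str, str],
    hlamp_bins: np.ndarray,
) -> tuple[pd.DataFrame, float]:
    """Across-cell variance of ploidy- and clone-adjusted raw copy.

    Adjusted value = raw_copy / cell_ploidy minus the clone mean of the same
    quantity per bin.  Returns the per-bin table and the dataset mean over
    HLAMP bins.
    """
    adj = cn.raw_copy / np.asarray(ploidies, dtype=float)[:, None]
    centered = np.full_like(adj, np.nan)
    labels = np.array([clones.get(c) for c in cn.cells], dtype=object)
    for lab in pd.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) == 1:
            logger.info("clone %s has a single cell; adjusted values are 0", lab)
        with np.errstate(all="ignore"):
            centered[idx] = adj[idx] - np.nanmean(adj[idx], axis=0)
    rows = []
    for j in np.flatnonzero(hlamp_bins):
        v = centered[:, j]
        v = v[np.isfinite(v)]
        var = float(np.var(v, ddof=1)) if len(v) > 1 else 0.0
        rows.append((j, var))
    table = pd.DataFrame(rows, columns=["bin", "variance"])
    mean_var = float(table["variance"].mean()) if len(table) else math.nan
    return table, mean_var


def clone_amplitude_ratio(
    consensus: ConsensusProfile, genes: pd.DataFrame, grid: BinGrid
) -> pd.DataFrame:
    """Max/min clone-level consensus copy per gene region.

    Genes are flagged "variable" when the ratio is >= 2 (a zero minimum gives
    an infinite, variable ratio).
    """
    if len(consensus.groups) < 2:
        raise ValueError("amplitude ratio needs at least two clones")
    rows = []
    gstart = grid.bins["start"].to_numpy()
    gend = grid.bins["end"].to_numpy()
    gchrom = grid.bins["chrom"].to_numpy()
    for gene in genes.itertuples():
        hit = (
            (gchrom == str(gene.chrom))
            & (gstart <= gene.end)
            & (gend >= gene.start)
            & consensus.mask
        )
        if not hit.any():
            raise ValueError(f"gene {gene.name} outside bin grid")
        vals = np.nanmean(consensus.copy[:, hit], axis=1)
        lo, hi = float(np.min(vals)), float(np.max(vals))
        ratio = math.inf if lo == 0 else hi / lo
        rows.append((gene.name, ratio, ratio >= AMPLITUDE_RATIO_MIN))
    return pd.DataFrame(rows, columns=["gene", "ratio", "variable"])


# ---------------------------------------------------------------------------
# Disjoint segmentation
# ---------------------------------------------------------------------------


@dataclass
class SegmentTable:
    """Disjoint segments from the union of group-level breakpoints, genotyped
    in every cell by the modal (total, a, b) over covered unmasked bins."""

    segments: pd.DataFrame  # segment_id, chrom, start, end, start_bin, end_bin, span
    cells: list[str]
    total: np.ndarray  # (n_cells, n_segments)
    a: np.ndarray
    b: np.ndarray

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def to_long_df(self) -> pd.DataFrame:
        recs = []
        for si, seg in enumerate(self.segments.itertuples()):
            for ci, cell in enumerate(self.cells):
                recs.append(
                    (
                        seg.segment_id,
                        seg.chrom,
                        seg.start,
                        seg.end,
                        cell,
                        int(self.total[ci, si]),
                        int(self.a[ci, si]),
                        int(self.b[ci, si]),
                    )
                )
        return pd.DataFrame(
            recs,
            columns=["segment_id", "chrom", "start", "end", "cell_id", "total", "a", "b"],
        )

    def to_tsv(self, path) -> None:
        self.to_long_df().to_csv(path, sep="\t", index=False)


def segment_bins(states: np.ndarray, bins: np.ndarray, mask: np.ndarray) -> list[tuple]:
    """Maximal runs of equal state over the unmasked bins of one chromosome;
    returns (start_bin, end_bin, state) tuples in bin coordinates."""
    um = bins[mask[bins]]
    if len(um) == 0:
        return []
    out = []
    start = 0
    vals = states[um]
    for i in range(1, len(um) + 1):
        if i == len(um) or vals[i] != vals[start]:
            out.append((int(um[start]), int(um[i - 1]), int(vals[start])))
            start = i
    return out


def clone_segmentations(consensus: ConsensusProfile, grid: BinGrid) -> list[pd.DataFrame]:
    """Per-clone segmentations of the consensus total states, as (chrom,
    start_bin, end_bin) tables ready for :func:`disjoin_and_genotype`."""
    out = []
    for gi in range(len(consensus.groups)):
        rows = []
        for chrom in grid.chroms:
            bins = grid.chrom_bins(chrom)
            for s, e, _ in segment_bins(consensus.state[gi], bins, consensus.mask):
                rows.append((chrom, s, e))
        out.append(pd.DataFrame(rows, columns=["chrom", "start_bin", "end_bin"]))
    return out


def recurrent_breakpoint_segmentation(
    cn: CellCNMatrix,
    hscn: HSCNMatrix | None = None,
    min_cell_fraction: float = 0.01,
    merge_radius: int = 5,
) -> pd.DataFrame:
    """Segmentation from breakpoints recurring across cells.

    Collects per-cell change points of the (total, a, b) profile and keeps
    positions shared by more than ``min_cell_fraction`` of cells (sporadic
    single-cell noise breakpoints do not recur at the same bin).  Recurrent
    positions within ``merge_radius`` bins of a better-supported one are
    treated as jitter of the same breakpoint and merged into it.  Returns a
    (chrom, start_bin, end_bin) table covering every chromosome, suitable for
    :func:`disjoin_and_genotype`; rare but recurrent subclonal breakpoints
    are retained, unlike in a clone-consensus segmentation.
    """
    grid = cn.grid
    n_cells = cn.n_cells
    rows = []
    for chrom in grid.chroms:
        bins = grid.chrom_bins(chrom)
        um = bins[cn.mask[bins]]
        if len(um) == 0:
            continue
        counts: dict[int, int] = {}
        for ci in range(n_cells):
            if hscn is not None:
                prof = list(
                    zip(cn.state[ci, um], hscn.a[ci, um], hscn.b[ci, um])
                )
            else:
                prof = list(cn.state[ci, um])
            for k in range(1, len(um)):
                if prof[k] != prof[k - 1]:
                    counts[int(um[k])] = counts.get(int(um[k]), 0) + 1
        # greedy merge: best-supported positions absorb jittered neighbours
        accepted: list[int] = []
        absorbed: dict[int, int] = {}
        for p, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
            near = [q for q in accepted if abs(q - p) <= merge_radius]
            if near:
                absorbed[p] = min(near, key=lambda q: (abs(q - p), q))
            else:
                accepted.append(p)
        support = {q: 0 for q in accepted}
        for p, c in counts.items():
            support[absorbed.get(p, p)] += c
        cuts = sorted(q for q in accepted if support[q] > min_cell_fraction * n_cells)
        bounds = [int(um[0])] + cuts + [int(um[-1]) + 1]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if hi > lo:
                rows.append((chrom, lo, hi - 1))
    return pd.DataFrame(rows, columns=["chrom", "start_bin", "end_bin"])


def disjoin_and_genotype(
    segmentations: list[pd.DataFrame],
    cn: CellCNMatrix,
    hscn: HSCNMatrix | None = None,
) -> SegmentTable:
    """Disjoint union of group-level breakpoints, genotyped per cell.

    ``segmentations`` are DataFrames with columns ``chrom, start_bin,
    end_bin`` (bin coordinates on the shared grid).  The output segments
    partition the union of the input segments; each cell's genotype per
    segment is the modal (total, a, b) over the segment's unmasked bins, ties
    to the lexicographically smaller triple.
    """
    grid = cn.grid
    seg_rows = []
    for chrom in grid.chroms:
        cuts: set[int] = set()
        covered: set[int] = set()
        for segdf in segmentations:
            sel = segdf[segdf["chrom"] == chrom]
            for r in sel.itertuples():
                cuts.add(int(r.start_bin))
                cuts.add(int(r.end_bin) + 1)
                covered.update(range(int(r.start_bin), int(r.end_bin) + 1))
        if not covered:
            continue
        bounds = sorted(cuts)
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            seg = [bb for bb in range(lo, hi) if bb in covered]
            if seg:
                seg_rows.append((chrom, seg[0], seg[-1]))
    seg_df = pd.DataFrame(seg_rows, columns=["chrom", "start_bin", "end_bin"])
    seg_df["segment_id"] = [f"seg{i}" for i in range(len(seg_df))]
    seg_df["start"] = grid.bins["start"].to_numpy()[seg_df["start_bin"]]
    seg_df["end"] = grid.bins["end"].to_numpy()[seg_df["end_bin"]]
    seg_df["span"] = seg_df["end"] - seg_df["start"] + 1
    seg_df = seg_df[
        ["segment_id", "chrom", "start", "end", "start_bin", "end_bin", "span"]
    ]
    n_cells = cn.n_cells
    total = np.zeros((n_cells, len(seg_df)), dtype=np.int64)
    a = np.zeros_like(total)
    b = np.zeros_like(total)
    for si, seg in enumerate(seg_df.itertuples()):
        bins = np.arange(seg.start_bin, seg.end_bin + 1)
        bins = bins[cn.mask[bins]]
        if len(bins) == 0:
            continue
        for ci in range(n_cells):
            if hscn is not None:
                trip = list(zip(cn.state[ci, bins], hscn.a[ci, bins], hscn.b[ci, bins]))
            else:
                trip = [(s, 0, 0) for s in cn.state[ci, bins]]
            vals, counts = np.unique(np.array(trip), axis=0, return_counts=True)
            # np.unique sorts lexicographically, so argmax picks the smaller triple on ties
            best = vals[int(np.argmax(counts))]
            total[ci, si], a[ci, si], b[ci, si] = map(int, best)
    return SegmentTable(
        segments=seg_df.reset_index(drop=True), cells=list(cn.cells), total=total, a=a, b=b
    )


# ---------------------------------------------------------------------------
# HLAMP locus features
# ---------------------------------------------------------------------------


def hlamp_feature_vector(
    locus: tuple[str, int],
    cn: CellCNMatrix,
    hscn: HSCNMatrix,
    svs: pd.DataFrame | None,
    window: int = HLAMP_WINDOW,
) -> dict[str, float]:
    """Genomic feature record around an amplified locus (window clipped at
    chromosome ends).  SV-derived features are 0 when no SVs fall in the
    window.  Averages are across cells."""
    chrom, pos = locus
    grid = cn.grid
    bins = grid.chrom_bins(chrom)
    starts = grid.bins["start"].to_numpy()[bins]
    ends = grid.bins["end"].to_numpy()[bins]
    lo, hi = pos - window, pos + window
    wbins = bins[(starts <= hi) & (ends >= lo) & cn.mask[bins]]
    # entropy of haplotype-specific state frequencies in the window
    pairs = np.stack([hscn.a[:, wbins].ravel(), hscn.b[:, wbins].ravel()], axis=1)
    _, counts = np.unique(pairs, axis=0, return_counts=True)
    freq = counts / counts.sum()
    entropy = float(-(freq * np.log2(freq)).sum())
    # SV features
    sv_count = 0.0
    props = {k: 0.0 for k in ("foldback", "duplication", "deletion", "translocation")}
    n_tr_chroms = 0.0
    if svs is not None and len(svs):
        in_win = (
            ((svs["chrom1"].astype(str) == chrom) & svs["pos1"].between(lo, hi))
            | ((svs["chrom2"].astype(str) == chrom) & svs["pos2"].between(lo, hi))
        )
        sel = svs[in_win]
        sv_count = float(len(sel))
        if len(sel):
            for k in props:
                props[k] = float((sel["type"] == k).mean())
            tr = sel[sel["type"] == "translocation"]
            n_tr_chroms = float(
                len(set(tr["chrom1"].astype(str)) | set(tr["chrom2"].astype(str)))
            )
    # copy features
    locus_bin = bins[(starts <= pos) & (ends >= pos)]
    with np.errstate(all="ignore"):
        chrom_mean = np.nanmean(cn.raw_copy[:, bins[cn.mask[bins]]], axis=1)
        locus_copy = np.nanmean(cn.raw_copy[:, locus_bin], axis=1)
        copy_ratio = float(np.nanmean(locus_copy / np.where(chrom_mean > 0, chrom_mean, np.nan)))
    mean_state = float(cn.state[:, wbins].mean())
    seg_sizes, seg_counts = [], []
    for ci in range(cn.n_cells):
        segs = segment_bins(cn.state[ci], wbins, cn.mask)
        seg_counts.append(len(segs))
        seg_sizes.extend(e - s + 1 for s, e, _ in segs)
    minor = np.minimum(hscn.a[:, wbins], hscn.b[:, wbins])
    feats = {
        "hscn_entropy": entropy,
        "sv_count": sv_count,
        "prop_foldback": props["foldback"],
        "prop_duplication": props["duplication"],
        "prop_deletion": props["deletion"],
        "prop_translocation": props["translocation"],
        "n_translocation_chroms": n_tr_chroms,
        "copy_ratio": copy_ratio,
        "mean_copy_state": mean_state,
        "mean_segment_size": float(np.mean(seg_sizes)) if seg_sizes else 0.0,
        "mean_segment_count": float(np.mean(seg_counts)),
        "mean_minor_copy": float(minor.mean()),
    }
    return feats


def cluster_hlamp_features(features: pd.DataFrame, max_k: int = 8) -> pd.Series:
    """Hierarchical (Ward) clustering of standardized locus features with the
    number of clusters chosen by silhouette width."""
    from scipy.cluster.hierarchy import fcluster, linkage
    from sklearn.metrics import silhouette_score

    X = features.to_numpy(dtype=float)
    sd = X.std(axis=0)
    X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    Z = linkage(X, method="ward")
    best_k, best_score, best_labels = 1, -np.inf, np.ones(len(X), dtype=int)
    for k in range(2, min(max_k, len(X) - 1) + 1):
        labels = fcluster(Z, k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(X, labels)
        if score > best_score:
            best_k, best_score, best_labels = k, score, labels
    return pd.Series(best_labels, index=features.index, name=f"cluster_k{best_k}")
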