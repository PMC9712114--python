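"""Evolutionary statistics on haplotype-specific copy number.

Parallel CNA detection, clonality classes, a WGD-aware copy-number
transformation distance, parsimony event rates on single-cell phylogenies and
cophenetic diversity.

The copy-number transformation distance counts the minimum number of
operations needed to turn one integer copy profile into another, where an
operation adds or subtracts one copy on a contiguous interval, values floor
at zero and a position at zero can never regain copies.  The implementation
uses a dynamic program over the number of deletion/amplification intervals
covering each position; an optimal solution always exists with all deletions
before all amplifications, which makes the per-position interval multiplicity
a sufficient state.
"""

from __future__ import annotations

import logging
import math

import dendropy
import numpy as np
import pandas as pd

from .core_io import BinGrid
from .cn_metrics import SegmentTable, _mode_int

logger = logging.getLogger(__name__)

PARALLEL_MIN_SPAN = 4_000_000
PARALLEL_MIN_FRACTION = 0.01
CCF_CLONAL = 0.8
CCF_RARE = 0.2
SCALE_COVERAGE = 0.95


# ---------------------------------------------------------------------------
# Copy-number transformation distance
# ---------------------------------------------------------------------------


def cnt_distance(u, v) -> float:
    """Minimum number of +/-1 contiguous-interval operations turning ``u``
    into ``v`` (floor at zero; zeros never regain).  ``inf`` when infeasible
    (a zero position with positive target)."""
    u = np.asarray(u, dtype=np.int64)
    v = np.asarray(v, dtype=np.int64)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    if np.any((u == 0) & (v > 0)):
        return math.inf
    if len(u) == 0:
        return 0
    # compress runs with identical (source, target); constraints are per-value
    keep = np.ones(len(u), dtype=bool)
    keep[1:] = (u[1:] != u[:-1]) | (v[1:] != v[:-1])
    pairs = list(zip(u[keep], v[keep]))
    d_max = int(u.max())
    # DP over (deletions covering the position, amplifications at the last
    # target-positive position); cost counts interval openings
    states: dict[tuple[int, int], int] = {(0, 0): 0}
    for s, t in pairs:
        s, t = int(s), int(t)
        new: dict[tuple[int, int], int] = {}
        if t > 0:
            for delta in range(max(0, s - t), s):
                alpha = delta + t - s
                best = math.inf
                for (dp, ap), c in states.items():
                    cost = c + max(delta - dp, 0) + max(alpha - ap, 0)
                    if cost < best:
                        best = cost
                new[(delta, alpha)] = int(best)
        else:
            for delta in range(s, d_max + 1):
                for (dp, ap), c in states.items():
                    cost = c + max(delta - dp, 0)
                    key = (delta, ap)
                    if cost < new.get(key, math.inf):
                        new[key] = cost
        states = new
    return min(states.values())


def profile_distance(
    a1: np.ndarray, b1: np.ndarray, a2: np.ndarray, b2: np.ndarray, chrom: np.ndarray
) -> float:
    """Transformation distance summed per chromosome over both haplotypes."""
    total = 0.0
    for c in pd.unique(chrom):
        sel = chrom == c
        total += cnt_distance(a1[sel], a2[sel]) + cnt_distance(b1[sel], b2[sel])
        if math.isinf(total):
            return math.inf
    return total


def wgd_distance(
    a1: np.ndarray, b1: np.ndarray, a2: np.ndarray, b2: np.ndarray, chrom: np.ndarray
) -> float:
    """WGD-aware distance: ``min(d1, d2, d3)`` over the plain distance and the
    distances after doubling either profile, counting WGD as one extra event.
    A tie with the undoubled distance resolves to it with no increment."""
    d1 = profile_distance(a1, b1, a2, b2, chrom)
    d2 = profile_distance(2 * a1, 2 * b1, a2, b2, chrom)
    d3 = profile_distance(a1, b1, 2 * a2, 2 * b2, chrom)
    if d1 <= min(d2, d3):
        return d1
    return min(d2, d3) + 1


def pairwise_distance_matrix(
    hscn,
    max_n: int = 250,
    seed: int | None = None,
    use_wgd: bool = True,
):
    """All pairwise WGD-aware distances over (a subsample of) cells.

    When more than ``max_n`` cells are present a uniform random subsample
    without replacement is taken (seeded).  The transformation distance is
    directional (a lost homologue can never be regained), so each pair is
    evaluated in both directions and the smaller value kept, making the
    matrix symmetric and finite whenever either direction is feasible.
    Returns ``(cell_ids, distance_matrix, summary)``.
    """
    n = len(hscn.cells)
    if n < 2:
        raise ValueError("need at least 2 cells")
    rng = np.random.default_rng(seed)
    if n > max_n:
        idx = np.sort(rng.choice(n, size=max_n, replace=False))
    else:
        idx = np.arange(n)
    chrom = hscn.grid.bins["chrom"].to_numpy()[hscn.mask]
    a = hscn.a[:, hscn.mask]
    b = hscn.b[:, hscn.mask]
    m = len(idx)
    D = np.zeros((m, m))
    fn = wgd_distance if use_wgd else profile_distance
    for i in range(m):
        for j in range(i + 1, m):
            d = fn(a[idx[i]], b[idx[i]], a[idx[j]], b[idx[j]], chrom)
            if math.isinf(d):
                d = fn(a[idx[j]], b[idx[j]], a[idx[i]], b[idx[i]], chrom)
            else:
                d = min(d, fn(a[idx[j]], b[idx[j]], a[idx[i]], b[idx[i]], chrom))
            D[i, j] = D[j, i] = d
    iu = np.triu_indices(m, 1)
    vals = D[iu]
    summary = {
        "n_cells": m,
        "n_pairs": len(vals),
        "mean": float(np.mean(vals)),
        "median": float(np.median(vals)),
    }
    return [hscn.cells[i] for i in idx], D, summary


# ---------------------------------------------------------------------------
# Parallel CNAs and clonality
# ---------------------------------------------------------------------------


def classify_clonality(ccf: float) -> str:
    """Clonal (CCF > 80%), subclonal (20% < CCF <= 80%) or rare (CCF <= 20%)."""
    if ccf > CCF_CLONAL:
        return "clonal"
    if ccf > CCF_RARE:
        return "subclonal"
    return "rare"


def detect_parallel_cna(
    st: SegmentTable,
    min_span: float = PARALLEL_MIN_SPAN,
    min_fraction: float = PARALLEL_MIN_FRACTION,
) -> pd.DataFrame:
    """Segments altered on both homologues in independent cells.

    Per segment the modal haplotype states (a*, b*) define the reference; a
    parallel gain needs the fraction of cells with a > a* and the fraction
    with b > b* both above 1%, on a segment spanning more than 4 Mbp
    (analogously for losses).  The CCF of the total-copy event and its
    clonality class are reported alongside.
    """
    rows = []
    for si, seg in enumerate(st.segments.itertuples()):
        span = int(seg.span)
        a = st.a[:, si]
        b = st.b[:, si]
        total = st.total[:, si]
        a_star, b_star = _mode_int(a), _mode_int(b)
        t_star = _mode_int(total)
        n = len(a)
        for direction, fa, fb, ccf in (
            (
                "gain",
                (a > a_star).mean(),
                (b > b_star).mean(),
                (total > t_star).mean(),
            ),
            (
                "loss",
                (a < a_star).mean(),
                (b < b_star).mean(),
                (total < t_star).mean(),
            ),
        ):
            parallel = (
                span > min_span and fa > min_fraction and fb > min_fraction
            )
            if parallel:
                rows.append(
                    (
                        seg.segment_id,
                        seg.chrom,
                        seg.start,
                        seg.end,
                        span,
                        direction,
                        float(fa),
                        float(fb),
                        float(ccf),
                        classify_clonality(float(ccf)),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "segment_id",
            "chrom",
            "start",
            "end",
            "span",
            "direction",
            "frac_a",
            "frac_b",
            "ccf",
            "clonality",
        ],
    )


# ---------------------------------------------------------------------------
# Phylogeny: parsimony event rates and cophenetic diversity
# ---------------------------------------------------------------------------


def load_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def sankoff_score(tree: dendropy.Tree, tip_states: dict[str, int], n_states: int = 2) -> int:
    """Minimum number of state transitions (unit cost) explaining the tip
    states on the tree; works on arbitrary (multifurcating) trees."""
    INF = math.inf
    costs: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            if label not in tip_states:
                costs[node] = np.zeros(n_states)  # uninformative tip
                continue
            c = np.full(n_states, INF)
            c[tip_states[label]] = 0
            costs[node] = c
        else:
            c = np.zeros(n_states)
            for child in node.child_nodes():
                cc = costs[child]
                trans = np.array(
                    [min(cc[j] + (1 if i != j else 0) for j in range(n_states)) for i in range(n_states)]
                )
                c = c + trans
            costs[node] = c
    return int(min(costs[tree.seed_node]))


def classify_segment_scale(
    segment,
    grid: BinGrid,
    centromeres: pd.DataFrame | None,
    mask: np.ndarray,
    coverage: float = SCALE_COVERAGE,
) -> str:
    """Whole chromosome (>= 95% of the chromosome's unmasked bins), arm
    (>= 95% of one arm but not the chromosome) or segmental."""
    chrom = str(segment.chrom)
    bins = grid.chrom_bins(chrom)
    um = bins[mask[bins]]
    seg_bins = um[(um >= segment.start_bin) & (um <= segment.end_bin)]
    if len(um) and len(seg_bins) / len(um) >= coverage:
        return "whole_chromosome"
    if centromeres is None or chrom not in set(centromeres["chrom"].astype(str)):
        logger.warning("no centromere record for %s; classified segmental", chrom)
        return "segmental"
    row = centromeres[centromeres["chrom"].astype(str) == chrom].iloc[0]
    ends = grid.bins["end"].to_numpy()
    starts = grid.bins["start"].to_numpy()
    p_arm = um[ends[um] <= row["cent_start"]]
    q_arm = um[starts[um] >= row["cent_end"]]
    for arm in (p_arm, q_arm):
        if len(arm):
            frac = np.isin(arm, seg_bins).mean()
            if frac >= coverage:
                return "arm"
    return "segmental"


def parsimony_event_rate(
    tree: dendropy.Tree,
    st: SegmentTable,
    grid: BinGrid,
    centromeres: pd.DataFrame | None,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per segment-class and direction: parsimony score and per-cell rate.

    States per cell per segment are binary (gained / not gained and lost /
    not lost) relative to the modal total state across cells.  Transitions
    cost 1; the minimal-cost ancestral labelling is found with the Sankoff
    algorithm.  The background column records the modal haplotype state of the
    segment (e.g. ``1|1`` diploid, ``2|2`` tetraploid).
    """
    if mask is None:
        mask = np.ones(grid.n_bins, dtype=bool)
    tips = {t.label for t in tree.taxon_namespace}
    cell_idx = [i for i, c in enumerate(st.cells) if c in tips]
    missing = tips - set(st.cells)
    if missing:
        logger.warning("%d tree tips without genotypes are uninformative", len(missing))
    n_cells = len(tips)
    rows = []
    for si, seg in enumerate(st.segments.itertuples()):
        total = st.total[:, si]
        t_star = _mode_int(total)
        a_star = _mode_int(st.a[:, si])
        b_star = _mode_int(st.b[:, si])
        background = f"{a_star}|{b_star}"
        scale = classify_segment_scale(seg, grid, centromeres, mask)
        for direction, altered in (
            ("gain", total > t_star),
            ("loss", total < t_star),
        ):
            tip_states = {st.cells[i]: int(altered[i]) for i in cell_idx}
            score = sankoff_score(tree, tip_states) if any(altered[cell_idx]) else 0
            rows.append(
                (seg.segment_id, scale, direction, background, score, n_cells, score / n_cells)
            )
    return pd.DataFrame(
        rows,
        columns=["segment_id", "scale", "direction", "background", "score", "n_cells", "rate"],
    )


def aggregate_event_rates(per_segment: pd.DataFrame) -> pd.DataFrame:
    """Sum parsimony scores within (scale, direction, background) and divide
    by the cell count."""
    out = (
        per_segment.groupby(["scale", "direction", "background"], as_index=False)
        .agg(score=("score", "sum"), n_cells=("n_cells", "first"))
    )
    out["rate"] = out["score"] / out["n_cells"]
    return out


def cophenetic_diversity(tree: dendropy.Tree) -> float:
    """Mean pairwise path length between tips (branch lengths are copy-number
    change counts)."""
    taxa = list(tree.taxon_namespace)
    if len(taxa) < 2:
        raise ValueError("need at least 2 tips")
    pdm = tree.phylogenetic_distance_matrix()
    dists = [
        pdm.distance(t1, t2)
        for i, t1 in enumerate(taxa)
        for t2 in taxa[i + 1 :]
    ]
    return float(np.mean(dists))
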