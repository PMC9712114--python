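"""Allelic imbalance in scRNA-seq using DNA-derived haplotype phasing.

SNP counts from scRNA-seq are phased with the block orientations learned from
the scDNA-seq, aggregated to large segments (>= 10 Mbp) to overcome sparsity,
and compared with the DNA B-allele frequencies.  A nearest-neighbour
enrichment score quantifies transcriptional convergence of cells sharing an
allelic state.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

logger = logging.getLogger(__name__)

MIN_SNP_COUNTS = 200  # cells below this total are removed
MIN_SEGMENT_SIZE = 10_000_000


@dataclass
class RnaSegmentBaf:
    """Cells x segments aggregated phased counts from scRNA-seq."""

    segments: pd.DataFrame  # segment_id, chrom, start, end
    cells: list[str]
    b: np.ndarray
    t: np.ndarray

    @property
    def baf(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.t > 0, self.b / np.where(self.t > 0, self.t, 1), np.nan)


def aggregate_rna_baf(
    snps: pd.DataFrame,
    segments: pd.DataFrame,
    orientation: dict[int, int] | None = None,
    min_counts: int = MIN_SNP_COUNTS,
    min_size: float = MIN_SEGMENT_SIZE,
) -> RnaSegmentBaf:
    """Aggregate phased SNP counts per cell over segments of >= 10 Mbp.

    ``snps`` columns: cell_id, chrom, pos, allele_b_count, total_count and
    optionally block_id.  ``orientation`` maps block_id to +/-1 (DNA-derived
    phasing); flipped blocks contribute ``t - b``.  Cells with fewer than 200
    total SNP counts are removed.
    """
    snps = snps.copy()
    if orientation is not None and "block_id" in snps.columns:
        orient = snps["block_id"].map(lambda k: orientation.get(k, 1)).to_numpy()
        flip = orient < 0
        snps.loc[flip, "allele_b_count"] = (
            snps.loc[flip, "total_count"] - snps.loc[flip, "allele_b_count"]
        )
    per_cell = snps.groupby("cell_id")["total_count"].sum()
    keep_cells = per_cell[per_cell >= min_counts].index
    dropped = len(per_cell) - len(keep_cells)
    if dropped:
        logger.info("dropped %d cells below %d SNP counts", dropped, min_counts)
    snps = snps[snps["cell_id"].isin(keep_cells)]
    segs = segments[(segments["end"] - segments["start"] + 1) >= min_size].reset_index(
        drop=True
    )
    cells = list(keep_cells)
    cell_pos = {c: i for i, c in enumerate(cells)}
    b = np.zeros((len(cells), len(segs)), dtype=np.int64)
    t = np.zeros_like(b)
    for si, seg in enumerate(segs.itertuples()):
        sel = snps[
            (snps["chrom"].astype(str) == str(seg.chrom))
            & snps["pos"].between(seg.start, seg.end)
        ]
        if len(sel) == 0:
            continue
        g = sel.groupby("cell_id")[["allele_b_count", "total_count"]].sum()
        for cell, row in g.iterrows():
            ci = cell_pos[cell]
            b[ci, si] = row["allele_b_count"]
            t[ci, si] = row["total_count"]
    return RnaSegmentBaf(segments=segs, cells=cells, b=b, t=t)


def aggregate_dna_baf(counts, segments: pd.DataFrame) -> pd.DataFrame:
    """Segment-level BAF per cell from oriented DNA block counts.

    Blocks are assigned to segments by midpoint.  Returns a long table
    (cell_id, segment_id, baf); rows without informative reads are omitted.
    """
    mids = (counts.blocks["start"].to_numpy() + counts.blocks["end"].to_numpy()) // 2
    chroms = counts.blocks["chrom"].to_numpy().astype(str)
    b_or = counts.oriented_b()
    rows = []
    for seg in segments.itertuples():
        sel = (chroms == str(seg.chrom)) & (mids >= seg.start) & (mids <= seg.end)
        if not sel.any():
            continue
        b = b_or[:, sel].sum(axis=1)
        t = counts.t[:, sel].sum(axis=1)
        for ci, cell in enumerate(counts.cells):
            if t[ci] > 0:
                rows.append((cell, seg.segment_id, b[ci] / t[ci]))
    return pd.DataFrame(rows, columns=["cell_id", "segment_id", "baf"])


def compare_dna_rna_baf(
    dna_baf: pd.DataFrame, rna_baf: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Per-segment mean BAF in each modality and their Pearson correlation.

    Inputs are tables with columns ``segment_id, baf`` (one row per cell and
    segment); segments present in both modalities are compared.  Correlation
    is NaN with fewer than 3 shared segments.
    """
    d = dna_baf.groupby("segment_id")["baf"].mean()
    r = rna_baf.groupby("segment_id")["baf"].mean()
    shared = sorted(set(d.index) & set(r.index))
    table = pd.DataFrame(
        {"segment_id": shared, "dna_baf": d[shared].to_numpy(), "rna_baf": r[shared].to_numpy()}
    )
    table = table.dropna()
    if len(table) < 3:
        return table, math.nan
    corr = float(pearsonr(table["dna_baf"], table["rna_baf"])[0])
    return table, corr


def nn_enrichment(
    neighbors: dict[str, list[str]], states: dict[str, str]
) -> pd.Series:
    """Per-cell log2 enrichment of same-state cells among nearest neighbours.

    Score = log2(observed fraction / expected fraction), with the expected
    fraction the global fraction of cells in the cell's state.  0 marks a
    perfectly mixed neighbourhood, positive overrepresentation, negative
    underrepresentation; an observed fraction of 0 yields -inf (censored
    minimum).
    """
    labels = pd.Series(states)
    global_frac = labels.value_counts(normalize=True)
    scores = {}
    for cell, nbrs in neighbors.items():
        if cell not in states or not nbrs:
            continue
        state = states[cell]
        obs = np.mean([states.get(n) == state for n in nbrs])
        exp = global_frac[state]
        scores[cell] = -math.inf if obs == 0 else math.log2(obs / exp)
    return pd.Series(scores, name="enrichment")


def knn_from_embedding(
    embedding: np.ndarray, cell_ids: list[str], k: int = 10
) -> dict[str, list[str]]:
    """k-nearest-neighbour lists from any embedding matrix (testing utility)."""
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    return {cell_ids[i]: [cell_ids[j] for j in idx[i, 1:]] for i in range(len(cell_ids))}
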