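"""Data model, delimited-table readers/writers and the bin/cell filters.

All genomic coordinates are 1-based inclusive.  BED input is converted at the
I/O boundary (:func:`read_blacklist_bed`).  Tables are plain TSV with a header
so fixtures stay diffable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 500_000
MAPPABILITY_MIN = 0.99  # bins with mappability <= this are masked
QUALITY_MIN = 0.75
CONTAM_MAX = 0.05

GRID_COLUMNS = ["chrom", "start", "end", "mappability", "gc"]
CN_COLUMNS = ["cell_id", "chrom", "start", "end", "state", "raw_copy"]
ALLELE_COLUMNS = ["cell_id", "chrom", "start", "end", "b_count", "t_count"]
QC_COLUMNS = ["cell_id", "quality", "s_phase_flag", "contam_fraction", "clone"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class BinGrid:
    """Ordered fixed-width genomic bins.

    ``bins`` has columns ``chrom, start, end, mappability, gc``.  Bins must be
    grouped by chromosome, sorted by start within each chromosome, and
    non-overlapping.  The bin id is the positional index into ``bins``.
    """

    bins: pd.DataFrame
    width: int = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        df = self.bins.reset_index(drop=True)
        missing = [c for c in GRID_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"bin grid missing columns {missing}")
        self.bins = df
        self._validate()
        self._chrom_index = {
            c: np.flatnonzero(df["chrom"].to_numpy() == c) for c in self.chroms
        }

    def _validate(self) -> None:
        df = self.bins
        if (df["end"] < df["start"]).any():
            row = int(np.flatnonzero((df["end"] < df["start"]).to_numpy())[0])
            raise ValueError(f"bin grid row {row}: end < start")
        seen: list[str] = []
        for chrom, grp in df.groupby("chrom", sort=False):
            if chrom in seen:
                raise ValueError(f"bins of chromosome {chrom} are not contiguous")
            seen.append(str(chrom))
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if not np.all(np.diff(starts) > 0):
                row = int(grp.index[np.argmin(np.diff(starts) > 0) + 1])
                raise ValueError(f"bin grid row {row}: bins out of order on {chrom}")
            if np.any(starts[1:] <= ends[:-1]):
                row = int(grp.index[int(np.flatnonzero(starts[1:] <= ends[:-1])[0]) + 1])
                raise ValueError(f"bin grid row {row}: overlapping bins on {chrom}")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def chroms(self) -> list[str]:
        return list(pd.unique(self.bins["chrom"]))

    def chrom_bins(self, chrom: str) -> np.ndarray:
        """Positional bin indices of one chromosome."""
        return self._chrom_index[chrom]

    @property
    def bin_lengths(self) -> np.ndarray:
        return (self.bins["end"] - self.bins["start"] + 1).to_numpy()

    @classmethod
    def uniform(
        cls,
        n_chromosomes: int,
        bins_per_chromosome: int,
        width: int = DEFAULT_BIN_WIDTH,
        mappability: float = 1.0,
        gc: float = 0.45,
    ) -> "BinGrid":
        rows = []
        for c in range(1, n_chromosomes + 1):
            for i in range(bins_per_chromosome):
                rows.append((str(c), i * width + 1, (i + 1) * width, mappability, gc))
        return cls(pd.DataFrame(rows, columns=GRID_COLUMNS), width=width)

    @classmethod
    def from_tsv(cls, path) -> "BinGrid":
        df = pd.read_csv(path, sep="\t")
        df["chrom"] = df["chrom"].astype(str)
        width = int((df["end"] - df["start"] + 1).mode().iloc[0])
        return cls(df, width=width)

    def to_tsv(self, path) -> None:
        self.bins.to_csv(path, sep="\t", index=False)


@dataclass
class CellCNMatrix:
    """Cells x bins integer states and real-valued raw copy.

    ``state`` is the integer total copy number, ``raw_copy`` the GC-corrected
    read count scaled so each cell's mean over unmasked bins equals its ploidy
    (NaN where unavailable).  ``mask`` is True for bins retained by filters.
    """

    grid: BinGrid
    cells: list[str]
    state: np.ndarray
    raw_copy: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype=np.int64)
        self.raw_copy = np.asarray(self.raw_copy, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.grid.n_bins, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        n_cells, n_bins = self.state.shape
        if n_cells != len(self.cells) or n_bins != self.grid.n_bins:
            raise ValueError("state shape does not match cells x bins")
        if self.raw_copy.shape != self.state.shape:
            raise ValueError("raw_copy shape does not match state")
        if (self.state < 0).any():
            raise ValueError("negative copy number state")
        with np.errstate(invalid="ignore"):
            if np.any(self.raw_copy < 0):
                raise ValueError("negative raw_copy")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_index(self, cell_id: str) -> int:
        return self.cells.index(cell_id)

    def to_long_df(self) -> pd.DataFrame:
        g = self.grid.bins
        n_cells, n_bins = self.state.shape
        return pd.DataFrame(
            {
                "cell_id": np.repeat(self.cells, n_bins),
                "chrom": np.tile(g["chrom"].to_numpy(), n_cells),
                "start": np.tile(g["start"].to_numpy(), n_cells),
                "end": np.tile(g["end"].to_numpy(), n_cells),
                "state": self.state.ravel(),
                "raw_copy": self.raw_copy.ravel(),
            }
        )

    @classmethod
    def from_long_df(cls, df: pd.DataFrame, grid: BinGrid) -> "CellCNMatrix":
        missing = [c for c in CN_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"copy number table missing columns {missing}")
        df = df.assign(chrom=df["chrom"].astype(str))
        if (df["state"] < 0).any():
            row = int(df.index[df["state"] < 0][0])
            raise ValueError(f"copy number table row {row}: negative state")
        key = _bin_key(grid)
        cells = list(pd.unique(df["cell_id"]))
        n_bins = grid.n_bins
        state = np.zeros((len(cells), n_bins), dtype=np.int64)
        raw = np.full((len(cells), n_bins), np.nan)
        cell_pos = {c: i for i, c in enumerate(cells)}
        bin_idx = df.apply(lambda r: key.get((r["chrom"], int(r["start"]))), axis=1)
        if bin_idx.isna().any():
            row = int(df.index[bin_idx.isna()][0])
            raise ValueError(f"copy number table row {row}: bin not on grid")
        rows = df["cell_id"].map(cell_pos).to_numpy()
        cols = bin_idx.to_numpy(dtype=np.int64)
        state[rows, cols] = df["state"].to_numpy()
        raw[rows, cols] = df["raw_copy"].to_numpy()
        return cls(grid=grid, cells=[str(c) for c in cells], state=state, raw_copy=raw)

    def to_tsv(self, path) -> None:
        self.to_long_df().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, grid: BinGrid) -> "CellCNMatrix":
        return cls.from_long_df(pd.read_csv(path, sep="\t"), grid)


@dataclass
class BlockAlleleCounts:
    """Cells x haplotype blocks (B-count, total count) with phase orientation.

    ``orientation`` is +1/-1 per block; the oriented B count of a flipped
    block is ``t - b``.
    """

    blocks: pd.DataFrame  # chrom, start, end
    cells: list[str]
    b: np.ndarray
    t: np.ndarray
    orientation: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.blocks = self.blocks.reset_index(drop=True)
        self.b = np.asarray(self.b, dtype=np.int64)
        self.t = np.asarray(self.t, dtype=np.int64)
        if self.orientation is None:
            self.orientation = np.ones(len(self.blocks), dtype=np.int8)
        self.orientation = np.asarray(self.orientation, dtype=np.int8)
        if self.b.shape != self.t.shape or self.b.shape != (len(self.cells), len(self.blocks)):
            raise ValueError("allele count arrays must be cells x blocks")
        if (self.b < 0).any() or (self.t < 0).any():
            raise ValueError("negative allele counts")
        if (self.b > self.t).any():
            cell, block = map(int, np.argwhere(self.b > self.t)[0])
            raise ValueError(
                f"b_count > t_count for cell {self.cells[cell]}, block {block}"
            )
        if not np.all(np.isin(self.orientation, [-1, 1])):
            raise ValueError("orientation must be +1/-1")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def oriented_b(self) -> np.ndarray:
        """B counts after applying per-block orientation flips."""
        flip = self.orientation < 0
        out = self.b.copy()
        out[:, flip] = self.t[:, flip] - self.b[:, flip]
        return out

    def to_long_df(self) -> pd.DataFrame:
        n_cells, n_blocks = self.b.shape
        blk = self.blocks
        return pd.DataFrame(
            {
                "cell_id": np.repeat(self.cells, n_blocks),
                "chrom": np.tile(blk["chrom"].to_numpy(), n_cells),
                "start": np.tile(blk["start"].to_numpy(), n_cells),
                "end": np.tile(blk["end"].to_numpy(), n_cells),
                "b_count": self.b.ravel(),
                "t_count": self.t.ravel(),
            }
        )

    @classmethod
    def from_long_df(cls, df: pd.DataFrame) -> "BlockAlleleCounts":
        missing = [c for c in ALLELE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"allele table missing columns {missing}")
        df = df.assign(chrom=df["chrom"].astype(str))
        bad = df["b_count"] > df["t_count"]
        if bad.any():
            row = int(df.index[bad][0])
            raise ValueError(f"allele table row {row}: b_count > t_count")
        blocks = (
            df[["chrom", "start", "end"]]
            .drop_duplicates()
            .sort_values(["chrom", "start"], kind="stable")
            .reset_index(drop=True)
        )
        block_pos = {
            (r.chrom, int(r.start)): i for i, r in enumerate(blocks.itertuples())
        }
        cells = list(pd.unique(df["cell_id"]))
        cell_pos = {c: i for i, c in enumerate(cells)}
        b = np.zeros((len(cells), len(blocks)), dtype=np.int64)
        t = np.zeros_like(b)
        rows = df["cell_id"].map(cell_pos).to_numpy()
        cols = [block_pos[(c, int(s))] for c, s in zip(df["chrom"], df["start"])]
        b[rows, cols] = df["b_count"].to_numpy()
        t[rows, cols] = df["t_count"].to_numpy()
        return cls(blocks=blocks, cells=[str(c) for c in cells], b=b, t=t)

    def to_tsv(self, path) -> None:
        self.to_long_df().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BlockAlleleCounts":
        return cls.from_long_df(pd.read_csv(path, sep="\t"))


def read_qc(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in QC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"QC table missing columns {missing}")
    df["s_phase_flag"] = df["s_phase_flag"].astype(bool)
    return df


def write_qc(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_centromeres(path) -> pd.DataFrame:
    """Centromere coordinates: one (chrom, cent_start, cent_end) per chromosome."""
    df = pd.read_csv(path, sep="\t")
    df["chrom"] = df["chrom"].astype(str)
    if df["chrom"].duplicated().any():
        raise ValueError("centromere table has duplicate chromosomes")
    return df


def read_blacklist_bed(path) -> pd.DataFrame:
    """Read a BED blacklist; converts 0-based half-open to 1-based inclusive."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"]
    )
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"] + 1
    return df


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def filter_bins(grid: BinGrid, blacklist: pd.DataFrame | None = None) -> np.ndarray:
    """Boolean keep-mask over bins.

    Removes bins with mappability <= 0.99 and bins overlapping any blacklist
    interval (1-based inclusive coordinates).  Blacklist intervals on
    chromosomes absent from the grid raise a warning and are ignored.
    """
    keep = grid.bins["mappability"].to_numpy() > MAPPABILITY_MIN
    if blacklist is not None and len(blacklist):
        starts = grid.bins["start"].to_numpy()
        ends = grid.bins["end"].to_numpy()
        chroms = grid.bins["chrom"].to_numpy()
        for row in blacklist.itertuples():
            chrom = str(row.chrom)
            if chrom not in grid._chrom_index:
                warnings.warn(f"blacklist interval on unknown chromosome {chrom}")
                continue
            hit = (chroms == chrom) & (starts <= row.end) & (ends >= row.start)
            keep &= ~hit
    return keep


def filter_cells(qc: pd.DataFrame) -> np.ndarray:
    """Boolean keep-mask over QC rows.

    Keeps cells with quality >= 0.75, no S-phase flag and contamination
    fraction <= 0.05.  Cells with missing quality are dropped with a logged
    reason.
    """
    quality = qc["quality"].to_numpy(dtype=float)
    for i in np.flatnonzero(np.isnan(quality)):
        logger.info("cell %s dropped: missing quality", qc["cell_id"].iloc[i])
    with np.errstate(invalid="ignore"):
        keep = (
            (quality >= QUALITY_MIN)
            & ~qc["s_phase_flag"].to_numpy(dtype=bool)
            & (qc["contam_fraction"].to_numpy(dtype=float) <= CONTAM_MAX)
        )
    keep[np.isnan(quality)] = False
    return keep


def raw_copy_from_reads(
    reads: np.ndarray, ploidy: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Scale per-cell GC-corrected read counts so the unmasked-bin mean equals
    the cell's ploidy."""
    reads = np.asarray(reads, dtype=float)
    means = reads[:, mask].mean(axis=1)
    if np.any(means <= 0):
        raise ValueError("cell with zero mean read count; cannot normalize")
    return reads * (np.asarray(ploidy, dtype=float) / means)[:, None]


# ---------------------------------------------------------------------------
# Convenience bundles
# ---------------------------------------------------------------------------


def read_tables(grid_path, cn_path, allele_path, qc_path):
    """Read the four core tables; returns (BinGrid, CellCNMatrix,
    BlockAlleleCounts, qc DataFrame)."""
    grid = BinGrid.from_tsv(grid_path)
    cn = CellCNMatrix.from_tsv(cn_path, grid)
    alleles = BlockAlleleCounts.from_tsv(allele_path)
    qc = read_qc(qc_path)
    return grid, cn, alleles, qc


def _bin_key(grid: BinGrid) -> dict:
    return {
        (r.chrom, int(r.start)): i for i, r in enumerate(grid.bins.itertuples())
    }
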