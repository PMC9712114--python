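"""Seeded generator of clone-structured single-cell populations.

Emulates shallow single-cell WGS readouts with known haplotype-specific
ground truth: clone-level gains/losses at whole-chromosome, arm and segment
scale, whole-genome doubling, high-level amplifications with cell-to-cell
amplitude jitter, parallel events on opposite haplotypes, serrate (jittered)
breakpoints, negative-binomial bin read counts and Beta-Binomial block allele
counts with randomized block polarity and phase-switch errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import betabinom

from .core_io import (
    BinGrid,
    BlockAlleleCounts,
    CellCNMatrix,
    raw_copy_from_reads,
)
from .cn_metrics import cell_ploidies


@dataclass
class HlampSpec:
    """A high-level amplification locus: integer state ``copies`` on one
    haplotype for the carrier clone, with per-cell lognormal amplitude jitter
    affecting read depth."""

    chrom: str
    bin: int  # bin index within the chromosome
    copies: int = 12
    clone: int | None = None  # None -> all cells
    jitter_sd: float = 0.3
    haplotype: str = "a"


@dataclass
class CloneEventSpec:
    """An explicit clone-level haplotype-specific event (deterministic, in
    addition to the randomly sampled event menu)."""

    chrom: str
    start_bin: int
    end_bin: int
    clone: int = 0
    haplotype: str = "a"
    delta: int = -1


@dataclass
class ParallelSpec:
    """A parallel event: independent cell subsets altered on haplotype A and
    on haplotype B over the same segment."""

    chrom: str
    start_bin: int
    end_bin: int
    direction: str = "loss"  # or "gain"
    frac_a: float = 0.02
    frac_b: float = 0.03


@dataclass
class SerrateSpec:
    """A clone-level breakpoint whose per-cell position is jittered around the
    modal bin with a signed geometric offset (smaller ``p`` -> more serrate)."""

    chrom: str
    boundary_bin: int  # first bin of the altered right-hand side (modal)
    clone: int = 0
    haplotype: str = "a"
    delta: int = 1
    p: float = 0.7


@dataclass
class SimConfig:
    """Study conditions of the simulated population.

    Defaults describe a 200-cell population on two 50 Mb chromosomes of
    500-kb bins, with ~100 reads per diploid bin and ~20 allele-informative
    counts per bin at Beta-Binomial concentration 50.
    """

    n_cells: int = 200
    n_chromosomes: int = 2
    bins_per_chromosome: int = 100
    bin_width: int = 500_000
    n_clones: int = 2
    clone_fractions: list[float] | None = None
    # event menu (rates are Poisson means per clone lineage)
    whole_chrom_rate: float = 0.3
    arm_rate: float = 0.3
    segment_rate: float = 1.0
    cell_event_rate: float = 0.0  # private events per cell
    wgd_prob: float = 0.0
    clone_events: list[CloneEventSpec] = field(default_factory=list)
    hlamp_loci: list[HlampSpec] = field(default_factory=list)
    parallel_events: list[ParallelSpec] = field(default_factory=list)
    serrate_events: list[SerrateSpec] = field(default_factory=list)
    # readout
    reads_per_copy: float = 50.0
    nb_dispersion: float = 10.0
    blocks_per_bin: int = 2
    allele_thinning: float = 0.2  # fraction of bin reads that are allele-informative
    bb_concentration: float = 50.0
    phase_switch_prob: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clone_fractions is None:
            self.clone_fractions = [1.0 / self.n_clones] * self.n_clones
        if abs(sum(self.clone_fractions) - 1.0) > 1e-9:
            raise ValueError("clone fractions must sum to 1")


@dataclass
class GroundTruth:
    """Per-cell per-bin true haplotype states plus the event registry."""

    a: np.ndarray
    b: np.ndarray
    clones: dict[str, str]
    events: pd.DataFrame
    block_polarity: np.ndarray  # true +/-1 polarity per block
    tree_newick: str
    seed: int

    @property
    def total(self) -> np.ndarray:
        return self.a + self.b


@dataclass
class SimResult:
    grid: BinGrid
    cn: CellCNMatrix
    alleles: BlockAlleleCounts
    qc: pd.DataFrame
    truth: GroundTruth
    reads: np.ndarray | None = None  # raw negative-binomial bin read counts


def _apply_event(a, b, bins, hap, delta, registry, kind, chrom, who):
    """Apply +/-delta to one haplotype over bins with floor at 0; skipped when
    a loss would go below zero everywhere it applies."""
    target = a if hap == "a" else b
    if delta < 0 and np.all(target[bins] == 0):
        registry.append((kind, chrom, int(bins[0]), int(bins[-1]), hap, delta, who, "skipped"))
        return
    target[bins] = np.maximum(target[bins] + delta, 0)
    registry.append((kind, chrom, int(bins[0]), int(bins[-1]), hap, delta, who, "applied"))


def simulate_population(config: SimConfig) -> SimResult:
    """Generate a clone-structured population; fully reproducible by seed."""
    rng = np.random.default_rng(config.seed)
    grid = BinGrid.uniform(
        config.n_chromosomes, config.bins_per_chromosome, config.bin_width
    )
    n_bins = grid.n_bins
    n_cells = config.n_cells
    registry: list[tuple] = []

    # --- clone genotypes ------------------------------------------------
    clone_a = np.ones((config.n_clones, n_bins), dtype=np.int64)
    clone_b = np.ones((config.n_clones, n_bins), dtype=np.int64)
    if rng.random() < config.wgd_prob:
        clone_a *= 2
        clone_b *= 2
        registry.append(("wgd", "*", 0, n_bins - 1, "ab", 2, "root", "applied"))
    for k in range(1, config.n_clones):
        parent = int(rng.integers(0, k))
        clone_a[k] = clone_a[parent].copy()
        clone_b[k] = clone_b[parent].copy()
        for kind, rate in (
            ("whole_chromosome", config.whole_chrom_rate),
            ("arm", config.arm_rate),
            ("segment", config.segment_rate),
        ):
            for _ in range(rng.poisson(rate)):
                chrom = str(int(rng.integers(1, config.n_chromosomes + 1)))
                bins = grid.chrom_bins(chrom)
                if kind == "arm":
                    mid = len(bins) // 2
                    bins = bins[:mid] if rng.random() < 0.5 else bins[mid:]
                elif kind == "segment":
                    w = min(int(rng.integers(8, 30)), len(bins))
                    s = int(rng.integers(0, max(1, len(bins) - w + 1)))
                    bins = bins[s : s + w]
                hap = "a" if rng.random() < 0.5 else "b"
                delta = 1 if rng.random() < 0.5 else -1
                _apply_event(
                    clone_a[k], clone_b[k], bins, hap, delta, registry, kind, chrom, f"clone{k}"
                )

    for ev in config.clone_events:
        bins = grid.chrom_bins(ev.chrom)[ev.start_bin : ev.end_bin + 1]
        _apply_event(
            clone_a[ev.clone], clone_b[ev.clone], bins, ev.haplotype, ev.delta,
            registry, "clone_event", ev.chrom, f"clone{ev.clone}",
        )

    # --- cells ----------------------------------------------------------
    clone_of = rng.choice(config.n_clones, size=n_cells, p=config.clone_fractions)
    cells = [f"cell{i:04d}" for i in range(n_cells)]
    a = clone_a[clone_of].copy()
    b = clone_b[clone_of].copy()

    for i in range(n_cells):
        for _ in range(rng.poisson(config.cell_event_rate)):
            chrom = str(int(rng.integers(1, config.n_chromosomes + 1)))
            bins = grid.chrom_bins(chrom)
            w = min(int(rng.integers(8, 30)), len(bins))
            s = int(rng.integers(0, max(1, len(bins) - w + 1)))
            hap = "a" if rng.random() < 0.5 else "b"
            delta = 1 if rng.random() < 0.5 else -1
            _apply_event(
                a[i], b[i], bins[s : s + w], hap, delta, registry, "private", chrom, cells[i]
            )

    for ev in config.parallel_events:
        bins = grid.chrom_bins(ev.chrom)[ev.start_bin : ev.end_bin + 1]
        delta = 1 if ev.direction == "gain" else -1
        n_a = int(round(ev.frac_a * n_cells))
        n_b = int(round(ev.frac_b * n_cells))
        chosen = rng.choice(n_cells, size=n_a + n_b, replace=False)
        for i in chosen[:n_a]:
            _apply_event(a[i], b[i], bins, "a", delta, registry, "parallel", ev.chrom, cells[i])
        for i in chosen[n_a:]:
            _apply_event(a[i], b[i], bins, "b", delta, registry, "parallel", ev.chrom, cells[i])

    for ev in config.serrate_events:
        bins = grid.chrom_bins(ev.chrom)
        members = np.flatnonzero(clone_of == ev.clone)
        offsets = (rng.geometric(ev.p, size=len(members)) - 1) * rng.choice(
            [-1, 1], size=len(members)
        )
        for i, off in zip(members, offsets):
            start = int(np.clip(ev.boundary_bin + off, 1, len(bins) - 1))
            _apply_event(
                a[i], b[i], bins[start:], ev.haplotype, ev.delta, registry,
                "serrate", ev.chrom, cells[i],
            )

    # amplitude matrix for read generation (HLAMP jitter enters here)
    amp = (a + b).astype(float)
    for ev in config.hlamp_loci:
        bin_idx = grid.chrom_bins(ev.chrom)[ev.bin]
        carriers = (
            np.arange(n_cells) if ev.clone is None else np.flatnonzero(clone_of == ev.clone)
        )
        target = a if ev.haplotype == "a" else b
        other = b if ev.haplotype == "a" else a
        target[carriers, bin_idx] = ev.copies
        jitter = rng.lognormal(mean=0.0, sigma=ev.jitter_sd, size=len(carriers))
        amp[carriers, bin_idx] = other[carriers, bin_idx] + ev.copies * jitter
        amp[carriers, bin_idx] = np.maximum(amp[carriers, bin_idx], 0.0)
        for i in carriers:
            registry.append(
                ("hlamp", ev.chrom, int(bin_idx), int(bin_idx), ev.haplotype, ev.copies,
                 cells[int(i)], "applied")
            )
    amp[(a + b) > 0] = np.maximum(amp[(a + b) > 0], 1e-9)

    # --- readouts ---------------------------------------------------------
    mu = config.reads_per_copy * amp
    r = config.nb_dispersion
    with np.errstate(divide="ignore", invalid="ignore"):
        p_nb = np.where(mu > 0, r / (r + mu), 1.0)
    reads = np.where(mu > 0, rng.negative_binomial(r, np.clip(p_nb, 1e-12, 1.0)), 0)

    state = a + b
    cn = CellCNMatrix(
        grid=grid, cells=cells, state=state, raw_copy=np.zeros_like(state, dtype=float)
    )
    ploidy = cell_ploidies(cn)
    safe_reads = np.maximum(reads, 0)
    if np.all(safe_reads.sum(axis=1) > 0):
        cn.raw_copy = raw_copy_from_reads(safe_reads + 1e-9, ploidy, cn.mask)

    # blocks: subdivide each bin
    blk_rows = []
    bw = config.bin_width // config.blocks_per_bin
    for bi, row in enumerate(grid.bins.itertuples()):
        for j in range(config.blocks_per_bin):
            s = row.start + j * bw
            e = min(row.start + (j + 1) * bw - 1, row.end)
            blk_rows.append((row.chrom, s, e, bi))
    blocks = pd.DataFrame(blk_rows, columns=["chrom", "start", "end", "bin"])
    n_blocks = len(blocks)
    bin_of_block = blocks["bin"].to_numpy()
    t_counts = rng.binomial(
        reads[:, bin_of_block], config.allele_thinning / config.blocks_per_bin
    )
    total = state[:, bin_of_block]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu_b = np.where(total > 0, b[:, bin_of_block] / np.where(total > 0, total, 1), 0.5)
    s_conc = config.bb_concentration
    b_counts = np.zeros_like(t_counts)
    mid = (mu_b > 0) & (mu_b < 1) & (t_counts > 0)
    if mid.any():
        b_counts[mid] = betabinom.rvs(
            t_counts[mid],
            mu_b[mid] * s_conc,
            (1.0 - mu_b[mid]) * s_conc,
            random_state=np.random.RandomState(rng.integers(0, 2**31 - 1)),
        )
    b_counts[mu_b >= 1] = t_counts[mu_b >= 1]
    # polarity: which parental haplotype the block's counted allele tracks
    polarity = rng.choice(np.array([1, -1], dtype=np.int8), size=n_blocks)
    switch = rng.random((n_cells, n_blocks)) < config.phase_switch_prob
    eff = polarity[None, :] * np.where(switch, -1, 1)
    b_emit = np.where(eff > 0, b_counts, t_counts - b_counts)
    alleles = BlockAlleleCounts(
        blocks=blocks[["chrom", "start", "end"]].copy(),
        cells=cells,
        b=b_emit,
        t=t_counts,
    )

    qc = pd.DataFrame(
        {
            "cell_id": cells,
            "quality": 1.0,
            "s_phase_flag": False,
            "contam_fraction": 0.0,
            "clone": [f"clone{k}" for k in clone_of],
        }
    )
    tree = _population_newick(cells, clone_of, config.n_clones)
    truth = GroundTruth(
        a=a,
        b=b,
        clones={c: f"clone{k}" for c, k in zip(cells, clone_of)},
        events=pd.DataFrame(
            registry,
            columns=["kind", "chrom", "start_bin", "end_bin", "haplotype", "delta", "who", "status"],
        ),
        block_polarity=polarity,
        tree_newick=tree,
        seed=config.seed,
    )
    return SimResult(grid=grid, cn=cn, alleles=alleles, qc=qc, truth=truth, reads=reads)


def _population_newick(cells, clone_of, n_clones) -> str:
    clades = []
    for k in range(n_clones):
        members = [cells[i] for i in np.flatnonzero(clone_of == k)]
        if not members:
            continue
        if len(members) == 1:
            clades.append(f"{members[0]}:2")
        else:
            inner = ",".join(f"{m}:1" for m in members)
            clades.append(f"({inner})clone{k}:1")
    return f"({','.join(clades)})root;"


def simulate_rna_counts(
    truth: GroundTruth,
    grid: BinGrid,
    snps_per_bin: int = 2,
    depth: float = 1.5,
    seed: int = 1,
) -> pd.DataFrame:
    """Phased scRNA-like SNP counts drawn from the DNA ground truth.

    Expression-derived allele counts per SNP: total ~ Poisson(depth), B count
    ~ Binomial(total, b / (a + b)) of the containing bin.  Counts are emitted
    already phased (B tracks the true B haplotype), mirroring phasing carried
    over from scDNA-seq.
    """
    rng = np.random.default_rng(seed)
    n_cells, n_bins = truth.a.shape
    rows = []
    starts = grid.bins["start"].to_numpy()
    ends = grid.bins["end"].to_numpy()
    chroms = grid.bins["chrom"].to_numpy()
    cells = list(truth.clones.keys())
    for bi in range(n_bins):
        pos = np.linspace(starts[bi], ends[bi], snps_per_bin + 2)[1:-1].astype(int)
        for pp in pos:
            t = rng.poisson(depth, size=n_cells)
            tot = truth.a[:, bi] + truth.b[:, bi]
            with np.errstate(divide="ignore", invalid="ignore"):
                mu = np.where(tot > 0, truth.b[:, bi] / np.where(tot > 0, tot, 1), 0.5)
            t = np.where(tot > 0, t, 0)
            bb = rng.binomial(t, mu)
            nz = t > 0
            for ci in np.flatnonzero(nz):
                rows.append((cells[ci], chroms[bi], int(pp), int(bb[ci]), int(t[ci]), bi))
    return pd.DataFrame(
        rows, columns=["cell_id", "chrom", "pos", "allele_b_count", "total_count", "block_id"]
    )


# ---------------------------------------------------------------------------
# Accuracy against ground truth
# ---------------------------------------------------------------------------


def truth_metrics(hscn, truth: GroundTruth) -> dict[str, float]:
    """Bin-level state accuracy and segment-level LOH precision/recall.

    Accuracy allows a global A/B relabel per chromosome (phasing is defined up
    to that symmetry).  LOH calls are evaluated on the disjoint clone-consensus
    segmentation with modal genotypes per cell per segment (the unit at which
    segment calls are compared across cells): a call is LOH when the modal
    minor-allele copy is zero and the modal total is positive.
    """
    from .cn_metrics import clone_segmentations, consensus_profile, disjoin_and_genotype
    from .hscn_hmm import HSCNMatrix

    grid = hscn.grid
    correct = 0
    total_bins = 0
    for chrom in grid.chroms:
        bins = grid.chrom_bins(chrom)
        same = (hscn.a[:, bins] == truth.a[:, bins]) & (hscn.b[:, bins] == truth.b[:, bins])
        swap = (hscn.a[:, bins] == truth.b[:, bins]) & (hscn.b[:, bins] == truth.a[:, bins])
        correct += max(same.sum(), swap.sum())
        total_bins += same.size
    cells = list(hscn.cells)
    cn_inf = CellCNMatrix(
        grid=grid, cells=cells, state=hscn.a + hscn.b,
        raw_copy=np.full(hscn.a.shape, np.nan), mask=hscn.mask,
    )
    consensus = consensus_profile(cn_inf, truth.clones, hscn)
    segs = clone_segmentations(consensus, grid)
    st_inf = disjoin_and_genotype(segs, cn_inf, hscn)
    hscn_true = HSCNMatrix(
        grid=grid, cells=cells, a=truth.a, b=truth.b,
        baf=np.full(truth.a.shape, np.nan), posterior=np.ones(truth.a.shape),
        mask=hscn.mask,
    )
    cn_true = CellCNMatrix(
        grid=grid, cells=cells, state=truth.total,
        raw_copy=np.full(truth.a.shape, np.nan), mask=hscn.mask,
    )
    st_true = disjoin_and_genotype(segs, cn_true, hscn_true)
    loh_inf = (np.minimum(st_inf.a, st_inf.b) == 0) & (st_inf.total > 0)
    loh_true = (np.minimum(st_true.a, st_true.b) == 0) & (st_true.total > 0)
    tp = int((loh_inf & loh_true).sum())
    fp = int((loh_inf & ~loh_true).sum())
    fn = int((~loh_inf & loh_true).sum())
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return {
        "bin_accuracy": correct / total_bins,
        "loh_precision": precision,
        "loh_recall": recall,
    }
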