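"""Serriform structural variation (SSV) scoring.

Cell-to-cell variation in the genomic position of a shared copy-number
breakpoint produces serrate edges in single-cell heat maps.  This module
matches per-cell segments to clone-consensus segments, filters noisy cells at
each breakpoint and scores each clone-level breakpoint by the fraction of
cells whose breakpoint position is rare (< 5% of event cells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import BinGrid, CellCNMatrix
from .cn_metrics import ConsensusProfile, cell_ploidies, segment_bins

logger = logging.getLogger(__name__)

RARE_FRACTION = 0.05  # strictly below this frequency a position is rare
MIN_EVENT_CELLS = 100
MIN_ADJACENT_SPAN = 20_000_000  # summed span of the two flanking segments
NOISE_WINDOW = 5  # bins each side of the breakpoint
SERRATION_THRESHOLD = 0.15


def normalize_to_clone_ploidy(
    states: np.ndarray, cell_ploidy: float, clone_ploidy: float
) -> np.ndarray:
    """Rescale a cell's states onto its clone's ploidy (real-valued)."""
    if cell_ploidy == 0:
        raise ValueError("cell ploidy 0; cannot normalize")
    return np.asarray(states, dtype=float) * clone_ploidy / cell_ploidy


def _classify(state: float, left: float | None, right: float | None) -> str:
    """Relation of a segment state to its neighbours: min/max/intermediate.
    Terminal segments (one neighbour) use the one-sided rule."""
    neigh = [x for x in (left, right) if x is not None]
    if all(state < x for x in neigh):
        return "min"
    if all(state > x for x in neigh):
        return "max"
    if len(neigh) == 2 and min(neigh) < state < max(neigh):
        return "mid"
    return "other"


def _compatible(cell_state: float, left: float | None, right: float | None, cls: str) -> bool:
    neigh = [x for x in (left, right) if x is not None]
    if cls == "min":
        return all(cell_state < x for x in neigh)
    if cls == "max":
        return all(cell_state > x for x in neigh)
    if cls == "mid":
        return min(neigh) < cell_state < max(neigh)
    return False


def match_cell_segments(
    cell_segments: list[tuple],
    clone_segments: list[tuple],
    cell_states_norm: list[float],
) -> list[int | None]:
    """Assign each cell segment to a compatible clone segment.

    Segments are (start_bin, end_bin, state) on one chromosome.  A cell
    segment (its state ploidy-normalized, real valued) is compatible with a
    clone segment when it stands in the same relation to the clone segment's
    neighbour states as the clone segment itself (below both / above both /
    strictly between).  Assignment goes to the compatible segment with
    maximal bin overlap, ties to the leftmost.  Returns the clone-segment
    index per cell segment, None when unmatched.
    """
    cls = []
    for k, (_, _, state) in enumerate(clone_segments):
        left = clone_segments[k - 1][2] if k > 0 else None
        right = clone_segments[k + 1][2] if k < len(clone_segments) - 1 else None
        cls.append((_classify(state, left, right), left, right))
    out: list[int | None] = []
    for (cs, ce, _), state in zip(cell_segments, cell_states_norm):
        best, best_ov = None, 0
        for k, (ks, ke, _) in enumerate(clone_segments):
            c, left, right = cls[k]
            if not _compatible(state, left, right, c):
                continue
            ov = min(ce, ke) - max(cs, ks) + 1
            if ov > best_ov:
                best, best_ov = k, ov
        out.append(best)
    return out


@dataclass
class BreakpointEvent:
    """One clone-level breakpoint with its matched cell breakpoints."""

    event_id: str
    clone: str
    chrom: str
    position: int  # first bin of the right-hand consensus segment
    adjacent_span: int  # summed bp span of the two flanking consensus segments
    cell_ids: list[str]
    positions: np.ndarray  # matched breakpoint bin per cell
    noise: np.ndarray = field(default=None)  # type: ignore[assignment]
    retained: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def eligible(self) -> bool:
        return self.n_cells >= MIN_EVENT_CELLS and self.adjacent_span >= MIN_ADJACENT_SPAN


def find_breakpoint_events(
    cn: CellCNMatrix,
    clones: dict[str, str],
    consensus: ConsensusProfile,
) -> list[BreakpointEvent]:
    """Clone-consensus breakpoints with matched cell breakpoint positions.

    Cell states are normalized to the clone ploidy before compatibility
    matching; a cell carries a breakpoint when it has segments matched to
    both flanking consensus segments, its position being the first bin of the
    segment matched on the right.
    """
    grid = cn.grid
    ploidies = cell_ploidies(cn)
    lengths = grid.bin_lengths
    events: list[BreakpointEvent] = []
    for clone in consensus.groups:
        gi = consensus.group_index(clone)
        clone_ploidy = consensus.ploidy(clone)
        members = [i for i, c in enumerate(cn.cells) if clones.get(c) == clone]
        for chrom in grid.chroms:
            bins = grid.chrom_bins(chrom)
            clone_segs = segment_bins(consensus.state[gi], bins, cn.mask)
            if len(clone_segs) < 2:
                continue
            # per-cell matching on this chromosome
            cell_match: dict[int, tuple[list[tuple], list[int | None]]] = {}
            for ci in members:
                segs = segment_bins(cn.state[ci], bins, cn.mask)
                norm = [
                    float(
                        normalize_to_clone_ploidy(
                            np.array([s]), ploidies[ci], clone_ploidy
                        )[0]
                    )
                    for _, _, s in segs
                ]
                cell_match[ci] = (segs, match_cell_segments(segs, clone_segs, norm))
            for k in range(len(clone_segs) - 1):
                pos = clone_segs[k + 1][0]
                span = int(
                    lengths[clone_segs[k][0] : clone_segs[k][1] + 1].sum()
                    + lengths[clone_segs[k + 1][0] : clone_segs[k + 1][1] + 1].sum()
                )
                ids, positions = [], []
                for ci in members:
                    segs, match = cell_match[ci]
                    left_ok = any(m == k for m in match)
                    right = [
                        (min(e, clone_segs[k + 1][1]) - max(s, clone_segs[k + 1][0]) + 1, s)
                        for (s, e, _), m in zip(segs, match)
                        if m == k + 1
                    ]
                    if not left_ok or not right:
                        continue
                    ids.append(cn.cells[ci])
                    positions.append(max(right)[1])  # largest-overlap segment's start
                if ids:
                    events.append(
                        BreakpointEvent(
                            event_id=f"{clone}:{chrom}:{pos}",
                            clone=clone,
                            chrom=chrom,
                            position=pos,
                            adjacent_span=span,
                            cell_ids=ids,
                            positions=np.array(positions, dtype=np.int64),
                        )
                    )
    return events


def breakpoint_noise_filter(
    event: BreakpointEvent, cn: CellCNMatrix, window: int = NOISE_WINDOW
) -> BreakpointEvent:
    """Remove cells whose local raw-copy noise exceeds the stable-cell mean.

    Noise per cell is the mean |raw_copy - integer state| over up to
    ``window`` unmasked bins on each side of the cell's breakpoint (clipped at
    chromosome ends).  Stable cells are those whose breakpoint equals the
    clone-level position; the threshold is their mean noise.
    """
    grid = cn.grid
    bins = grid.chrom_bins(event.chrom)
    um = bins[cn.mask[bins]]
    noise = np.zeros(event.n_cells)
    for i, (cell, pos) in enumerate(zip(event.cell_ids, event.positions)):
        ci = cn.cells.index(cell)
        at = int(np.searchsorted(um, pos))
        lo = max(0, at - window)
        hi = min(len(um), at + window)
        sel = um[lo:hi]
        vals = cn.raw_copy[ci, sel] - cn.state[ci, sel]
        vals = vals[np.isfinite(vals)]
        noise[i] = float(np.abs(vals).mean()) if len(vals) else 0.0
    stable = event.positions == event.position
    if not stable.any():
        logger.info("event %s has no stable cells; skipped", event.event_id)
        event.noise = noise
        event.retained = np.zeros(event.n_cells, dtype=bool)
        return event
    threshold = noise[stable].mean()
    event.noise = noise
    event.retained = noise <= threshold
    return event


def serration_score(event: BreakpointEvent) -> float:
    """Fraction of retained cells whose breakpoint position is rare.

    A position is rare when it occurs in strictly less than 5% of retained
    cells.  Undefined (NaN) with fewer than 2 retained cells.
    """
    if event.retained is None:
        raise ValueError("apply breakpoint_noise_filter first")
    pos = event.positions[event.retained]
    if len(pos) < 2:
        logger.info("event %s has <2 retained cells; score undefined", event.event_id)
        return float("nan")
    _, inv, counts = np.unique(pos, return_inverse=True, return_counts=True)
    freq = counts[inv] / len(pos)
    return float((freq < RARE_FRACTION).mean())


def score_breakpoints(
    cn: CellCNMatrix,
    clones: dict[str, str],
    consensus: ConsensusProfile,
    window: int = NOISE_WINDOW,
) -> pd.DataFrame:
    """End-to-end SSV scoring: events, noise filter and per-event scores."""
    rows = []
    for ev in find_breakpoint_events(cn, clones, consensus):
        ev = breakpoint_noise_filter(ev, cn, window=window)
        score = serration_score(ev)
        rows.append(
            (
                ev.event_id,
                ev.clone,
                ev.chrom,
                ev.position,
                ev.n_cells,
                int(ev.retained.sum()),
                ev.adjacent_span,
                score,
                ev.eligible,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "clone",
            "chrom",
            "position",
            "n_cells",
            "n_retained",
            "adjacent_span",
            "score",
            "eligible",
        ],
    )


def serration_summary(
    events: pd.DataFrame, threshold: float = SERRATION_THRESHOLD
) -> dict[str, float]:
    """Distribution summary over eligible events only."""
    elig = events[events["eligible"] & events["score"].notna()]
    if len(elig) == 0:
        return {"n_eligible": 0, "mean_score": float("nan"), "frac_above": float("nan")}
    return {
        "n_eligible": int(len(elig)),
        "mean_score": float(elig["score"].mean()),
        "frac_above": float((elig["score"] >= threshold).mean()),
    }
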