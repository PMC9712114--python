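import numpy as np
import pandas as pd
import pytest

from hapcells.core_io import BinGrid, CellCNMatrix


@pytest.fixture
def small_grid() -> BinGrid:
    """Two chromosomes of 10 bins each, 500 kb wide, fully mappable."""
    return BinGrid.uniform(n_chromosomes=2, bins_per_chromosome=10)


@pytest.fixture
def diploid_cn(small_grid) -> CellCNMatrix:
    n_cells = 4
    state = np.full((n_cells, small_grid.n_bins), 2, dtype=int)
    raw = state.astype(float)
    return CellCNMatrix(
        grid=small_grid,
        cells=[f"c{i}" for i in range(n_cells)],
        state=state,
        raw_copy=raw,
    )


def _make_cn(grid, states, raw=None, mask=None):
    states = np.asarray(states)
    if raw is None:
        raw = states.astype(float)
    return CellCNMatrix(
        grid=grid,
        cells=[f"c{i}" for i in range(states.shape[0])],
        state=states,
        raw_copy=np.asarray(raw, dtype=float),
        mask=mask,
    )


@pytest.fixture
def make_cn():
    """Factory building a CellCNMatrix from a states array."""
    return _make_cn


@pytest.fixture
def qc_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": ["c0", "c1", "c2", "c3"],
            "quality": [0.9, 0.75, 0.74, 0.9],
            "s_phase_flag": [False, False, False, True],
            "contam_fraction": [0.0, 0.05, 0.0, 0.0],
            "clone": ["A", "A", "B", "B"],
        }
    )
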