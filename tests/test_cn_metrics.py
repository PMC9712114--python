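"""Ploidy, consensus, missegregation, gain/loss segments and HLAMP metrics."""

import math

import numpy as np
import pandas as pd
import pytest

from hapcells.cn_metrics import (
    call_gain_loss_segments,
    cell_ploidies,
    cell_ploidy,
    clone_amplitude_ratio,
    cluster_hlamp_features,
    consensus_profile,
    detect_hlamp_bins,
    detect_missegregations,
    disjoin_and_genotype,
    gain_loss_ratio,
    hlamp_copy_variance,
    hlamp_feature_vector,
)
from hapcells.hscn_hmm import HSCNMatrix


def hscn_from(grid, a, b):
    a = np.asarray(a)
    return HSCNMatrix(
        grid=grid,
        cells=[f"c{i}" for i in range(a.shape[0])],
        a=a,
        b=np.asarray(b),
        baf=np.full(a.shape, np.nan),
        posterior=np.ones(a.shape),
    )


class TestPloidy:
    @pytest.mark.parametrize(
        "states,expected",
        [
            ([2] * 6 + [3] * 4, 2),  # plain mode
            ([2] * 5 + [4] * 5, 2),  # tie resolves to the smaller state
            ([4] * 10, 4),  # polyploid cell
        ],
    )
    def test_modal_state(self, states, expected):
        mask = np.ones(len(states), dtype=bool)
        assert cell_ploidy(np.array(states), mask) == expected

    def test_all_masked_raises(self):
        with pytest.raises(ValueError, match="masked"):
            cell_ploidy(np.array([2, 2]), np.zeros(2, dtype=bool))


class TestConsensus:
    def test_mode_median_and_hscn_mode(self, small_grid, make_cn):
        states = np.array([[2] * 20, [2] * 20, [3] * 20])
        raw = np.array([[0.2] * 20, [0.4] * 20, [np.nan] * 20])
        cn = make_cn(small_grid, states, raw=raw)
        a = np.array([[2] * 20, [2] * 20, [1] * 20])
        b = np.array([[1] * 20, [1] * 20, [2] * 20])
        hscn = hscn_from(small_grid, a, b)
        clones = {"c0": "X", "c1": "X", "c2": "X"}
        cons = consensus_profile(cn, clones, hscn)
        assert cons.state[0, 0] == 2  # mode of {2,2,3}
        assert cons.copy[0, 0] == pytest.approx(0.3)  # median of {0.2, 0.4}
        assert (cons.a[0, 0], cons.b[0, 0]) == (2, 1)  # mode of {(2,1)x2,(1,2)}

    def test_empty_group_dropped(self, small_grid, make_cn):
        cn = make_cn(small_grid, np.full((2, 20), 2))
        cons = consensus_profile(cn, {"c0": "X", "c1": "X"})
        assert cons.groups == ["X"]


class TestMissegregation:
    def test_75_percent_rule_boundaries(self, make_cn):
        from hapcells.core_io import BinGrid

        grid = BinGrid.uniform(2, 100)
        cells = np.full((10, 200), 2)  # enough normal cells to anchor the consensus
        cells[1, :80] = 3  # 80% of chr1 at offset +1 -> event
        cells[2, :74] = 3  # 74% -> no event
        cells[3, :75] = 3  # exactly 75% -> event
        cn = make_cn(grid, cells)
        clones = {f"c{i}": "X" for i in range(10)}
        cons = consensus_profile(cn, clones)
        events = detect_missegregations(cn, clones, cons)
        assert set(events["cell_id"]) == {"c1", "c3"}
        assert (events["offset"] == 1).all()

    def test_tetraploid_cell_normalized_to_diploid_clone(self, make_cn):
        from hapcells.core_io import BinGrid

        grid = BinGrid.uniform(2, 20)
        states = np.full((4, 40), 2)
        states[3] = 4  # uniformly tetraploid cell in a diploid clone
        cn = make_cn(grid, states)
        clones = {f"c{i}": "X" for i in range(4)}
        cons = consensus_profile(cn, clones)
        events = detect_missegregations(cn, clones, cons)
        assert len(events) == 0  # normalization removes the offset entirely


class TestGainLossSegments:
    def test_span_boundary_3_vs_4_bins(self, make_cn):
        from hapcells.core_io import BinGrid

        grid = BinGrid.uniform(1, 20)
        states = np.full(20, 2)
        states[0:3] = 3  # 1.5 Mb -> discarded
        states[10:14] = 3  # 2.0 Mb -> kept
        segs = call_gain_loss_segments(states, 2, grid, np.ones(20, dtype=bool))
        assert len(segs) == 1
        assert segs.iloc[0]["label"] == "gain"
        assert segs.iloc[0]["span"] == 2_000_000

    def test_flat_profile_empty(self, small_grid):
        segs = call_gain_loss_segments(
            np.full(20, 2), 2, small_grid, np.ones(20, dtype=bool)
        )
        assert len(segs) == 0

    def test_invariant_to_masked_bins_inside_run(self, make_cn):
        from hapcells.core_io import BinGrid

        grid = BinGrid.uniform(1, 20)
        states = np.full(20, 2)
        states[5:12] = 1
        mask_all = np.ones(20, dtype=bool)
        mask_holes = mask_all.copy()
        mask_holes[[7, 8]] = False
        # the masked variant sees the same loss run minus the masked bins
        a = call_gain_loss_segments(states, 2, grid, mask_all)
        states2 = states.copy()
        states2[[7, 8]] = 9  # garbage under the mask must not matter
        b = call_gain_loss_segments(states2, 2, grid, mask_holes)
        assert len(a) == len(b) == 1
        assert a.iloc[0]["label"] == b.iloc[0]["label"] == "loss"

    @pytest.mark.parametrize(
        "labels,expected",
        [
            (["gain"] * 4 + ["loss"] * 2, 2.0),
            ([], math.nan),
            (["gain"] * 5, math.inf),
        ],
    )
    def test_gain_loss_ratio(self, labels, expected):
        segs = pd.DataFrame({"label": labels})
        ratio, _, _ = gain_loss_ratio(segs)
        if math.isnan(expected):
            assert math.isnan(ratio)
        else:
            assert ratio == expected


class TestHlamp:
    def test_cell_count_boundary(self, small_grid, make_cn):
        raw = np.full((12, 20), 2.0)
        raw[:10, 0] = 10.2  # 10 cells at >= 10 -> HLAMP
        raw[:9, 1] = 10.2  # 9 cells -> not
        cn = make_cn(small_grid, np.full((12, 20), 2), raw=raw)
        hl = detect_hlamp_bins(cn)
        assert hl[0] and not hl[1]
        assert hl.sum() == 1

    def test_all_diploid_no_hlamp(self, small_grid, make_cn):
        cn = make_cn(small_grid, np.full((12, 20), 2))
        assert detect_hlamp_bins(cn).sum() == 0

    def test_variance_zero_after_clone_centering(self, small_grid, make_cn):
        # two clones with different means but no within-clone spread
        raw = np.r_[np.full((5, 20), 10.0), np.full((5, 20), 14.0)]
        cn = make_cn(small_grid, np.full((10, 20), 2), raw=raw)
        clones = {f"c{i}": ("A" if i < 5 else "B") for i in range(10)}
        hl = np.zeros(20, dtype=bool)
        hl[0] = True
        table, mean_var = hlamp_copy_variance(cn, np.full(10, 2), clones, hl)
        assert mean_var == pytest.approx(0.0)

    def test_variance_invariant_to_ploidy_scaling(self, small_grid, make_cn):
        rng = np.random.default_rng(0)
        raw = rng.uniform(8, 16, size=(20, 20))
        cn1 = make_cn(small_grid, np.full((20, 20), 2), raw=raw)
        cn2 = make_cn(small_grid, np.full((20, 20), 4), raw=2 * raw)
        clones = {f"c{i}": "A" for i in range(20)}
        hl = np.ones(20, dtype=bool)
        _, v1 = hlamp_copy_variance(cn1, np.full(20, 2), clones, hl)
        _, v2 = hlamp_copy_variance(cn2, np.full(20, 4), clones, hl)
        assert v1 == pytest.approx(v2)

    def test_planted_jitter_variance_recovered(self, make_cn):
        from hapcells.core_io import BinGrid

        grid = BinGrid.uniform(1, 4)
        rng = np.random.default_rng(123)
        n = 500
        sigma = 0.8
        raw = np.full((n, 4), 2.0)
        raw[:, 0] = 12.0 + rng.normal(0, sigma * 2, n)  # ploidy 2 divides it out
        cn = make_cn(grid, np.full((n, 4), 2), raw=np.abs(raw))
        clones = {f"c{i}": "A" for i in range(n)}
        hl = np.array([True, False, False, False])
        _, var = hlamp_copy_variance(cn, np.full(n, 2), clones, hl)
        assert var == pytest.approx(sigma**2, rel=0.2)


class TestAmplitudeRatio:
    @pytest.mark.parametrize(
        "copies,expected_ratio,variable",
        [
            ((16.0, 8.0), 2.0, True),  # boundary: ratio exactly 2 is variable
            ((3.0, 2.0), 1.5, False),
            ((6.0, 0.0), math.inf, True),
        ],
    )
    def test_ratio_rules(self, small_grid, make_cn, copies, expected_ratio, variable):
        raw = np.r_[np.full((3, 20), copies[0]), np.full((3, 20), copies[1])]
        cn = make_cn(small_grid, np.full((6, 20), 2), raw=raw)
        clones = {f"c{i}": ("A" if i < 3 else "B") for i in range(6)}
        cons = consensus_profile(cn, clones)
        genes = pd.DataFrame({"name": ["g"], "chrom": ["1"], "start": [1], "end": [100]})
        out = clone_amplitude_ratio(cons, genes, small_grid)
        assert out.iloc[0]["ratio"] == expected_ratio
        assert bool(out.iloc[0]["variable"]) is variable

    def test_gene_outside_grid_raises(self, small_grid, make_cn):
        cn = make_cn(small_grid, np.full((4, 20), 2))
        clones = {f"c{i}": ("A" if i < 2 else "B") for i in range(4)}
        cons = consensus_profile(cn, clones)
        genes = pd.DataFrame(
            {"name": ["g"], "chrom": ["1"], "start": [10**9], "end": [10**9 + 1]}
        )
        with pytest.raises(ValueError, match="outside"):
            clone_amplitude_ratio(cons, genes, small_grid)


class TestDisjoin:
    def test_interval_disjoin(self, small_grid, make_cn):
        cn = make_cn(small_grid, np.full((2, 20), 2))
        seg_a = pd.DataFrame(
            {"chrom": ["1", "1"], "start_bin": [0, 5], "end_bin": [4, 9]}
        )
        seg_b = pd.DataFrame(
            {"chrom": ["1", "1"], "start_bin": [0, 8], "end_bin": [7, 9]}
        )
        st = disjoin_and_genotype([seg_a, seg_b], cn)
        spans = st.segments[["start_bin", "end_bin"]].to_records(index=False).tolist()
        assert spans == [(0, 4), (5, 7), (8, 9)]

    def test_single_segmentation_identity(self, small_grid, make_cn):
        cn = make_cn(small_grid, np.full((2, 20), 2))
        seg = pd.DataFrame({"chrom": ["1"], "start_bin": [0], "end_bin": [9]})
        st = disjoin_and_genotype([seg], cn)
        assert len(st.segments) == 1
        assert st.segments.iloc[0]["end_bin"] == 9

    def test_modal_genotype(self, small_grid, make_cn):
        states = np.full((1, 20), 2)
        states[0, 3] = 3  # minority bin inside the segment
        cn = make_cn(small_grid, states)
        seg = pd.DataFrame({"chrom": ["1"], "start_bin": [0], "end_bin": [9]})
        st = disjoin_and_genotype([seg], cn)
        assert st.total[0, 0] == 2

    def test_segments_partition_coverage(self, small_grid, make_cn):
        cn = make_cn(small_grid, np.full((1, 20), 2))
        seg_a = pd.DataFrame({"chrom": ["1"], "start_bin": [0], "end_bin": [9]})
        seg_b = pd.DataFrame({"chrom": ["1"], "start_bin": [3], "end_bin": [6]})
        st = disjoin_and_genotype([seg_a, seg_b], cn)
        covered = []
        for seg in st.segments.itertuples():
            covered.extend(range(seg.start_bin, seg.end_bin + 1))
        assert sorted(covered) == list(range(10))  # exactly once each


class TestHlampFeatures:
    def test_entropy_and_sv_features(self, small_grid, make_cn):
        cn = make_cn(small_grid, np.full((3, 20), 4.0).astype(int))
        hscn = hscn_from(small_grid, np.full((3, 20), 2), np.full((3, 20), 2))
        svs = pd.DataFrame(
            {
                "chrom1": ["1"] * 4,
                "pos1": [100] * 4,
                "strand1": "+",
                "chrom2": ["1"] * 4,
                "pos2": [200] * 4,
                "strand2": "-",
                "type": ["foldback", "foldback", "deletion", "duplication"],
            }
        )
        feats = hlamp_feature_vector(("1", 500_000), cn, hscn, svs)
        assert feats["hscn_entropy"] == pytest.approx(0.0)  # single state
        assert feats["prop_foldback"] == pytest.approx(0.5)
        assert feats["sv_count"] == 4
        assert feats["mean_minor_copy"] == pytest.approx(2.0)

    def test_copy_ratio(self, small_grid, make_cn):
        raw = np.full((2, 20), 4.0)
        raw[:, 0] = 16.0
        raw[:, 10:] = np.nan  # other chromosome irrelevant
        cn = make_cn(small_grid, np.full((2, 20), 4), raw=raw)
        hscn = hscn_from(small_grid, np.full((2, 20), 2), np.full((2, 20), 2))
        feats = hlamp_feature_vector(("1", 100), cn, hscn, None)
        # locus bin 16 vs chromosome mean (16 + 9*4)/10 = 5.2
        assert feats["copy_ratio"] == pytest.approx(16.0 / 5.2)
        assert feats["sv_count"] == 0.0

    def test_clustering_selects_separated_groups(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            np.r_[rng.normal(0, 0.1, (10, 3)), rng.normal(5, 0.1, (10, 3))]
        )
        labels = cluster_hlamp_features(X)
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert set(labels[:10]) != set(labels[10:])
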