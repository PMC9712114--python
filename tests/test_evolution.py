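"""Copy-number distance, parallel CNAs, parsimony rates and cophenetic
diversity, each checked against an independent brute-force oracle."""

import itertools
import math
from collections import deque

import dendropy
import numpy as np
import pandas as pd
import pytest

from hapcells.cn_metrics import SegmentTable
from hapcells.evolution import (
    aggregate_event_rates,
    classify_clonality,
    classify_segment_scale,
    cnt_distance,
    cophenetic_diversity,
    detect_parallel_cna,
    load_tree,
    pairwise_distance_matrix,
    parsimony_event_rate,
    profile_distance,
    sankoff_score,
    wgd_distance,
)


def bfs_distances(source, cap):
    """All transformation distances from one profile: interval +/-1 operations,
    floor at zero, zeros never regain copies."""
    n = len(source)
    dist = {tuple(source): 0}
    queue = deque([tuple(source)])
    while queue:
        x = queue.popleft()
        d = dist[x]
        for i in range(n):
            for j in range(i, n):
                for op in (1, -1):
                    y = list(x)
                    for k in range(i, j + 1):
                        if y[k] == 0:
                            continue
                        y[k] = max(y[k] + op, 0)
                    y = tuple(y)
                    if max(y) > cap or y in dist:
                        continue
                    dist[y] = d + 1
                    queue.append(y)
    return dist


class TestCntDistance:
    def test_identity(self):
        assert cnt_distance([2, 3, 1], [2, 3, 1]) == 0

    def test_uniform_gain(self):
        assert cnt_distance([2, 2, 2], [4, 4, 4]) == 2

    def test_valley_fill(self):
        assert cnt_distance([1, 2, 1], [2, 2, 2]) == 2

    def test_infeasible_zero_regain(self):
        assert math.isinf(cnt_distance([1, 0, 1], [1, 1, 1]))

    def test_floor_saves_operations(self):
        # driving the middle to zero lets one wide deletion cover both sides
        assert cnt_distance([5, 1, 5], [2, 0, 2]) == 3

    def test_matches_bfs_oracle_on_sampled_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            n = int(rng.integers(1, 5))
            u = rng.integers(0, 4, n)
            dist = bfs_distances(u, cap=5)
            for _ in range(10):
                v = rng.integers(0, 4, n)
                oracle = dist.get(tuple(v), math.inf)
                assert cnt_distance(u, v) == oracle

    def test_metric_axioms_on_positive_profiles(self):
        profiles = list(itertools.product([1, 2, 3], repeat=3))
        D = {
            (u, v): cnt_distance(u, v)
            for u in profiles
            for v in profiles
        }
        for u in profiles:
            assert D[(u, u)] == 0
            for v in profiles:
                assert D[(u, v)] == D[(v, u)]
                assert (D[(u, v)] == 0) == (u == v)
        for u, v, w in itertools.product(profiles, repeat=3):
            assert D[(u, w)] <= D[(u, v)] + D[(v, w)]


class TestWgdDistance:
    def test_equal_profiles(self):
        chrom = np.array(["1", "1"])
        a = np.array([2, 2])
        assert wgd_distance(a, a, a, a, chrom) == 0

    def test_doubling_costs_one(self):
        chrom = np.array(["1", "1", "1"])
        a = np.array([2, 1, 3])
        b = np.array([1, 1, 2])
        assert wgd_distance(a, b, 2 * a, 2 * b, chrom) == 1

    def test_small_gain_beats_doubling(self):
        chrom = np.array(["1", "1"])
        assert (
            wgd_distance(
                np.array([2, 2]), np.array([2, 2]), np.array([3, 3]), np.array([2, 2]), chrom
            )
            == 1
        )

    def test_tie_with_d1_takes_d1_without_increment(self):
        # A=(1,1), B=(2,1): plain distance d1 = 1 equals the doubled route
        # d2 = f((2,2),(2,1)) = 1; the tie resolves to d1 with no WGD increment
        chrom = np.array(["1"])
        one = np.array([1])
        two = np.array([2])
        assert profile_distance(one, one, two, one, chrom) == 1
        assert wgd_distance(one, one, two, one, chrom) == 1

    def test_doubled_profile_always_one_for_positive_profiles(self):
        rng = np.random.default_rng(4)
        chrom = np.repeat(["1", "2"], 5)
        for _ in range(20):
            a = rng.integers(1, 5, 10)
            b = rng.integers(1, 5, 10)
            assert wgd_distance(a, b, 2 * a, 2 * b, chrom) == 1


def make_segment_table(total, a, b, span_bp=5_000_000, chrom="1"):
    total = np.asarray(total)
    n_bins = int(span_bp // 500_000)
    segments = pd.DataFrame(
        {
            "segment_id": ["seg0"],
            "chrom": [chrom],
            "start": [1],
            "end": [span_bp],
            "start_bin": [0],
            "end_bin": [n_bins - 1],
            "span": [span_bp],
        }
    )
    return SegmentTable(
        segments=segments,
        cells=[f"c{i}" for i in range(len(total))],
        total=total.reshape(-1, 1),
        a=np.asarray(a).reshape(-1, 1),
        b=np.asarray(b).reshape(-1, 1),
    )


class TestParallelCna:
    def _population(self, n, frac_a, frac_b, span_bp, direction="loss"):
        delta = 1 if direction == "gain" else -1
        a = np.ones(n, dtype=int)
        b = np.ones(n, dtype=int)
        n_a, n_b = int(frac_a * n), int(frac_b * n)
        a[:n_a] += delta
        b[n_a : n_a + n_b] += delta
        return make_segment_table(a + b, a, b, span_bp=span_bp)

    def test_detected_above_both_thresholds(self):
        st = self._population(1000, 0.02, 0.03, 5_000_000)
        out = detect_parallel_cna(st)
        assert len(out) == 1
        assert out.iloc[0]["direction"] == "loss"
        assert out.iloc[0]["frac_a"] == pytest.approx(0.02)

    def test_span_rule_excludes_small_segment(self):
        st = self._population(1000, 0.02, 0.03, 3_000_000)
        assert len(detect_parallel_cna(st)) == 0

    def test_fraction_rule_strict(self):
        # 1% on one allele is not "more than 1%"
        st = self._population(1000, 0.01, 0.03, 5_000_000)
        assert len(detect_parallel_cna(st)) == 0

    def test_ccf_and_clonality_reported(self):
        st = self._population(1000, 0.02, 0.03, 5_000_000)
        out = detect_parallel_cna(st)
        assert out.iloc[0]["ccf"] == pytest.approx(0.05)
        assert out.iloc[0]["clonality"] == "rare"


class TestClonality:
    @pytest.mark.parametrize(
        "ccf,expected",
        [
            (0.85, "clonal"),
            (0.5, "subclonal"),
            (0.2, "rare"),  # boundary inclusive
            (0.8, "subclonal"),  # boundary: 0.8 is still subclonal
            (0.801, "clonal"),
        ],
    )
    def test_boundaries(self, ccf, expected):
        assert classify_clonality(ccf) == expected


def exhaustive_parsimony(tree, tip_states):
    """Brute-force minimum transition count over all internal labellings."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = math.inf
    for labels in itertools.product([0, 1], repeat=len(internals)):
        assign = dict(zip(internals, labels))
        cost = 0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            s = (
                tip_states[node.taxon.label]
                if node.is_leaf()
                else assign[node]
            )
            sp = assign[node.parent_node]
            cost += int(s != sp)
        best = min(best, cost)
    return best


def random_binary_tree(labels, rng):
    parts = [f"{x}:1" for x in labels]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), 2, replace=False))
        merged = f"({parts[i]},{parts[j]}):1"
        parts = [p for k, p in enumerate(parts) if k not in (i, j)] + [merged]
    return parts[0].rsplit(":", 1)[0] + ";"


class TestParsimony:
    def test_star_tree_single_gain(self):
        tips = [f"c{i}" for i in range(10)]
        tree = load_tree("(" + ",".join(f"{t}:1" for t in tips) + ");")
        states = {t: 0 for t in tips}
        states["c3"] = 1
        assert sankoff_score(tree, states) == 1

    def test_balanced_quartet_shared_gain(self):
        tree = load_tree("((A:1,B:1):1,(C:1,D:1):1);")
        assert sankoff_score(tree, {"A": 1, "B": 1, "C": 0, "D": 0}) == 1

    def test_no_altered_tips_zero(self):
        tree = load_tree("((A:1,B:1):1,(C:1,D:1):1);")
        assert sankoff_score(tree, {t: 0 for t in "ABCD"}) == 0

    def test_matches_exhaustive_oracle_on_random_trees(self):
        rng = np.random.default_rng(7)
        for n_tips in (4, 5, 6, 7, 8):
            for _ in range(6):
                labels = [f"t{i}" for i in range(n_tips)]
                tree = load_tree(random_binary_tree(labels, rng))
                states = {t: int(rng.integers(0, 2)) for t in labels}
                assert sankoff_score(tree, states) == exhaustive_parsimony(tree, states)

    def test_event_rate_table(self):
        tree = load_tree("((c0:1,c1:1):1,(c2:1,c3:1):1);")
        a = np.array([0, 1, 1, 1])  # one tip lost an allele
        b = np.array([1, 1, 1, 1])
        st = make_segment_table(a + b, a, b)
        rates = parsimony_event_rate(tree, st, _grid(10), None)
        loss = rates[rates["direction"] == "loss"].iloc[0]
        assert loss["score"] == 1
        assert loss["rate"] == pytest.approx(0.25)
        agg = aggregate_event_rates(rates)
        assert agg[agg["direction"] == "loss"]["rate"].iloc[0] == pytest.approx(0.25)


def _grid(n_bins, n_chrom=1):
    from hapcells.core_io import BinGrid

    return BinGrid.uniform(n_chrom, n_bins)


class TestSegmentScale:
    def _centromeres(self):
        return pd.DataFrame(
            {"chrom": ["1"], "cent_start": [4_500_001], "cent_end": [5_500_000]}
        )

    def _seg(self, start_bin, end_bin):
        return pd.Series(
            {"chrom": "1", "start_bin": start_bin, "end_bin": end_bin}
        )

    def test_whole_chromosome(self):
        grid = _grid(20)
        out = classify_segment_scale(
            self._seg(0, 19), grid, self._centromeres(), np.ones(20, dtype=bool)
        )
        assert out == "whole_chromosome"

    def test_p_arm(self):
        grid = _grid(20)
        out = classify_segment_scale(
            self._seg(0, 8), grid, self._centromeres(), np.ones(20, dtype=bool)
        )
        assert out == "arm"

    def test_interior_segment(self):
        grid = _grid(20)
        out = classify_segment_scale(
            self._seg(6, 12), grid, self._centromeres(), np.ones(20, dtype=bool)
        )
        assert out == "segmental"

    def test_missing_centromere_falls_back(self):
        grid = _grid(20)
        out = classify_segment_scale(
            self._seg(0, 8), grid, None, np.ones(20, dtype=bool)
        )
        assert out == "segmental"


class TestCophenetic:
    def test_two_tips(self):
        assert cophenetic_diversity(load_tree("(A:1,B:1);")) == pytest.approx(2.0)

    def test_star_tree(self):
        tree = load_tree("(A:1,B:1,C:1,D:1);")
        assert cophenetic_diversity(tree) == pytest.approx(2.0)

    def test_matches_brute_force_on_caterpillar(self):
        newick = "((((A:1,B:2):1,C:3):2,D:1):1,E:4);"
        tree = load_tree(newick)
        pdm = dendropy.Tree.get(data=newick, schema="newick").phylogenetic_distance_matrix()
        taxa = list(pdm.taxon_iter())
        pairs = [
            pdm.distance(t1, t2) for i, t1 in enumerate(taxa) for t2 in taxa[i + 1 :]
        ]
        assert cophenetic_diversity(tree) == pytest.approx(np.mean(pairs))

    def test_single_tip_raises(self):
        with pytest.raises(ValueError):
            cophenetic_diversity(load_tree("(A:1);"))


def test_pairwise_distance_matrix_deterministic(small_grid):
    from hapcells.hscn_hmm import HSCNMatrix

    rng = np.random.default_rng(0)
    n = 12
    a = rng.integers(1, 4, (n, 20))
    b = rng.integers(1, 4, (n, 20))
    h = HSCNMatrix(
        grid=small_grid,
        cells=[f"c{i}" for i in range(n)],
        a=a,
        b=b,
        baf=np.full((n, 20), np.nan),
        posterior=np.ones((n, 20)),
    )
    cells1, D1, s1 = pairwise_distance_matrix(h, max_n=8, seed=5)
    cells2, D2, s2 = pairwise_distance_matrix(h, max_n=8, seed=5)
    assert cells1 == cells2
    np.testing.assert_array_equal(D1, D2)
    assert s1 == s2
    assert s1["n_pairs"] == 28
    # identical population -> all zero distances
    h0 = HSCNMatrix(
        grid=small_grid,
        cells=["x", "y"],
        a=np.ones((2, 20), dtype=int),
        b=np.ones((2, 20), dtype=int),
        baf=np.full((2, 20), np.nan),
        posterior=np.ones((2, 20)),
    )
    _, D0, _ = pairwise_distance_matrix(h0, seed=0)
    assert (D0 == 0).all()
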