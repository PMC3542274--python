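"""Two-point RH analysis, binning, framework mapping and resolution."""

import math

import numpy as np
import pytest
from dataclasses import replace

from rhpanel.genotype import GenotypeMatrix
from rhpanel.mapping import (
    ChainScorer,
    _pair_loglik,
    bin_markers,
    build_framework,
    cr_from_theta,
    estimate_retention,
    graphical_genotype,
    map_summary,
    obligate_breaks,
    obligate_breaks_total,
    order_markers,
    resolution_estimate,
    theta_from_cr,
    two_point,
)
from rhpanel.simulate import simulate_panel


def _matrix(grid):
    grid = np.asarray(grid, dtype=float)
    return GenotypeMatrix(
        grid,
        [f"L{i}" for i in range(grid.shape[0])],
        [f"m{j}" for j in range(grid.shape[1])],
    )


class TestCrTransform:
    def test_zero_and_inverse(self):
        assert cr_from_theta(0.0) == 0.0
        for theta in (0.0, 0.1, 0.5, 0.99):
            assert theta_from_cr(cr_from_theta(theta)) == pytest.approx(theta)

    def test_unlinked_is_infinite(self):
        assert math.isinf(cr_from_theta(1.0))

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            cr_from_theta(1.5)
        with pytest.raises(ValueError):
            theta_from_cr(-1.0)


class TestTwoPoint:
    def test_identical_patterns_theta_zero(self):
        m = _matrix([[1, 1], [0, 0], [1, 1], [0, 0]])
        res = two_point(m, "m0", "m1", 0.5)
        assert res.theta == 0.0
        assert res.cR == 0.0
        assert res.linked

    def test_no_concordant_patterns_unlinked(self):
        m = _matrix([[1, 0], [0, 1], [1, 0], [0, 1]])
        res = two_point(m, "m0", "m1", 0.5)
        assert res.theta == 1.0
        assert not res.linked
        assert math.isinf(res.cR)

    def test_symmetric_in_marker_order(self):
        rng = np.random.default_rng(4)
        m = _matrix(rng.choice([0.0, 1.0], size=(30, 2)))
        a = two_point(m, "m0", "m1", 0.6)
        b = two_point(m, "m1", "m0", 0.6)
        assert a.theta == pytest.approx(b.theta)
        assert a.lod == pytest.approx(b.lod)

    def test_missing_dropped_pairwise(self):
        m = _matrix([[1, 1], [0, np.nan], [np.nan, 0], [1, 0]])
        res = two_point(m, "m0", "m1", 0.5)
        assert res.n_informative == 2

    def test_all_missing_rejected(self):
        m = _matrix([[1, np.nan], [np.nan, 1]])
        with pytest.raises(ValueError):
            two_point(m, "m0", "m1", 0.5)

    def test_mle_matches_grid_search_oracle(self):
        """The closed-form breakage MLE agrees with a brute-force maximizer
        of the same likelihood over a 1e-4 grid, on random 10-50-line toys."""
        rng = np.random.default_rng(12)
        grid = np.arange(0.0, 1.0 + 1e-9, 1e-4)
        for _ in range(60):
            n = int(rng.integers(10, 51))
            r = float(rng.uniform(0.2, 0.9))
            theta_true = float(rng.uniform(0.0, 1.0))
            x1 = (rng.random(n) < r).astype(float)
            broke = rng.random(n) < theta_true
            x2 = np.where(broke, (rng.random(n) < r).astype(float), x1)
            m = _matrix(np.c_[x1, x2])
            res = two_point(m, "m0", "m1", r)
            a = int(((x1 == 1) & (x2 == 1)).sum())
            b = int((x1 != x2).sum())
            c = int(((x1 == 0) & (x2 == 0)).sum())
            ll = [
                _pair_loglik(a, b, c, r, min(t, 1 - 1e-12)) for t in grid
            ]
            theta_grid = grid[int(np.argmax(ll))]
            assert res.theta == pytest.approx(theta_grid, abs=1e-4)

    def test_lod_high_for_tightly_linked_markers(self):
        m = _matrix([[1, 1]] * 30 + [[0, 0]] * 20 + [[1, 0]] * 2)
        res = two_point(m, "m0", "m1")
        assert res.lod > 3


class TestRetention:
    def test_all_retained(self):
        m = _matrix(np.ones((4, 3)))
        assert estimate_retention(m) == 1.0

    def test_complement_of_loss_frequency(self, small_panel):
        from rhpanel.stats import marker_loss_frequency

        r = estimate_retention(small_panel.matrix)
        loss = marker_loss_frequency(
            small_panel.matrix, "marker"
        ).table["frequency"].mean()
        assert r == pytest.approx(1.0 - loss)


class TestBins:
    def test_identical_patterns_one_bin(self):
        m = _matrix([[1, 1, 1], [0, 0, 0], [1, 1, 1]])
        bins = bin_markers(m, m.marker_ids)
        assert bins.groups == [["m0", "m1", "m2"]]
        assert bins.conflicts == []

    def test_all_distinct_patterns(self):
        m = _matrix([[1, 0, 1], [0, 1, 1], [1, 1, 0], [0, 0, 1]])
        bins = bin_markers(m, m.marker_ids)
        assert len(bins.groups) == 3

    def test_missing_is_wildcard(self):
        m = _matrix([[1, 1], [0, np.nan], [1, 1]])
        bins = bin_markers(m, m.marker_ids)
        assert bins.groups == [["m0", "m1"]]

    def test_matches_bruteforce_partition(self):
        """On a complete-data toy the partition equals the brute-force
        pairwise-identity partition."""
        rng = np.random.default_rng(9)
        base = rng.choice([0.0, 1.0], size=(16, 5))
        grid = base[:, [0, 1, 0, 2, 3, 1, 4]]  # duplicates by construction
        m = _matrix(grid)
        bins = bin_markers(m, m.marker_ids)
        # brute force: group columns by exact pattern equality
        patterns = {}
        for j, mid in enumerate(m.marker_ids):
            patterns.setdefault(tuple(grid[:, j]), []).append(mid)
        expected = sorted(tuple(v) for v in patterns.values())
        assert sorted(tuple(g) for g in bins.groups) == expected

    def test_wildcard_conflicts_reported(self):
        # m0 and m2 contradict but both match all-missing m1
        m = _matrix(
            [[1.0, np.nan, 0.0], [0.0, np.nan, 1.0]]
        )
        bins = bin_markers(m, m.marker_ids)
        assert len(bins.groups) == 1
        assert ("m0", "m2") in bins.conflicts


class TestObligateBreaks:
    @pytest.mark.parametrize(
        "calls,expected",
        [
            ([1, 1, 1, 1], 0),
            ([1, 0, 0, 1], 2),
            ([0, 0, 1, 1], 1),  # terminal deletion: one break
            ([1, 0, np.nan, 0, 1], 2),  # missing skipped
            ([1, np.nan, 1, 0], 1),
        ],
    )
    def test_transition_counts(self, calls, expected):
        assert obligate_breaks(calls) == expected

    def test_too_few_scored_calls(self):
        with pytest.raises(ValueError):
            obligate_breaks([1, np.nan, np.nan])

    def test_total_skips_sparse_lines(self):
        m = _matrix([[1, 0, 1], [np.nan, np.nan, 1]])
        assert obligate_breaks_total(m, m.marker_ids) == 2


class TestResolution:
    def test_distal_bin_arithmetic(self):
        est = resolution_estimate(3_200_000, 23)
        assert est.kb_per_break == pytest.approx(139.13, abs=0.005)
        assert est.kb_per_break < 140

    def test_contig_pair_arithmetic(self):
        assert resolution_estimate(400_000, 4).kb_per_break == pytest.approx(
            100.0
        )

    def test_trivial_and_invalid(self):
        assert resolution_estimate(1000, 1).kb_per_break == pytest.approx(1.0)
        with pytest.raises(ValueError):
            resolution_estimate(1000, 0)
        with pytest.raises(ValueError):
            resolution_estimate(0, 3)


def _sim_chromosome(mapping_scenario, chrom2d_map, seed, n_lines=400):
    sim = simulate_panel(replace(mapping_scenario, seed=seed), chrom2d_map)
    informative = [
        l
        for l, has in zip(sim.matrix.line_ids, sim.matrix.is_lost.any(axis=1))
        if has
    ]
    return sim.matrix.subset_lines(informative[:n_lines])


class TestFramework:
    def test_two_markers_distance_is_two_point_cr(self):
        rng = np.random.default_rng(21)
        x1 = (rng.random(200) < 0.7).astype(float)
        broke = rng.random(200) < 0.3
        x2 = np.where(broke, (rng.random(200) < 0.7).astype(float), x1)
        m = _matrix(np.c_[x1, x2])
        fw = build_framework(m, m.marker_ids, ["m0", "m1"])
        r = estimate_retention(m)
        assert fw.total_cR == pytest.approx(two_point(m, "m0", "m1", r).cR)
        assert fw.ordered_markers == ["m0", "m1"]

    def test_identical_patterns_share_bin_and_position(self):
        rng = np.random.default_rng(22)
        x1 = (rng.random(150) < 0.7).astype(float)
        broke = rng.random(150) < 0.4
        x2 = np.where(broke, (rng.random(150) < 0.7).astype(float), x1)
        m = GenotypeMatrix(
            np.c_[x1, x1, x2],
            [f"L{i}" for i in range(150)],
            ["a1", "a2", "b"],
        )
        fw = build_framework(m, ["a1", "a2", "b"], ["a1", "b"])
        pos = {p.marker_id: p for p in fw.positions}
        assert pos["a1"].position_cR == pos["a2"].position_cR
        assert pos["a1"].bin_id == pos["a2"].bin_id
        assert pos["b"].bin_id != pos["a1"].bin_id

    def test_anchor_validation(self):
        m = _matrix([[1, 1], [0, 1]])
        with pytest.raises(ValueError, match=">=2 anchors"):
            build_framework(m, m.marker_ids, ["m0"])
        with pytest.raises(ValueError, match="not among"):
            build_framework(m, m.marker_ids, ["m0", "zz"])
        m2 = _matrix([[1, np.nan], [0, np.nan]])
        with pytest.raises(ValueError, match="no scored calls"):
            build_framework(m2, m2.marker_ids, ["m0", "m1"])

    def test_recovers_simulated_order(self, mapping_scenario, chrom2d_map):
        """400 informative lines on a 25-marker chromosome recover the true
        order (or its reverse) through the anchored iterative procedure."""
        true_order = chrom2d_map.marker_ids
        anchors = [true_order[i] for i in (0, 5, 10, 14, 19, 24)]
        hits = 0
        for seed in range(10):
            mat = _sim_chromosome(mapping_scenario, chrom2d_map, 300 + seed)
            fw = build_framework(mat, true_order, anchors)
            got = fw.ordered_markers
            if got in (true_order, true_order[::-1]):
                hits += 1
        assert hits >= 9

    def test_positions_non_decreasing_and_total_matches(
        self, mapping_scenario, chrom2d_map
    ):
        mat = _sim_chromosome(mapping_scenario, chrom2d_map, 555)
        fw = build_framework(
            mat, chrom2d_map.marker_ids,
            [chrom2d_map.marker_ids[0], chrom2d_map.marker_ids[-1]],
        )
        pos = [p.position_cR for p in fw.positions]
        assert pos == sorted(pos)
        assert fw.total_cR == pytest.approx(max(pos))
        summary = map_summary(fw, genetic_length_cM=fw.total_cR / 5.2)
        assert summary.cr_per_cm == pytest.approx(5.2)
        assert summary.n_bins == len(fw.bins)

    def test_chain_score_reversal_invariant(self, mapping_scenario,
                                            chrom2d_map):
        mat = _sim_chromosome(mapping_scenario, chrom2d_map, 777, n_lines=150)
        scorer = ChainScorer(mat, mat.marker_ids)
        order = list(range(len(mat.marker_ids)))
        fwd = scorer.score(np.array(order))
        rev = scorer.score(np.array(order[::-1]))
        assert fwd == pytest.approx(rev)

    def test_order_search_matches_exhaustive_on_small_sets(
        self, mapping_scenario, chrom2d_map
    ):
        """Greedy+flips+polish finds the same optimum as exhaustive search
        on 7-marker subsets."""
        mat = _sim_chromosome(mapping_scenario, chrom2d_map, 888, n_lines=200)
        subset = mat.marker_ids[:7]
        sub = mat.subset_markers(subset)
        exhaustive = order_markers(sub, subset, exhaustive_limit=8)
        local = order_markers(sub, subset, exhaustive_limit=2)
        scorer = ChainScorer(sub, subset)
        assert scorer.score_ids(local) == pytest.approx(
            scorer.score_ids(exhaustive)
        )


class TestGraphicalGenotype:
    def test_grid_follows_map_order_and_codes(self, mapping_scenario,
                                              chrom2d_map):
        mat = _sim_chromosome(mapping_scenario, chrom2d_map, 999, n_lines=16)
        ids = chrom2d_map.marker_ids
        fw = build_framework(mat, ids, [ids[0], ids[12], ids[24]])
        grid = graphical_genotype(mat, fw)
        assert list(grid.columns) == fw.ordered_markers
        assert set(np.unique(grid.to_numpy())) <= {"0", "1", "NA"}

    def test_single_all_retained_line(self):
        m = _matrix([[1, 1], [0, 1]] * 40)
        fw = build_framework(m, m.marker_ids, ["m0", "m1"])
        grid = graphical_genotype(m, fw, lines=["L0"])
        assert list(grid.loc["L0"]) == ["1", "1"]
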