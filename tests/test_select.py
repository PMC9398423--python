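"""Clustering and selection policies: oracles, invariances, semantics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cryoscreen as cs
from cryoscreen.targets import HoleTarget, SquareTarget


def exhaustive_1d_partition(values: np.ndarray, k: int) -> list[set[int]]:
    """Optimal 1-D k-partition by enumerating contiguous splits in sorted order.

    The within-cluster sum of squares is minimized by clusters that are
    contiguous in value order, so enumerating split points is exhaustive.
    """
    order = np.argsort(values, kind="stable")
    n = len(values)
    best, best_cost = None, np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        cost = 0.0
        parts = []
        for a, b in zip(bounds, bounds[1:]):
            chunk = values[order[a:b]]
            cost += float(((chunk - chunk.mean()) ** 2).sum())
            parts.append(set(order[a:b].tolist()))
        if cost < best_cost - 1e-12:
            best_cost, best = cost, parts
    return best


def _holes(intensities):
    return [
        HoleTarget(id=i, parent_square_id=0, center_um=(float(i), 0.0), radius_um=0.6, median_intensity=float(v))
        for i, v in enumerate(intensities)
    ]


def _squares(areas):
    return [
        SquareTarget(id=i, center_um=(float(i), 0.0), bbox_px=(0, 0, 10, 10), area_px=int(a), class_label="good")
        for i, a in enumerate(areas)
    ]


class TestKMeans1D:
    def test_matches_exhaustive_oracle_on_separated_values(self):
        values = np.array([10.0, 11.0, 50.0, 51.0, 90.0, 91.0])
        assign, centers = cs.kmeans_1d(values, 3)
        oracle = exhaustive_1d_partition(values, 3)
        got = [set(np.flatnonzero(assign == j).tolist()) for j in range(3)]
        assert sorted(map(sorted, got)) == sorted(map(sorted, oracle))
        assert set(np.flatnonzero(assign == 0)) == {0, 1}  # cluster 0 = darkest

    def test_two_well_separated_groups(self):
        values = np.array([1.0, 1.0, 1.0, 100.0, 100.0, 100.0])
        assign, _ = cs.kmeans_1d(values, 2)
        assert set(assign[:3]) == {0} and set(assign[3:]) == {1}

    def test_k_reduced_to_distinct_values(self):
        assign, centers = cs.kmeans_1d(np.array([5.0, 5.0, 5.0]), 4)
        assert len(centers) == 1 and set(assign) == {0}

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3, allow_nan=False), min_size=2, max_size=24), st.integers(1, 5))
    def test_permutation_invariance(self, values, k):
        values = np.array(values)
        assign, _ = cs.kmeans_1d(values, k)
        perm = np.random.RandomState(0).permutation(len(values))
        assign_p, _ = cs.kmeans_1d(values[perm], k)
        assert np.array_equal(assign[perm], assign_p)

    def test_shift_invariance(self):
        values = np.array([10.0, 11.0, 50.0, 51.0, 90.0, 91.0])
        a1, _ = cs.kmeans_1d(values, 3)
        a2, _ = cs.kmeans_1d(values + 123.4, 3)
        assert np.array_equal(a1, a2)


class TestSquareSelection:
    def test_k1_single_cluster(self):
        squares = _squares([10, 20, 30])
        cs.cluster_squares(squares, "size", 1)
        assert {s.cluster_id for s in squares} == {0}

    def test_perfect_split_on_bimodal_areas(self):
        squares = _squares([1, 1, 1, 100, 100, 100])
        cs.cluster_squares(squares, "size", 2)
        assert {s.cluster_id for s in squares[:3]} == {0}
        assert {s.cluster_id for s in squares[3:]} == {1}

    def test_representatives_span_clusters(self):
        squares = _squares([1, 1, 1, 100, 100, 100, 1000, 1000])
        cs.cluster_squares(squares, "size", 3)
        cs.select_square_representatives(squares, 3)
        chosen_clusters = {s.cluster_id for s in squares if s.selected}
        assert len(chosen_clusters) == 3
        assert sum(s.selected for s in squares) == 3

    def test_unbalanced_clusters_one_each(self):
        squares = _squares([1, 1, 1, 1, 1, 100])
        cs.cluster_squares(squares, "size", 2)
        cs.select_square_representatives(squares, 2)
        sel = [s for s in squares if s.selected]
        assert len(sel) == 2
        assert {s.cluster_id for s in sel} == {0, 1}

    def test_n_at_least_population_selects_all(self):
        squares = _squares([1, 2, 3])
        cs.cluster_squares(squares, "size", 2)
        cs.select_square_representatives(squares, 10)
        assert all(s.selected for s in squares)


class TestHoleSelection:
    def test_pure_pairs_cluster_and_darkest_rejected(self):
        holes = _holes([10, 11, 50, 51, 90, 91])
        cs.cluster_holes(holes, 3)
        assert [h.intensity_cluster_id for h in holes] == [0, 0, 1, 1, 2, 2]
        cs.apply_default_exclusion(holes, reject_darkest=True)
        assert [h.status for h in holes] == ["rejected", "rejected", "detected", "detected", "detected", "detected"]

    def test_no_rejection_when_disabled_or_single_cluster(self):
        holes = _holes([10, 11, 50, 51])
        cs.cluster_holes(holes, 2)
        cs.apply_default_exclusion(holes, reject_darkest=False)
        assert all(h.status == "detected" for h in holes)
        equal = _holes([5, 5, 5])
        cs.cluster_holes(equal, 3)  # k collapses to 1
        cs.apply_default_exclusion(equal, reject_darkest=True)
        assert all(h.status == "detected" for h in equal)

    def test_n_zero_selects_every_included_hole(self):
        holes = _holes(range(20))
        holes[3].is_contaminant = True
        holes[4].status = "rejected"
        cs.select_holes(holes, 0)
        sel = [h for h in holes if h.selected]
        assert len(sel) == 18
        assert holes[3] not in sel and holes[4] not in sel

    def test_round_robin_over_included_clusters(self):
        holes = _holes([10, 11, 50, 51, 90, 91])
        cs.cluster_holes(holes, 3)
        cs.apply_default_exclusion(holes, True)
        cs.select_holes(holes, 2)
        sel = sorted(h.intensity_cluster_id for h in holes if h.selected)
        assert sel == [1, 2]  # one per included cluster, brightest first

    def test_selection_never_includes_contaminant_or_rejected(self):
        holes = _holes([10, 11, 50, 51, 90, 91])
        holes[5].is_contaminant = True
        cs.cluster_holes(holes, 2)
        cs.apply_default_exclusion(holes, True)
        cs.select_holes(holes, 100)
        assert all(not (h.is_contaminant or h.status == "rejected") for h in holes if h.selected)


class TestAcquisitionValues:
    def test_zero_fraction_is_centered(self):
        h = HoleTarget(id=1, parent_square_id=0, center_um=(0, 0), radius_um=0.6)
        assert cs.acquisition_offset(h, 0.0, 42) == (0.0, 0.0)

    def test_offset_is_deterministic_per_seed_and_hole(self):
        h = HoleTarget(id=7, parent_square_id=2, center_um=(0, 0), radius_um=0.6)
        assert cs.acquisition_offset(h, 0.5, 42) == cs.acquisition_offset(h, 0.5, 42)
        assert cs.acquisition_offset(h, 0.5, 42) != cs.acquisition_offset(h, 0.5, 43)

    def test_uniform_disk_mean_radius(self):
        """E|offset| of a uniform draw on a disk of radius R is 2R/3."""
        radius = 0.6
        mags = []
        for i in range(10_000):
            h = HoleTarget(id=i, parent_square_id=0, center_um=(0, 0), radius_um=radius)
            off = cs.acquisition_offset(h, 1.0, 123)
            mags.append(np.hypot(*off))
        mags = np.array(mags)
        expected = 2.0 * radius / 3.0
        se = mags.std(ddof=1) / np.sqrt(len(mags))
        assert abs(mags.mean() - expected) < 3 * se

    def test_rolling_defocus_ladder(self):
        assert cs.rolling_defocus((-1.2, -1.8), 0) == pytest.approx(-1.2)
        assert cs.rolling_defocus((-1.2, -1.8), 6) == pytest.approx(-1.8)
        assert cs.rolling_defocus((-1.5, -1.5), 3) == -1.5
        for k in range(10):
            assert cs.rolling_defocus((-1.2, -1.8), k) == cs.rolling_defocus((-1.2, -1.8), k + 7)

    def test_policy_validation(self):
        with pytest.raises(ValueError):
            cs.SelectionPolicy(reject_darkest=True, n_intensity_clusters=1)
        with pytest.raises(ValueError):
            cs.SelectionPolicy(random_offset_fraction=1.5)
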