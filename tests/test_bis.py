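"""BIS group planning (with brute-force oracle) and tilt geometry."""

import numpy as np
import pytest

import cryoscreen as cs
from cryoscreen.targets import HoleTarget


def _holes(points):
    return [HoleTarget(id=i, parent_square_id=0, center_um=(float(p[0]), float(p[1])), radius_um=0.6) for i, p in enumerate(points)]


def random_instance(rng, n=None):
    n = n if n is not None else int(rng.integers(5, 201))
    pts = rng.uniform(0, 30, size=(n, 2))
    radius = float(rng.uniform(2.0, 6.0))
    min_size = int(rng.integers(1, 7))
    return pts, radius, min_size


class TestPlanner:
    def test_min_size_blocks_small_groups(self):
        holes = _holes([(0, 0), (1, 0), (2, 0)])
        groups, leftovers = cs.plan_bis_groups(holes, 4.0, 4)
        assert groups == [] and leftovers == [0, 1, 2]

    def test_single_hole_singleton_group(self):
        holes = _holes([(5, 5)])
        groups, leftovers = cs.plan_bis_groups(holes, 2.0, 1)
        assert len(groups) == 1 and leftovers == []
        assert groups[0].center_hole_id == 0 and groups[0].member_hole_ids == (0,)

    def test_empty_input_is_empty_plan(self):
        assert cs.plan_bis_groups([], 4.0, 4) == ([], [])

    def test_lattice_instance_with_typical_collection_settings(self):
        """12 holes on a 2.5 um pitch: 4 um radius, min size 4."""
        pts = [(i * 2.5, j * 2.5) for j in range(3) for i in range(4)]
        holes = _holes(pts)
        groups, leftovers = cs.plan_bis_groups(holes, 4.0, 4)
        report = cs.validate_bis_plan(groups, holes, 4.0, 4)
        assert report.ok, report.violations
        assert all(len(g.member_hole_ids) >= 4 for g in groups)
        by_id = {h.id: h for h in holes}
        for g in groups:
            c = np.array(by_id[g.center_hole_id].center_um)
            for hid in g.member_hole_ids:
                assert np.linalg.norm(np.array(by_id[hid].center_um) - c) <= 4.0 + 1e-9
        _, optimal = cs.optimal_group_count(np.array(pts, float), 4.0, 4)
        assert len(groups) <= optimal + 1

    def test_random_instances_always_validate(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            pts, radius, min_size = random_instance(rng)
            holes = _holes(pts)
            groups, _ = cs.plan_bis_groups(holes, radius, min_size)
            report = cs.validate_bis_plan(groups, holes, radius, min_size)
            assert report.ok, report.violations

    def test_greedy_close_to_optimal_on_small_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            pts, radius, min_size = random_instance(rng, n=int(rng.integers(3, 13)))
            holes = _holes(pts)
            groups, _ = cs.plan_bis_groups(holes, radius, min_size)
            cov, optimal = cs.optimal_group_count(pts, radius, min_size)
            covered = sum(len(g.member_hole_ids) for g in groups)
            if covered >= cov:
                assert len(groups) <= optimal + 1

    def test_determinism(self):
        rng = np.random.default_rng(2)
        pts, radius, min_size = random_instance(rng, n=40)
        a = cs.plan_bis_groups(_holes(pts), radius, min_size)
        b = cs.plan_bis_groups(_holes(pts), radius, min_size)
        assert [(g.center_hole_id, g.member_hole_ids) for g in a[0]] == [(g.center_hole_id, g.member_hole_ids) for g in b[0]]
        assert a[1] == b[1]

    def test_group_count_nonincreasing_in_radius(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            pts, _, _ = random_instance(rng, n=60)
            counts = []
            for radius in (2.0, 3.0, 4.0, 5.0, 6.0):
                groups, left = cs.plan_bis_groups(_holes(pts), radius, 1)
                assert left == []  # min size 1: everything covered
                counts.append(len(groups))
            assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_validator_catches_violations(self):
        holes = _holes([(0, 0), (1, 0), (10, 0)])
        bad_radius = [cs.BISGroup(id=0, center_hole_id=0, member_hole_ids=(0, 2), radius_um=2.0)]
        rep = cs.validate_bis_plan(bad_radius, holes, 2.0, 1)
        assert any("radius" in v for v in rep.violations)
        non_maximal = [cs.BISGroup(id=0, center_hole_id=0, member_hole_ids=(0,), radius_um=2.0)]
        rep2 = cs.validate_bis_plan(non_maximal, holes, 2.0, 1)
        assert any("ungrouped" in v for v in rep2.violations)


class TestTiltGeometry:
    def test_zero_tilt_and_on_axis_points_give_zero(self):
        geom0 = cs.TiltGeometry(tilt_deg=0.0, axis_deg=90.0)
        assert cs.tilt_height_offset((3.0, -2.0), geom0) == 0.0
        geom30 = cs.TiltGeometry(tilt_deg=30.0, axis_deg=90.0)
        assert cs.tilt_height_offset((0.0, 5.0), geom30) == pytest.approx(0.0)

    def test_closed_form_height_at_30_degrees(self):
        """v = 2 um at 30 degrees tilts up by exactly 1 um."""
        geom = cs.TiltGeometry(tilt_deg=30.0, axis_deg=90.0)
        point = (-2.0, 7.0)  # v = p . n = -(-2) = 2 for axis along +y
        assert cs.tilt_height_offset(point, geom) == pytest.approx(1.0, abs=1e-12)

    def test_untilted_correction_is_identity(self):
        geom = cs.TiltGeometry(tilt_deg=0.0)
        pos, defocus = cs.tilted_target_correction((3.0, 4.0), (1.0, 1.0), geom, -1.5)
        assert pos == pytest.approx((3.0, 4.0))
        assert defocus == -1.5

    def test_same_perpendicular_distance_keeps_nominal_defocus(self):
        geom = cs.TiltGeometry(tilt_deg=25.0, axis_deg=90.0)
        # axis along y: holes sharing x have equal v
        _, defocus = cs.tilted_target_correction((2.0, 9.0), (2.0, -3.0), geom, -1.5)
        assert defocus == pytest.approx(-1.5)

    def test_rotation_inverts_exactly(self):
        geom = cs.TiltGeometry(tilt_deg=33.0, axis_deg=40.0)
        inv = cs.TiltGeometry(tilt_deg=-33.0, axis_deg=40.0)
        p = np.array([3.0, -2.0, 0.0])
        q = cs.bis.tilt_point_3d(p, geom)
        back = cs.bis.tilt_point_3d(q, inv)
        assert np.abs(back - p).max() < 1e-12

    def test_plane_fit_recovers_tilt_and_axis(self):
        """Corrected defocus offsets of three targets encode (tilt, axis)."""
        geom = cs.TiltGeometry(tilt_deg=30.0, axis_deg=90.0)
        center = (0.0, 0.0)
        pts = np.array([(4.0, 0.0), (0.0, 4.0), (3.0, 5.0)])
        offsets = []
        for p in pts:
            _, defocus = cs.tilted_target_correction(tuple(p), center, geom, 0.0)
            offsets.append(defocus)
        tilt, axis = cs.recover_tilt_from_defocus(pts, np.array(offsets))
        assert tilt == pytest.approx(30.0, abs=1e-9)
        assert (axis - 90.0) % 180.0 == pytest.approx(0.0, abs=1e-9)

    def test_tilt_limit_enforced(self):
        with pytest.raises(ValueError):
            cs.TiltGeometry(tilt_deg=80.0)
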