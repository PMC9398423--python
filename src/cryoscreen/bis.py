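"""Beam-image-shift (BIS) group planning and tilted-acquisition geometry.

Several nearby holes can be exposed from a single stage position by
deflecting the beam electronically, which is far faster than moving the
stage.  The planner partitions the selected holes into groups whose
members all lie within a configurable image-shift radius of a designated
center hole, covering as many targets as possible with as few groups as
possible; a minimum group size prevents uneconomical small groups.

For tilted collection the specimen plane is modeled as rigidly rotated
about an in-plane axis: a point at signed perpendicular distance ``v``
from the axis rises by ``z = v sin(theta)`` and its in-plane coordinate
foreshortens to ``v cos(theta)``.  Per-target defocus is referenced to
the group's center hole, where autofocus runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, model_validator
from scipy.optimize import LinearConstraint, milp
from scipy.spatial import cKDTree

from .targets import HoleTarget


@dataclass
class BISGroup:
    id: int
    center_hole_id: int
    member_hole_ids: tuple[int, ...]
    radius_um: float


class TiltGeometry(BaseModel):
    """Specimen tilt: angle and the in-plane direction of the tilt axis."""

    tilt_deg: float = 0.0
    axis_deg: float = 90.0  # default: stage y-axis

    @model_validator(mode="after")
    def _check(self) -> "TiltGeometry":
        if abs(self.tilt_deg) >= 70:
            raise ValueError("|tilt_deg| must be < 70")
        return self


# ---------------------------------------------------------------------------
# planning

def plan_bis_groups(
    holes: list[HoleTarget], radius_um: float, min_group_size: int
) -> tuple[list[BISGroup], list[int]]:
    """Greedy maximum-coverage grouping of holes under a radius constraint.

    Repeatedly picks the ungrouped hole whose radius-disk covers the most
    ungrouped holes (ties by lowest hole id) and forms a group from all
    of them, stopping when no candidate reaches ``min_group_size``.
    Returns the groups plus the ids of leftover (uncovered) holes.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be positive")
    if min_group_size < 1:
        raise ValueError("min_group_size must be >= 1")
    if not holes:
        return [], []
    ids = np.array([h.id for h in holes])
    pts = np.array([h.center_um for h in holes], dtype=float)
    tree = cKDTree(pts)
    neighbors = tree.query_ball_point(pts, r=radius_um + 1e-9)
    ungrouped = set(range(len(holes)))
    groups: list[BISGroup] = []
    while ungrouped:
        best_idx, best_cover = None, None
        for idx in sorted(ungrouped, key=lambda i: ids[i]):
            cover = [j for j in neighbors[idx] if j in ungrouped]
            if best_cover is None or len(cover) > len(best_cover):
                best_idx, best_cover = idx, cover
        if best_cover is None or len(best_cover) < min_group_size:
            break
        members = tuple(sorted(int(ids[j]) for j in best_cover))
        gid = len(groups)
        groups.append(BISGroup(id=gid, center_hole_id=int(ids[best_idx]), member_hole_ids=members, radius_um=radius_um))
        ungrouped -= set(best_cover)
    leftovers = sorted(int(ids[i]) for i in ungrouped)
    by_id = {h.id: h for h in holes}
    for g in groups:
        for hid in g.member_hole_ids:
            by_id[hid].bis_group_id = g.id
    for hid in leftovers:
        by_id[hid].bis_group_id = None
    return groups, leftovers


@dataclass
class BISValidation:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_bis_plan(
    groups: list[BISGroup],
    holes: list[HoleTarget],
    radius_um: float,
    min_group_size: int,
) -> BISValidation:
    """Independent feasibility check of a BIS plan.

    Verifies the radius constraint, member disjointness, the minimum
    group size, and maximality (no leftover hole lies within the radius
    of an existing group's center hole).
    """
    report = BISValidation()
    by_id = {h.id: h for h in holes}
    seen: set[int] = set()
    for g in groups:
        if len(g.member_hole_ids) < min_group_size:
            report.violations.append(f"group {g.id}: size {len(g.member_hole_ids)} < {min_group_size}")
        if g.center_hole_id not in g.member_hole_ids:
            report.violations.append(f"group {g.id}: center hole not a member")
        center = np.array(by_id[g.center_hole_id].center_um)
        for hid in g.member_hole_ids:
            if hid in seen:
                report.violations.append(f"hole {hid}: appears in multiple groups")
            seen.add(hid)
            d = float(np.linalg.norm(np.array(by_id[hid].center_um) - center))
            if d > radius_um + 1e-9:
                report.violations.append(f"group {g.id}: hole {hid} at {d:.3f} um > radius {radius_um}")
    leftovers = [h for h in holes if h.id not in seen]
    for h in leftovers:
        for g in groups:
            center = np.array(by_id[g.center_hole_id].center_um)
            if float(np.linalg.norm(np.array(h.center_um) - center)) <= radius_um - 1e-9:
                report.violations.append(f"hole {h.id}: coverable by group {g.id} but left ungrouped")
                break
    return report


def optimal_group_count(points: np.ndarray, radius_um: float, min_group_size: int) -> tuple[int, int]:
    """Exact lexicographic optimum for small instances (oracle).

    Maximizes the number of covered holes, then minimizes the number of
    groups, over all choices of center holes and disjoint member
    assignments respecting the radius and minimum-size constraints.
    Solved as a small integer program; intended for <= ~15 points.
    Returns ``(max_covered, min_groups_at_that_coverage)``.
    """
    n = len(points)
    if n == 0:
        return 0, 0
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    in_range = d <= radius_um + 1e-9
    # variables: x[h, c] assignment (only where in range), y[c] center used
    pairs = [(h, c) for h in range(n) for c in range(n) if in_range[h, c]]
    nx = len(pairs)
    nv = nx + n
    c_obj = np.zeros(nv)
    c_obj[:nx] = -1.0  # maximize coverage
    c_obj[nx:] = 1.0 / (n + 1)  # then minimize groups
    rows, lb, ub = [], [], []
    # each hole assigned at most once
    for h in range(n):
        row = np.zeros(nv)
        for k, (hh, cc) in enumerate(pairs):
            if hh == h:
                row[k] = 1.0
        rows.append(row)
        lb.append(0.0)
        ub.append(1.0)
    # assignments only to used centers; used centers meet the minimum size
    for cidx in range(n):
        row_cap = np.zeros(nv)
        row_min = np.zeros(nv)
        for k, (hh, cc) in enumerate(pairs):
            if cc == cidx:
                row_cap[k] = 1.0
                row_min[k] = 1.0
        row_cap[nx + cidx] = -float(n)
        rows.append(row_cap)  # sum_h x <= n * y
        lb.append(-np.inf)
        ub.append(0.0)
        row_min[nx + cidx] = -float(min_group_size)
        rows.append(row_min)  # sum_h x >= min_size * y
        lb.append(0.0)
        ub.append(np.inf)
        # a used center is assigned to itself
        row_self = np.zeros(nv)
        k_self = pairs.index((cidx, cidx))
        row_self[k_self] = 1.0
        row_self[nx + cidx] = -1.0
        rows.append(row_self)
        lb.append(0.0)
        ub.append(0.0)
    cons = LinearConstraint(np.array(rows), np.array(lb), np.array(ub))
    res = milp(
        c=c_obj,
        constraints=cons,
        integrality=np.ones(nv),
        bounds=(0, 1),
    )
    if res.status != 0:
        raise RuntimeError(f"oracle MILP failed: {res.message}")
    x = np.round(res.x[:nx]).astype(int)
    y = np.round(res.x[nx:]).astype(int)
    return int(x.sum()), int(y.sum())


# ---------------------------------------------------------------------------
# tilt geometry

def _axis_vectors(geom: TiltGeometry) -> tuple[np.ndarray, np.ndarray]:
    a = math.radians(geom.axis_deg)
    u = np.array([math.cos(a), math.sin(a)])  # along the tilt axis
    n = np.array([-math.sin(a), math.cos(a)])  # perpendicular, in-plane
    return u, n


def tilt_height_offset(point_um, geom: TiltGeometry) -> float:
    """Specimen height change at a stage point due to the tilt.

    ``z = v * sin(tilt)`` with ``v`` the signed in-plane distance of the
    point from the tilt axis (taken through the stage origin).
    """
    _, n = _axis_vectors(geom)
    v = float(np.dot(np.asarray(point_um, dtype=float), n))
    return v * math.sin(math.radians(geom.tilt_deg))


def tilted_target_correction(
    hole_pos_um,
    group_center_um,
    geom: TiltGeometry,
    nominal_defocus_um: float,
) -> tuple[tuple[float, float], float]:
    """Apparent position and defocus of a hole on a tilted specimen.

    The in-plane coordinate perpendicular to the tilt axis foreshortens
    by ``cos(tilt)``.  Defocus is referenced to the group's center hole
    (where autofocus runs): ``defocus = nominal - (z_hole - z_center)``,
    with more negative meaning further underfocus.
    """
    u, n = _axis_vectors(geom)
    p = np.asarray(hole_pos_um, dtype=float)
    along = float(np.dot(p, u))
    v = float(np.dot(p, n))
    cos_t = math.cos(math.radians(geom.tilt_deg))
    apparent = along * u + (v * cos_t) * n
    z_hole = tilt_height_offset(p, geom)
    z_center = tilt_height_offset(np.asarray(group_center_um, dtype=float), geom)
    corrected = nominal_defocus_um - (z_hole - z_center)
    return (float(apparent[0]), float(apparent[1])), float(corrected)


def tilt_point_3d(point_um, geom: TiltGeometry) -> np.ndarray:
    """Rotate an (untilted) specimen-plane point into the tilted frame.

    Full 3-D rigid rotation about the in-plane axis; composing with the
    rotation at ``-tilt`` is the identity, which makes the correction
    exactly invertible.
    """
    u, n = _axis_vectors(geom)
    p = np.asarray(point_um, dtype=float)
    if p.shape[-1] == 2:
        p = np.array([p[0], p[1], 0.0])
    u3 = np.array([u[0], u[1], 0.0])
    n3 = np.array([n[0], n[1], 0.0])
    z3 = np.array([0.0, 0.0, 1.0])
    along = float(p @ u3)
    v = float(p @ n3)
    z = float(p @ z3)
    t = math.radians(geom.tilt_deg)
    v_new = v * math.cos(t) - z * math.sin(t)
    z_new = v * math.sin(t) + z * math.cos(t)
    return along * u3 + v_new * n3 + z_new * z3


def recover_tilt_from_defocus(points_um: np.ndarray, defocus_offsets_um: np.ndarray) -> tuple[float, float]:
    """Inverse oracle: fit tilt and axis from per-target defocus offsets.

    Given >= 3 non-collinear stage points and their defocus offsets
    relative to a reference (``-(z_i - z_ref)``), fits the implied height
    plane ``z = g . p + c`` and returns ``(tilt_deg, axis_deg)`` with
    ``|g| = sin(tilt)`` and the axis perpendicular to the gradient.
    """
    pts = np.asarray(points_um, dtype=float)
    z = -np.asarray(defocus_offsets_um, dtype=float)
    A = np.column_stack([pts, np.ones(len(pts))])
    coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    g = coef[:2]
    sin_t = float(np.linalg.norm(g))
    tilt = math.degrees(math.asin(min(sin_t, 1.0)))
    axis = math.degrees(math.atan2(g[1], g[0])) - 90.0
    axis = (axis + 180.0) % 360.0 - 180.0
    return tilt, axis
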