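"""Target selection: clustering, diversity-maximizing picks, offsets, defocus.

Squares are clustered 1-D on a selectable criterion (area or brightness)
and holes on their per-hole gray level (a proxy for ice thickness); the
darkest hole cluster is rejected by default.  Selection is round-robin
across clusters so the sampled targets span the diversity present on the
grid.  Every policy here is a pure deterministic function of its inputs
and the seed, which is what makes whole sessions replayable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, model_validator

from .targets import HoleTarget, SquareTarget


class SelectionPolicy(BaseModel):
    """Tunable selection parameters of one session."""

    square_criterion: str = "size"  # "size" | "brightness"
    n_squares: int = 3
    n_square_clusters: int = 3
    n_intensity_clusters: int = 5
    reject_darkest: bool = True
    n_holes_per_square: int = 0  # 0 selects every included hole (collection mode)
    random_offset_fraction: float = 0.0
    defocus_range_um: tuple[float, float] = (-1.2, -1.8)
    defocus_steps: int = 7
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SelectionPolicy":
        if self.square_criterion not in ("size", "brightness"):
            raise ValueError("square_criterion must be 'size' or 'brightness'")
        if self.reject_darkest and self.n_intensity_clusters < 2:
            raise ValueError("n_intensity_clusters must be >= 2 when reject_darkest is set")
        if not 0.0 <= self.random_offset_fraction <= 1.0:
            raise ValueError("random_offset_fraction must be in [0, 1]")
        return self


def kmeans_1d(values: np.ndarray, k: int, max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic 1-D k-means with quantile initialization.

    Centers start at the ``(i + 0.5) / k`` quantiles of the values, then
    Lloyd iterations run to convergence.  ``k`` is reduced to the number
    of distinct values when smaller.  Returns ``(assignments, centers)``
    with clusters relabeled in ascending center order, so cluster 0 is
    always the lowest-valued group.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        raise ValueError("cannot cluster zero values")
    distinct = np.unique(values)
    k = max(1, min(k, len(distinct)))
    # quantiles of the distinct values, so ties cannot collapse the init
    centers = np.quantile(distinct, (np.arange(k) + 0.5) / k)
    centers = np.unique(centers)
    k = len(centers)
    assign = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        dist = np.abs(values[:, None] - centers[None, :])
        new_assign = np.argmin(dist, axis=1)
        new_centers = centers.copy()
        for j in range(k):
            sel = new_assign == j
            if sel.any():
                new_centers[j] = values[sel].mean()
        if np.array_equal(new_assign, assign) and np.allclose(new_centers, centers):
            break
        assign, centers = new_assign, new_centers
    order = np.argsort(centers, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[assign], centers[order]


# ---------------------------------------------------------------------------
# squares

def cluster_squares(squares: list[SquareTarget], criterion: str, k: int, atlas_image: np.ndarray | None = None) -> list[SquareTarget]:
    """Cluster kept squares 1-D by area ("size") or mean gray ("brightness")."""
    if not squares:
        return squares
    if criterion == "size":
        vals = np.array([s.area_px for s in squares], dtype=float)
    elif criterion == "brightness":
        if atlas_image is None:
            raise ValueError("brightness criterion needs the atlas image")
        vals = np.array(
            [float(atlas_image[s.bbox_px[0] : s.bbox_px[2], s.bbox_px[1] : s.bbox_px[3]].mean()) for s in squares]
        )
    else:
        raise ValueError(f"unknown square criterion {criterion!r}")
    assign, _ = kmeans_1d(vals, k)
    for s, a in zip(squares, assign):
        s.cluster_id = int(a)
    return squares


def _criterion_value(s: SquareTarget) -> float:
    return float(s.area_px)


def select_square_representatives(squares: list[SquareTarget], n_squares: int) -> list[SquareTarget]:
    """Pick up to ``n_squares`` windows spread across the clusters.

    Round-robin over clusters, largest cluster first; within a cluster
    the square closest to the cluster centroid goes first, ties by lowest
    id.  Exactly ``min(n_squares, len(squares))`` squares get selected.
    """
    if n_squares < 1:
        raise ValueError("n_squares must be >= 1")
    for s in squares:
        s.selected = False
    by_cluster: dict[int, list[SquareTarget]] = {}
    for s in squares:
        by_cluster.setdefault(s.cluster_id if s.cluster_id is not None else 0, []).append(s)
    cluster_order = sorted(by_cluster, key=lambda c: (-len(by_cluster[c]), c))
    queues = []
    for c in cluster_order:
        members = by_cluster[c]
        centroid = float(np.mean([_criterion_value(s) for s in members]))
        members = sorted(members, key=lambda s: (abs(_criterion_value(s) - centroid), s.id))
        queues.append(list(members))
    want = min(n_squares, len(squares))
    picked = 0
    while picked < want:
        progressed = False
        for q in queues:
            if picked >= want:
                break
            if q:
                q.pop(0).selected = True
                picked += 1
                progressed = True
        if not progressed:
            break
    return squares


# ---------------------------------------------------------------------------
# holes

def cluster_holes(holes: list[HoleTarget], k: int) -> list[HoleTarget]:
    """Cluster non-contaminant holes on intensity; cluster 0 is the darkest."""
    eligible = [h for h in holes if not h.is_contaminant]
    if not eligible:
        return holes
    vals = np.array([h.median_intensity for h in eligible], dtype=float)
    if np.any(np.isnan(vals)):
        raise ValueError("all holes need a measured intensity before clustering")
    assign, _ = kmeans_1d(vals, k)
    for h, a in zip(eligible, assign):
        h.intensity_cluster_id = int(a)
    return holes


def apply_default_exclusion(holes: list[HoleTarget], reject_darkest: bool = True) -> list[HoleTarget]:
    """Reject the darkest intensity cluster (thick ice) when enabled.

    With fewer than two clusters present the guard leaves everything
    included; the rejection is recorded via ``status="rejected"`` and is
    reversible through the session record.
    """
    clustered = [h for h in holes if h.intensity_cluster_id is not None]
    n_clusters = len({h.intensity_cluster_id for h in clustered})
    if not reject_darkest or n_clusters < 2:
        return holes
    for h in clustered:
        if h.intensity_cluster_id == 0:
            h.status = "rejected"
            h.selected = False
    return holes


def included_holes(holes: list[HoleTarget]) -> list[HoleTarget]:
    return [h for h in holes if not h.is_contaminant and h.status != "rejected"]


def select_holes(holes: list[HoleTarget], n_holes_per_square: int) -> list[HoleTarget]:
    """Flag holes for acquisition.

    ``n == 0`` selects every included hole (exhaustive data collection);
    otherwise picks round-robin over included clusters brightest-first,
    nearest-to-centroid first within a cluster, ties by lowest id.
    Contaminant-flagged and rejected holes are never selected.
    """
    for h in holes:
        h.selected = False
    pool = included_holes(holes)
    if n_holes_per_square == 0:
        for h in pool:
            h.selected = True
        return holes
    by_cluster: dict[int, list[HoleTarget]] = {}
    for h in pool:
        by_cluster.setdefault(h.intensity_cluster_id if h.intensity_cluster_id is not None else 0, []).append(h)
    cluster_order = sorted(by_cluster, reverse=True)  # brightest first
    queues = []
    for c in cluster_order:
        members = by_cluster[c]
        centroid = float(np.mean([h.median_intensity for h in members]))
        queues.append(sorted(members, key=lambda h: (abs(h.median_intensity - centroid), h.id)))
    want = min(n_holes_per_square, len(pool))
    picked = 0
    while picked < want:
        progressed = False
        for q in queues:
            if picked >= want:
                break
            if q:
                q.pop(0).selected = True
                picked += 1
                progressed = True
        if not progressed:
            break
    return holes


# ---------------------------------------------------------------------------
# per-acquisition values

def acquisition_offset(hole: HoleTarget, random_offset_fraction: float, seed: int) -> tuple[float, float]:
    """Uniform random offset within ``fraction * radius`` of the hole center.

    Lets exposures sample different distances from the hole edge.  The
    draw is a pure function of ``(seed, parent square, hole id)``, so a
    replayed session commands identical offsets.
    """
    if not 0.0 <= random_offset_fraction <= 1.0:
        raise ValueError("random_offset_fraction must be in [0, 1]")
    if random_offset_fraction == 0.0:
        return (0.0, 0.0)
    rng = np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, (hole.parent_square_id or 0) & 0x7FFFFFFF, hole.id & 0x7FFFFFFF])
    )
    rmax = random_offset_fraction * hole.radius_um
    r = rmax * np.sqrt(rng.uniform())
    theta = rng.uniform(0.0, 2.0 * np.pi)
    return (float(r * np.cos(theta)), float(r * np.sin(theta)))


def rolling_defocus(range_um: tuple[float, float], exposure_index: int, steps: int = 7) -> float:
    """Cycle through an evenly spaced defocus ladder spanning the range.

    Index 0 returns the first endpoint; the ladder wraps every ``steps``
    exposures.  A degenerate range yields that constant value.
    """
    lo, hi = range_um
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if lo == hi or steps == 1:
        return float(lo)
    ladder = np.linspace(lo, hi, steps)
    return float(ladder[exposure_index % steps])
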