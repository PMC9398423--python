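"""Hole detection, contaminant flagging and per-hole intensity measurement.

Detection is a deterministic matched filter (disk minus annulus, sized by
the hole-diameter prior) followed by a RANSAC-style lattice fit driven by
the pitch prior.  Candidates that snap to the fitted lattice are true
hole positions; off-lattice, irregular or abnormally dark candidates are
flagged as contaminants but never deleted — downstream selection simply
ignores them.

All thresholds are relative (robust z-scores, ratios), so detection and
flagging are invariant under global affine rescaling of the image gray
levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from scipy.spatial import cKDTree
from skimage import measure
from skimage.feature import peak_local_max
from skimage.transform import resize

from .simulate import SquareView
from .targets import HoleTarget

MAX_SQUARE_PX = 1280


@dataclass
class HoleFinderConfig:
    max_image_px: int = MAX_SQUARE_PX
    response_z_threshold: float = 3.5
    peak_separation_factor: float = 0.3  # fraction of the pitch prior
    snap_tolerance_factor: float = 0.25  # fraction of the diameter prior
    darkness_z: float = 4.0  # robust z below the on-lattice intensity distribution
    min_circularity: float = 0.35
    measure_disk_factor: float = 0.8
    intensity_stat: str = "median"  # "median" per the default protocol; "mean" optional


def _disk_kernel(radius_px: float) -> np.ndarray:
    r = int(np.ceil(radius_px * 1.6)) + 1
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = yy**2 + xx**2
    inner = (d2 <= radius_px**2).astype(np.float64)
    annulus = ((d2 > radius_px**2) & (d2 <= (1.5 * radius_px) ** 2)).astype(np.float64)
    kernel = inner / inner.sum() - annulus / annulus.sum()
    return kernel


def _robust_scale(x: np.ndarray) -> tuple[float, float]:
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    return med, 1.4826 * mad if mad > 0 else 0.0


def _fit_lattice(points: np.ndarray, pitch_px: float, tol_px: float):
    """Best square lattice through the candidate points (RANSAC over pairs).

    Basis vectors are proposed from candidate pairs separated by roughly
    one pitch; the second basis vector is the 90-degree rotation of the
    first (square lattice).  The winning proposal maximizes the inlier
    count, breaking ties by lowest total snap distance then lowest
    proposing candidate ids, so the fit is fully deterministic.
    Returns ``(origin, basis, inlier_mask, snap_px)`` or ``None``.
    """
    n = len(points)
    if n < 3:
        return None
    tree = cKDTree(points)
    pairs = sorted(tree.query_pairs(1.25 * pitch_px))
    best = None
    for i, j in pairs:
        v = points[j] - points[i]
        norm = np.linalg.norm(v)
        if not (0.8 * pitch_px <= norm <= 1.25 * pitch_px):
            continue
        u = v / norm
        uperp = np.array([-u[1], u[0]])
        origin = points[i]
        d = points - origin
        a = d @ u / norm
        b = d @ uperp / norm
        res = np.hypot(a - np.round(a), b - np.round(b)) * norm
        inliers = res <= tol_px
        score = (int(inliers.sum()), -float(res[inliers].sum()), -i, -j)
        if best is None or score > best[0]:
            best = (score, origin, v, inliers, res)
    if best is None or best[0][0] < max(3, n // 10):
        return None
    _, origin, v, inliers, res = best
    return origin, v, inliers, res


def _local_shape(img: np.ndarray, r: float, c: float, radius_px: float, film_level: float) -> tuple[float, float]:
    """Estimated radius (px) and circularity of the blob at (r, c).

    The patch is denoised before thresholding and the center level taken
    as a small-neighborhood median, so the shape estimate is stable at
    realistic shot-noise levels.
    """
    half = int(np.ceil(3 * radius_px))
    r0, r1 = max(0, int(r) - half), min(img.shape[0], int(r) + half + 1)
    c0, c1 = max(0, int(c) - half), min(img.shape[1], int(c) + half + 1)
    patch = ndimage.gaussian_filter(img[r0:r1, c0:c1], max(1.0, radius_px / 3.0))
    rr, cc = int(round(r)) - r0, int(round(c)) - c0
    rr = min(max(rr, 0), patch.shape[0] - 1)
    cc = min(max(cc, 0), patch.shape[1] - 1)
    nb = patch[max(0, rr - 2) : rr + 3, max(0, cc - 2) : cc + 3]
    center_val = float(np.median(nb))
    if abs(center_val - film_level) < 1e-9:
        return radius_px, 1.0
    thresh = 0.5 * (center_val + film_level)
    mask = patch > thresh if center_val > film_level else patch < thresh
    labeled = measure.label(mask)
    lab = labeled[rr, cc]
    if lab == 0:
        return radius_px, 1.0
    region = next(rp for rp in measure.regionprops(labeled) if rp.label == lab)
    area = region.area
    perim = max(region.perimeter, 1.0)
    circ = min(1.0, 4.0 * np.pi * area / perim**2)
    return float(np.sqrt(area / np.pi)), float(circ)


def detect_holes(
    view: SquareView,
    pitch_prior_um: float,
    diameter_prior_um: float,
    config: HoleFinderConfig | None = None,
    parent_square_id: int | None = None,
) -> list[HoleTarget]:
    """Detect hole candidates in a square-level image.

    Candidate centers come from matched-filter peaks; centers consistent
    with the fitted 2-D lattice are snapped onto it and their residual is
    recorded in ``snap_distance_um`` (used later to flag off-lattice
    contaminants).  A constant image returns an empty list.  The image is
    resampled so its long side is at most 1280 px before filtering.
    """
    cfg = config or HoleFinderConfig()
    if pitch_prior_um <= diameter_prior_um or diameter_prior_um <= 0:
        raise ValueError("need pitch_prior_um > diameter_prior_um > 0")
    img = view.image.astype(np.float64)
    if np.ptp(img) < 1e-9:
        return []
    factor = 1.0
    long_side = max(img.shape)
    if long_side > cfg.max_image_px:
        factor = long_side / cfg.max_image_px
        new_shape = (int(round(img.shape[0] / factor)), int(round(img.shape[1] / factor)))
        img_w = resize(img, new_shape, order=1, anti_aliasing=True, preserve_range=True)
        factor = img.shape[0] / new_shape[0]
    else:
        img_w = img
    px_w = view.px_size_um * factor
    radius_px = (diameter_prior_um / 2.0) / px_w
    pitch_px = pitch_prior_um / px_w

    kernel = _disk_kernel(radius_px)
    response = fftconvolve(img_w, kernel[::-1, ::-1], mode="same")
    med, scale = _robust_scale(response)
    if scale <= 0:
        return []
    absdev = np.abs(response - med)
    peaks = peak_local_max(
        absdev,
        min_distance=max(1, int(cfg.peak_separation_factor * pitch_px)),
        threshold_abs=cfg.response_z_threshold * scale,
    )
    if len(peaks) == 0:
        return []
    pts = peaks.astype(float)  # (row, col)

    tol_px = cfg.snap_tolerance_factor * diameter_prior_um / px_w
    fit = _fit_lattice(pts, pitch_px, tol_px)
    film_level = med  # response median corresponds to flat film; use image median for shape
    film_gray = float(np.median(img_w))

    snapped = pts.copy()
    snap_res = np.zeros(len(pts))
    keep = np.ones(len(pts), dtype=bool)
    if fit is not None:
        origin, v, inliers, res = fit
        norm = np.linalg.norm(v)
        u = v / norm
        uperp = np.array([-u[1], u[0]])
        d = pts - origin
        a = np.round(d @ u / norm)
        b = np.round(d @ uperp / norm)
        lattice_pts = origin + np.outer(a, v) + np.outer(b, uperp * norm)
        snapped[inliers] = lattice_pts[inliers]
        snap_res = res
        # several peaks can snap to one lattice node; keep the best fit
        best_at: dict[tuple[int, int], int] = {}
        for i in np.flatnonzero(inliers):
            key = (int(a[i]), int(b[i]))
            j = best_at.get(key)
            if j is None or res[i] < res[j]:
                if j is not None:
                    keep[j] = False
                best_at[key] = i
            else:
                keep[i] = False

    holes: list[HoleTarget] = []
    order = [i for i in np.lexsort((snapped[:, 1], snapped[:, 0])) if keep[i]]
    for new_id, idx in enumerate(order):
        r_w, c_w = snapped[idx]
        est_radius_px, circ = _local_shape(img_w, pts[idx, 0], pts[idx, 1], radius_px, film_gray)
        # map working-resolution pixel back to the full-resolution raster
        r_full = (r_w + 0.5) * factor - 0.5
        c_full = (c_w + 0.5) * factor - 0.5
        xy = view.pixel_to_stage((r_full, c_full))
        holes.append(
            HoleTarget(
                id=new_id,
                parent_square_id=parent_square_id if parent_square_id is not None else view.square_id,
                center_um=(float(xy[0]), float(xy[1])),
                radius_um=float(min(est_radius_px, 1.5 * radius_px) * px_w),
                snap_distance_um=float(snap_res[idx] * px_w),
                circularity=circ,
            )
        )
    return holes


def measure_median_intensity(
    view: SquareView,
    hole: HoleTarget,
    disk_factor: float = 0.8,
    stat: str = "median",
) -> float:
    """Robust gray level of a hole: median (default) or mean over the inner disk.

    The disk radius is ``disk_factor * radius`` so the measurement avoids
    the gradient at the hole rim.  Even-sized samples use the standard
    mean-of-central-pair median.  Raises if the disk is clipped by the
    image edge.
    """
    img = view.image
    rc = view.stage_to_pixel(hole.center_um)
    r, c = float(rc[0]), float(rc[1])
    rad_px = disk_factor * hole.radius_um / view.px_size_um
    if r - rad_px < -0.5 or c - rad_px < -0.5 or r + rad_px > img.shape[0] - 0.5 or c + rad_px > img.shape[1] - 0.5:
        raise ValueError("measurement disk is clipped by the image edge")
    r0, r1 = int(np.floor(r - rad_px)), int(np.ceil(r + rad_px)) + 1
    c0, c1 = int(np.floor(c - rad_px)), int(np.ceil(c + rad_px)) + 1
    rr, cc = np.mgrid[max(r0, 0) : r1, max(c0, 0) : c1]
    mask = (rr - r) ** 2 + (cc - c) ** 2 <= rad_px**2
    vals = img[max(r0, 0) : r1, max(c0, 0) : c1][mask]
    if vals.size == 0:
        vals = np.array([img[int(round(r)), int(round(c))]])
    value = float(np.median(vals)) if stat == "median" else float(np.mean(vals))
    hole.median_intensity = value
    return value


def flag_contaminants(
    candidates: list[HoleTarget],
    view: SquareView,
    config: HoleFinderConfig | None = None,
    pitch_prior_um: float | None = None,
    diameter_prior_um: float | None = None,
) -> list[HoleTarget]:
    """Mark candidates that are contaminants rather than film holes.

    A candidate is flagged when it sits off the fitted lattice, has low
    circularity, or is extremely dark relative to the robust intensity
    distribution of the on-lattice candidates.  Flags are additive
    metadata; no candidate is ever removed.
    """
    cfg = config or HoleFinderConfig()
    if not candidates:
        return candidates
    snap_tol_um = None
    if diameter_prior_um is not None:
        snap_tol_um = cfg.snap_tolerance_factor * diameter_prior_um
    for h in candidates:
        if h.median_intensity is None:
            try:
                measure_median_intensity(view, h, cfg.measure_disk_factor, cfg.intensity_stat)
            except ValueError:
                h.median_intensity = float(view.image[tuple(np.clip(np.round(view.stage_to_pixel(h.center_um)).astype(int), 0, np.array(view.image.shape) - 1))])

    on_lattice = [h for h in candidates if h.snap_distance_um is not None and (snap_tol_um is None or h.snap_distance_um <= snap_tol_um)]
    ref = on_lattice if len(on_lattice) >= 3 else candidates
    med, scale = _robust_scale(np.array([h.median_intensity for h in ref]))
    for h in candidates:
        reasons = []
        if snap_tol_um is not None and h.snap_distance_um is not None and h.snap_distance_um > snap_tol_um:
            reasons.append("off_lattice")
        if h.circularity is not None and h.circularity < cfg.min_circularity:
            reasons.append("low_circularity")
        if scale > 0 and h.median_intensity < med - cfg.darkness_z * scale:
            reasons.append("dark")
        h.contaminant_reasons = tuple(reasons)
        h.is_contaminant = bool(reasons)
        if h.is_contaminant:
            h.selected = False
    return candidates
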