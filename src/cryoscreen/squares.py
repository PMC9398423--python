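"""Window ("square") detection and six-class quality classification.

The detector is deterministic and classical: smooth, threshold above the
bar background, close small gaps (cracks), fill interior holes
(contaminant blobs), label connected components, then prune by area,
aspect ratio and mutual overlap.  It sits behind the small
:class:`WindowDetector` interface so a learned detector could be plugged
in without touching the rest of the pipeline.

Classification assigns exactly one of six labels — ``good``, ``small``,
``cracked``, ``dry``, ``contaminated``, ``partial`` — from interpretable
features: bright-area ratio, dark-blob coverage, dark-fissure extent,
interior level relative to background, and truncation by the atlas edge.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .atlas import GridAtlas
from .targets import SquareTarget

SQUARE_CLASSES = ("good", "small", "cracked", "dry", "contaminated", "partial")


@dataclass
class SquareFinderConfig:
    """Thresholds of the classical window detector and classifier.

    Calibrated on the bundled specimen simulator; all ratios are relative
    so the pipeline is invariant to affine gray rescaling.
    """

    smooth_sigma_px: float = 2.0
    threshold_offset: float = 0.2  # fraction of (p99 - median) above the median
    min_area_px: int = 150
    aspect_bounds: tuple[float, float] = (0.8, 1.2)
    max_overlap: float = 0.3
    closing_radius_px: int = 3
    # classifier
    classify_smooth_sigma_px: float = 1.5
    small_bright_ratio: float = 0.6
    contaminated_coverage: float = 0.2
    crack_length_ratio: float = 0.5
    crack_min_dark_fraction: float = 0.005
    dry_level_fraction: float = 0.45  # window level below bg + frac*(bright-bg) => dry
    edge_margin_px: int = 2
    keep_classes: tuple[str, ...] = ("good",)


class WindowDetector(ABC):
    """Pluggable interface for window detection on an atlas."""

    @abstractmethod
    def detect(self, atlas: GridAtlas) -> list[SquareTarget]: ...


class ClassicalWindowDetector(WindowDetector):
    def __init__(self, config: SquareFinderConfig | None = None):
        self.config = config or SquareFinderConfig()

    def detect(self, atlas: GridAtlas) -> list[SquareTarget]:
        return detect_squares(atlas, self.config)


def _overlap_fraction(b1, b2) -> float:
    r0 = max(b1[0], b2[0])
    c0 = max(b1[1], b2[1])
    r1 = min(b1[2], b2[2])
    c1 = min(b1[3], b2[3])
    if r1 <= r0 or c1 <= c0:
        return 0.0
    inter = (r1 - r0) * (c1 - c0)
    a1 = (b1[2] - b1[0]) * (b1[3] - b1[1])
    a2 = (b2[2] - b2[0]) * (b2[3] - b2[1])
    return inter / min(a1, a2)


def detect_squares(atlas: GridAtlas, config: SquareFinderConfig | None = None) -> list[SquareTarget]:
    """Find candidate windows as bright connected regions of the atlas.

    Returns targets with geometry set and ``class_label`` unset.  A
    featureless (constant) atlas yields an empty list.  Candidates whose
    bounding-box aspect ratio falls outside the configured 0.8-1.2 band
    are suppressed, as are near-duplicates overlapping by more than 30%.
    """
    cfg = config or SquareFinderConfig()
    img = atlas.image.astype(np.float32)
    lo, med, hi = np.percentile(img, [1, 50, 99])
    if hi - med < 1e-6:  # constant image: no features
        return []
    smoothed = ndimage.gaussian_filter(img, cfg.smooth_sigma_px)
    thresh = med + cfg.threshold_offset * (hi - med)
    mask = smoothed > thresh
    mask = morphology.closing(mask, morphology.disk(cfg.closing_radius_px))
    mask = ndimage.binary_fill_holes(mask)
    labeled = measure.label(mask)
    candidates: list[SquareTarget] = []
    for region in measure.regionprops(labeled):
        if region.area < cfg.min_area_px:
            continue
        r0, c0, r1, c1 = region.bbox
        aspect = (c1 - c0) / (r1 - r0)
        if not (cfg.aspect_bounds[0] <= aspect <= cfg.aspect_bounds[1]):
            continue
        cr, cc = region.centroid
        cx, cy = atlas.pixel_to_stage((cr, cc))
        candidates.append(
            SquareTarget(
                id=-1,
                center_um=(float(cx), float(cy)),
                bbox_px=(r0, c0, r1, c1),
                area_px=int(region.area),
            )
        )
    # greedy overlap suppression, larger area wins
    candidates.sort(key=lambda s: (-s.area_px, s.bbox_px))
    kept: list[SquareTarget] = []
    for cand in candidates:
        if all(_overlap_fraction(cand.bbox_px, k.bbox_px) <= cfg.max_overlap for k in kept):
            kept.append(cand)
    # stable ids in raster order
    kept.sort(key=lambda s: s.bbox_px)
    for i, s in enumerate(kept):
        s.id = i
    return kept


def classify_square(
    atlas: GridAtlas,
    sq: SquareTarget,
    nominal_area_px: float,
    config: SquareFinderConfig | None = None,
) -> tuple[str, float]:
    """Assign one of the six quality classes to a detected window.

    Decision features, checked in order: atlas-edge truncation (partial),
    near-background interior (dry), reduced bright area (small), dark-blob
    coverage (contaminated), elongated dark fissure (cracked), else good.
    Returns ``(label, score)`` and stores both on the target.
    """
    cfg = config or SquareFinderConfig()
    img = atlas.image
    r0, c0, r1, c1 = sq.bbox_px
    h, w = r1 - r0, c1 - c0
    side = max(h, w)
    patch = ndimage.gaussian_filter(img[r0:r1, c0:c1].astype(np.float32), cfg.classify_smooth_sigma_px)

    def done(label: str, score: float) -> tuple[str, float]:
        sq.class_label = label
        sq.class_score = float(np.clip(score, 0.0, 1.0))
        return label, sq.class_score

    m = cfg.edge_margin_px
    if r0 <= m or c0 <= m or r1 >= img.shape[0] - m or c1 >= img.shape[1] - m:
        return done("partial", 1.0)

    bg = float(np.median(img))
    bright_ref = float(np.percentile(img, 99))
    window_level = float(np.percentile(patch, 90))
    if window_level < bg + cfg.dry_level_fraction * (bright_ref - bg):
        return done("dry", 1.0 - (window_level - bg) / max(bright_ref - bg, 1e-9))

    mid = bg + 0.5 * (window_level - bg)
    interior = patch[m:-m, m:-m] if h > 2 * m and w > 2 * m else patch
    bright = interior > mid
    dark = ~bright
    dark_fraction = float(dark.mean())

    # a "small" window has a shrunken bright region: its row/col span is a
    # fraction of the detected bbox.  Contaminant blobs leave the bright
    # span intact, so the two features do not interfere.
    if bright.any():
        rows = np.flatnonzero(bright.any(axis=1))
        cols = np.flatnonzero(bright.any(axis=0))
        span_ratio = ((rows[-1] - rows[0] + 1) / bright.shape[0]) * ((cols[-1] - cols[0] + 1) / bright.shape[1])
    else:
        span_ratio = 0.0
    if span_ratio < cfg.small_bright_ratio:
        return done("small", 1.0 - span_ratio / cfg.small_bright_ratio)

    # contaminant blobs are compact dark components (a crack is thin and
    # elongated, so its low filled fraction keeps it out of the coverage)
    blob_coverage = 0.0
    if dark_fraction > 0:
        labeled = measure.label(dark)
        for region in measure.regionprops(labeled):
            if region.extent > 0.35:
                blob_coverage += region.area
        blob_coverage /= dark.size
    if blob_coverage > cfg.contaminated_coverage:
        return done("contaminated", min(1.0, blob_coverage / (2 * cfg.contaminated_coverage)))

    # a fissure is thin, so it survives only light smoothing; noise pixels
    # cannot form components long enough to trip the length criterion
    patch_c = ndimage.gaussian_filter(img[r0:r1, c0:c1].astype(np.float32), 0.5)
    interior_c = patch_c[m:-m, m:-m] if h > 2 * m and w > 2 * m else patch_c
    dark_c = interior_c < mid
    if float(dark_c.mean()) > cfg.crack_min_dark_fraction:
        labeled = measure.label(dark_c)
        max_extent = 0.0
        for region in measure.regionprops(labeled):
            rr0, cc0, rr1, cc1 = region.bbox
            max_extent = max(max_extent, float(np.hypot(rr1 - rr0, cc1 - cc0)))
        if max_extent >= cfg.crack_length_ratio * side:
            return done("cracked", min(1.0, max_extent / side))

    return done("good", 1.0 - dark_fraction)


def classify_all(atlas: GridAtlas, squares: list[SquareTarget], nominal_area_px: float, config: SquareFinderConfig | None = None) -> list[SquareTarget]:
    for sq in squares:
        classify_square(atlas, sq, nominal_area_px, config)
    return squares


def filter_suboptimal(
    squares: list[SquareTarget], keep_classes: tuple[str, ...] = ("good",)
) -> tuple[list[SquareTarget], list[SquareTarget]]:
    """Partition classified windows into usable and excluded sets.

    Excluded windows get ``status="excluded"`` but stay in the session
    record; they are never queued or acquired.
    """
    kept, excluded = [], []
    for sq in squares:
        if sq.class_label is None:
            raise ValueError(f"square {sq.id} is not classified")
        if sq.class_label in keep_classes:
            kept.append(sq)
        else:
            sq.status = "excluded"
            excluded.append(sq)
    return kept, excluded
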