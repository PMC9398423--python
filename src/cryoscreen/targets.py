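"""Target records shared across detection, selection and the session engine."""

from __future__ import annotations

from dataclasses import dataclass, field

SQUARE_STATUSES = ("detected", "excluded", "queued", "acquired", "completed")
HOLE_STATUSES = ("detected", "rejected", "queued", "acquired", "completed", "failed")


@dataclass
class SquareTarget:
    """A detected grid window (region of interest)."""

    id: int
    center_um: tuple[float, float]
    bbox_px: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    area_px: int
    class_label: str | None = None
    class_score: float = 0.0
    cluster_id: int | None = None
    selected: bool = False
    status: str = "detected"

    @property
    def aspect_ratio(self) -> float:
        r0, c0, r1, c1 = self.bbox_px
        h, w = r1 - r0, c1 - c0
        return w / h if h else float("inf")


@dataclass
class HoleTarget:
    """A detected hole (target of interest) within one square."""

    id: int
    parent_square_id: int
    center_um: tuple[float, float]
    radius_um: float
    median_intensity: float | None = None
    is_contaminant: bool = False
    contaminant_reasons: tuple[str, ...] = ()
    intensity_cluster_id: int | None = None
    bis_group_id: int | None = None
    selected: bool = False
    status: str = "detected"
    applied_offset_um: tuple[float, float] = (0.0, 0.0)
    applied_defocus_um: float | None = None
    tilt_deg: float = 0.0
    snap_distance_um: float | None = None  # residual to the fitted lattice
    circularity: float | None = None
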