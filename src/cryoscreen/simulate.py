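"""Synthetic cryo-EM specimen simulator with exhaustive ground truth.

Emulates the imagery a screening microscope produces at three scales:

* **atlas tiles** — low-magnification views of a bar/window support grid,
  with square windows rendered in one of six quality classes
  (``good``, ``small``, ``cracked``, ``dry``, ``contaminated``, ``partial``);
* **square views** — medium magnification images of one window showing the
  periodic hole lattice of a holey support film (default 1.2 um holes on a
  2.5 um pitch), a smooth ice-thickness gradient that modulates each hole's
  gray level, and randomly placed dark contaminant blobs;
* **high-magnification views** — flat-field exposures of a single hole.

Gray convention: higher gray level means more electron transmission and
thus thinner ice; "darkest" always means lowest gray value.  All
randomness flows from the single integer seed in :class:`SyntheticSpec`
through named :class:`numpy.random.Generator` instances, so identical
specs yield bit-identical images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

SQUARE_CLASSES = ("good", "small", "cracked", "dry", "contaminated", "partial")

# Rendering gray levels (8-bit-like scale, stored as float32).
BAR_GRAY = 60.0
FILM_GRAY = 100.0
WINDOW_GRAY = 170.0
DRY_GRAY = 90.0
CRACK_GRAY = 45.0
BLOB_GRAY = 35.0


class SyntheticSpec(BaseModel):
    """Parameters of one simulated specimen grid.

    Defaults describe a typical holey-film single-particle specimen:
    90 um window pitch, 40 um windows, 1.2 um holes on a 2.5 um pitch,
    imaged as a 6 x 6 tile atlas with 10% tile overlap.
    """

    grid_pitch_um: float = 90.0
    square_size_um: float = 40.0
    hole_diameter_um: float = 1.2
    hole_pitch_um: float = 2.5
    n_tiles: int = 6
    tile_px: int = 256
    atlas_px_size_um: float = 0.6
    square_px_size_um: float = 0.04
    tile_overlap: float = 0.10
    class_probabilities: dict[str, float] = Field(
        default_factory=lambda: {
            "good": 0.55,
            "small": 0.12,
            "cracked": 0.08,
            "dry": 0.08,
            "contaminated": 0.10,
            "partial": 0.07,
        }
    )
    ice_gradient_direction: tuple[float, float] = (1.0, 0.0)
    ice_intensity_range: tuple[float, float] = (120.0, 200.0)
    contaminant_density: float = 3.0
    noise_sigma: float = 2.0
    seed: int = 0

    @field_validator("class_probabilities")
    @classmethod
    def _check_probs(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(SQUARE_CLASSES)
        if unknown:
            raise ValueError(f"unknown square classes: {sorted(unknown)}")
        if any(p < 0 for p in v.values()):
            raise ValueError("class probabilities must be non-negative")
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")
        return v

    @model_validator(mode="after")
    def _check_geometry(self) -> "SyntheticSpec":
        if not self.hole_pitch_um > self.hole_diameter_um:
            raise ValueError("hole_pitch_um must exceed hole_diameter_um")
        if not self.square_size_um < self.grid_pitch_um:
            raise ValueError("square_size_um must be smaller than grid_pitch_um")
        if not 0.0 <= self.tile_overlap < 1.0:
            raise ValueError("tile_overlap must be in [0, 1)")
        return self

    # -- derived geometry ------------------------------------------------
    @property
    def tile_size_um(self) -> float:
        return self.tile_px * self.atlas_px_size_um

    @property
    def tile_stride_um(self) -> float:
        return (1.0 - self.tile_overlap) * self.tile_size_um

    @property
    def field_um(self) -> float:
        """Side length of the stage region covered by the full tile mosaic."""
        return self.tile_stride_um * (self.n_tiles - 1) + self.tile_size_um

    @property
    def squares_per_axis(self) -> int:
        return int(math.floor((self.field_um - self.square_size_um) / self.grid_pitch_um)) + 1


@dataclass
class SquareTruth:
    """Ground truth for one window: stage-frame center, extent and class."""

    id: int
    center_um: tuple[float, float]
    size_um: float
    class_label: str


@dataclass
class HoleTruth:
    """Ground truth for one hole or contaminant blob within a square."""

    id: int
    center_um: tuple[float, float]  # stage frame
    radius_um: float
    intensity: float  # noiseless median gray level
    is_contaminant: bool


@dataclass
class Tile:
    id: int
    image: np.ndarray  # float32 (tile_px, tile_px)
    center_um: tuple[float, float]  # stage position of the tile center
    px_size_um: float


@dataclass
class GroundTruth:
    spec: SyntheticSpec
    squares: list[SquareTruth]
    field_um: float

    def squares_of_class(self, label: str) -> list[SquareTruth]:
        return [s for s in self.squares if s.class_label == label]


# ---------------------------------------------------------------------------
# helpers

def _rng(spec: SyntheticSpec, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, *stream]))


def _apply_noise(img: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson shot noise on the gray-level base plus additive Gaussian.

    ``sigma == 0`` disables both components so that noiseless renders are
    exact, which the oracle tests rely on.
    """
    if sigma <= 0:
        return img.astype(np.float32)
    noisy = rng.poisson(np.clip(img, 0, None)).astype(np.float32)
    noisy += rng.normal(0.0, sigma, size=img.shape).astype(np.float32)
    return noisy


def ice_intensity_at(spec: SyntheticSpec, point_um) -> float:
    """Noiseless hole gray level from the linear ice-thickness ramp.

    The ramp runs across the full grid field along the configured
    direction; the configured intensity range is attained at the field's
    extreme projections.
    """
    g = np.asarray(spec.ice_gradient_direction, dtype=float)
    g = g / np.linalg.norm(g)
    corners = np.array(
        [[0.0, 0.0], [spec.field_um, 0.0], [0.0, spec.field_um], [spec.field_um, spec.field_um]]
    )
    projs = corners @ g
    lo_p, hi_p = projs.min(), projs.max()
    t = (np.asarray(point_um, dtype=float) @ g - lo_p) / (hi_p - lo_p) if hi_p > lo_p else 0.0
    lo_i, hi_i = spec.ice_intensity_range
    return float(lo_i + np.clip(t, 0.0, 1.0) * (hi_i - lo_i))


def hole_lattice(spec: SyntheticSpec, square: SquareTruth) -> np.ndarray:
    """Stage-frame centers of all lattice holes whose center lies inside the window.

    The lattice is aligned to the stage axes and anchored at the window
    center; centers on the window boundary count as inside (closed window).
    """
    half = square.size_um / 2.0
    kmax = int(math.floor(half / spec.hole_pitch_um + 1e-9))
    offs = np.arange(-kmax, kmax + 1) * spec.hole_pitch_um
    gx, gy = np.meshgrid(offs, offs, indexing="ij")
    pts = np.column_stack([gx.ravel() + square.center_um[0], gy.ravel() + square.center_um[1]])
    return pts


# ---------------------------------------------------------------------------
# atlas generation

def _layout_squares(spec: SyntheticSpec) -> list[tuple[float, float]]:
    n = spec.squares_per_axis
    if n < 1:
        raise ValueError("square grid does not fit in the tiled field of view")
    span = (n - 1) * spec.grid_pitch_um
    start = (spec.field_um - span) / 2.0
    centers = []
    for j in range(n):  # y
        for i in range(n):  # x
            centers.append((start + i * spec.grid_pitch_um, start + j * spec.grid_pitch_um))
    return centers


def _assign_classes(spec: SyntheticSpec, n: int, rng: np.random.Generator) -> list[str]:
    labels = sorted(spec.class_probabilities)
    probs = np.array([spec.class_probabilities[label] for label in labels])
    idx = rng.choice(len(labels), size=n, p=probs)
    return [labels[i] for i in idx]


def _partial_shift(center: tuple[float, float], size: float, field: float) -> tuple[float, float]:
    """Move a window so ~15% of its width hangs past the nearest field edge."""
    x, y = center
    overhang = 0.15 * size
    dists = {"left": x, "right": field - x, "bottom": y, "top": field - y}
    side = min(dists, key=dists.get)
    if side == "left":
        return (size / 2.0 - overhang, y)
    if side == "right":
        return (field - size / 2.0 + overhang, y)
    if side == "bottom":
        return (x, size / 2.0 - overhang)
    return (x, field - size / 2.0 + overhang)


def _render_field(spec: SyntheticSpec, squares: list[SquareTruth], rng: np.random.Generator) -> np.ndarray:
    """Noiseless full-field atlas-resolution render of all windows."""
    px = spec.atlas_px_size_um
    n_px = int(round(spec.field_um / px))
    img = np.full((n_px, n_px), BAR_GRAY, dtype=np.float32)

    def to_rc(x: float, y: float) -> tuple[float, float]:
        return ((spec.field_um - y) / px, x / px)

    for sq in squares:
        cx, cy = sq.center_um
        half = sq.size_um / 2.0
        r0, c0 = to_rc(cx - half, cy + half)
        r1, c1 = to_rc(cx + half, cy - half)
        ri0, ri1 = max(0, int(round(r0))), min(n_px, int(round(r1)))
        ci0, ci1 = max(0, int(round(c0))), min(n_px, int(round(c1)))
        if ri1 <= ri0 or ci1 <= ci0:
            continue
        h, w = ri1 - ri0, ci1 - ci0
        label = sq.class_label
        if label == "dry":
            img[ri0:ri1, ci0:ci1] = DRY_GRAY
            continue
        if label == "small":
            # reduced bright area inside a faint full-size outline
            img[ri0:ri1, ci0:ci1] = DRY_GRAY
            shrink = 0.6
            mr, mc = int(h * (1 - shrink) / 2), int(w * (1 - shrink) / 2)
            img[ri0 + mr : ri1 - mr, ci0 + mc : ci1 - mc] = WINDOW_GRAY
            continue
        img[ri0:ri1, ci0:ci1] = WINDOW_GRAY
        if label == "cracked":
            # dark fissure polyline crossing the window
            n_seg = 8
            ys = np.linspace(ri0 + 1, ri1 - 2, n_seg)
            xs = ci0 + w * (0.5 + 0.25 * rng.uniform(-1, 1, size=n_seg))
            width = max(2, int(round(0.03 * w)))
            for k in range(n_seg - 1):
                steps = max(int(ys[k + 1] - ys[k]) + 1, 2)
                for t in np.linspace(0, 1, steps):
                    r = int(round(ys[k] + t * (ys[k + 1] - ys[k])))
                    c = int(round(xs[k] + t * (xs[k + 1] - xs[k])))
                    img[r, max(ci0, c - width // 2) : min(ci1, c + width // 2 + 1)] = CRACK_GRAY
        elif label == "contaminated":
            # dark blobs covering >= 20% of the window
            rr, cc = np.mgrid[ri0:ri1, ci0:ci1]
            for _ in range(3):
                br = 0.24 * min(h, w)
                bc_r = rng.uniform(ri0 + br, ri1 - br)
                bc_c = rng.uniform(ci0 + br, ci1 - br)
                mask = (rr - bc_r) ** 2 + (cc - bc_c) ** 2 <= br**2
                img[ri0:ri1, ci0:ci1][mask] = BLOB_GRAY
    return img


def generate_atlas(spec: SyntheticSpec) -> tuple[list[Tile], GroundTruth]:
    """Render the tile mosaic and its ground truth for one simulated grid.

    Returns ``n_tiles**2`` tiles with exact stage-center positions plus a
    :class:`GroundTruth` listing every window with its class label.  Raises
    ``ValueError`` if not even one window pitch fits in the tiled field.
    """
    rng_cls = _rng(spec, 1)
    rng_render = _rng(spec, 2)
    centers = _layout_squares(spec)
    labels = _assign_classes(spec, len(centers), rng_cls)
    squares = []
    for i, (c, label) in enumerate(zip(centers, labels)):
        if label == "partial":
            c = _partial_shift(c, spec.square_size_um, spec.field_um)
        squares.append(SquareTruth(id=i, center_um=c, size_um=spec.square_size_um, class_label=label))
    field_img = _render_field(spec, squares, rng_render)

    tiles: list[Tile] = []
    px = spec.atlas_px_size_um
    n_px = field_img.shape[0]
    for j in range(spec.n_tiles):  # y, bottom to top
        for i in range(spec.n_tiles):  # x, left to right
            x0 = i * spec.tile_stride_um
            y0 = j * spec.tile_stride_um
            cx = x0 + spec.tile_size_um / 2.0
            cy = y0 + spec.tile_size_um / 2.0
            # pixel window in the field render (row 0 = top = max y)
            c0 = int(round(x0 / px))
            r0 = int(round((spec.field_um - y0 - spec.tile_size_um) / px))
            c0 = min(max(c0, 0), n_px - spec.tile_px)
            r0 = min(max(r0, 0), n_px - spec.tile_px)
            sub = field_img[r0 : r0 + spec.tile_px, c0 : c0 + spec.tile_px].copy()
            tid = j * spec.n_tiles + i
            sub = _apply_noise(sub, spec.noise_sigma, _rng(spec, 3, tid))
            tiles.append(Tile(id=tid, image=sub, center_um=(cx, cy), px_size_um=px))
    return tiles, GroundTruth(spec=spec, squares=squares, field_um=spec.field_um)


# ---------------------------------------------------------------------------
# square-level views

RENDERABLE_CLASSES = frozenset(SQUARE_CLASSES) - {"dry"}


@dataclass
class SquareView:
    image: np.ndarray  # float32
    px_size_um: float
    center_um: tuple[float, float]  # stage position of the image center
    square_id: int

    def stage_to_pixel(self, xy) -> np.ndarray:
        arr = np.asarray(xy, dtype=float)
        single = arr.ndim == 1
        arr = np.atleast_2d(arr)
        n = self.image.shape[0]
        rc = np.empty_like(arr)
        rc[:, 1] = (arr[:, 0] - self.center_um[0]) / self.px_size_um + (n - 1) / 2.0
        rc[:, 0] = (self.center_um[1] - arr[:, 1]) / self.px_size_um + (n - 1) / 2.0
        return rc[0] if single else rc

    def pixel_to_stage(self, rc) -> np.ndarray:
        arr = np.asarray(rc, dtype=float)
        single = arr.ndim == 1
        arr = np.atleast_2d(arr)
        n = self.image.shape[0]
        xy = np.empty_like(arr)
        xy[:, 0] = (arr[:, 1] - (n - 1) / 2.0) * self.px_size_um + self.center_um[0]
        xy[:, 1] = self.center_um[1] - (arr[:, 0] - (n - 1) / 2.0) * self.px_size_um
        return xy[0] if single else xy


def generate_square_view(spec: SyntheticSpec, square: SquareTruth) -> tuple[SquareView, list[HoleTruth]]:
    """Render the hole lattice of one window plus contaminant blobs.

    Each hole is drawn as a uniform disk whose gray level is the ice ramp
    value at its center, so a noiseless median measurement recovers the
    truth exactly.  ``dry`` windows carry no film and are rejected.
    """
    if square.class_label == "dry":
        raise ValueError("dry windows render no hole lattice")
    rng = _rng(spec, 4, square.id)
    px = spec.square_px_size_um
    size = square.size_um
    fov = 1.3 * size
    n_px = int(round(fov / px))
    img = np.full((n_px, n_px), BAR_GRAY, dtype=np.float32)
    view = SquareView(image=img, px_size_um=px, center_um=square.center_um, square_id=square.id)

    # film extends slightly past the window so rim holes are fully supported
    half_film = size / 2.0 + spec.hole_diameter_um
    rc0 = view.stage_to_pixel((square.center_um[0] - half_film, square.center_um[1] + half_film))
    rc1 = view.stage_to_pixel((square.center_um[0] + half_film, square.center_um[1] - half_film))
    img[int(rc0[0]) : int(rc1[0]) + 1, int(rc0[1]) : int(rc1[1]) + 1] = FILM_GRAY

    holes: list[HoleTruth] = []
    radius = spec.hole_diameter_um / 2.0
    rr, cc = np.mgrid[0:n_px, 0:n_px]
    lattice = hole_lattice(spec, square)
    for hid, center in enumerate(lattice):
        val = ice_intensity_at(spec, center)
        holes.append(HoleTruth(id=hid, center_um=(float(center[0]), float(center[1])), radius_um=radius, intensity=val, is_contaminant=False))
        r, c = view.stage_to_pixel(center)
        mask = (rr - r) ** 2 + (cc - c) ** 2 <= (radius / px) ** 2
        img[mask] = val

    # contaminants: irregular dark blobs placed off-lattice inside the window
    n_cont = rng.poisson(spec.contaminant_density)
    placed = 0
    attempts = 0
    next_id = len(holes)
    while placed < n_cont and attempts < 50 * max(n_cont, 1):
        attempts += 1
        half = size / 2.0 - spec.hole_diameter_um
        pos = np.array(square.center_um) + rng.uniform(-half, half, size=2)
        snapped = np.round((pos - np.array(square.center_um)) / spec.hole_pitch_um) * spec.hole_pitch_um + np.array(square.center_um)
        if np.linalg.norm(pos - snapped) < 0.35 * spec.hole_pitch_um:
            continue
        brad = rng.uniform(0.3, 0.7)
        r, c = view.stage_to_pixel(pos)
        # union of jittered disks -> irregular, low-circularity blob
        mask = np.zeros_like(img, dtype=bool)
        for _ in range(3):
            jr = r + rng.uniform(-0.5, 0.5) * brad / px
            jc = c + rng.uniform(-0.5, 0.5) * brad / px
            sub_rad = rng.uniform(0.6, 1.0) * brad / px
            mask |= (rr - jr) ** 2 + (cc - jc) ** 2 <= sub_rad**2
        img[mask] = BLOB_GRAY
        holes.append(HoleTruth(id=next_id, center_um=(float(pos[0]), float(pos[1])), radius_um=brad, intensity=BLOB_GRAY, is_contaminant=True))
        next_id += 1
        placed += 1

    view.image = _apply_noise(img, spec.noise_sigma, rng)
    return view, holes


# ---------------------------------------------------------------------------
# high-magnification views

@dataclass
class HighMagTruth:
    hole_id: int
    offset_um: tuple[float, float]
    tilt_deg: float
    true_intensity: float


def generate_highmag_view(
    spec: SyntheticSpec,
    hole: HoleTruth,
    offset_um: tuple[float, float] = (0.0, 0.0),
    tilt_deg: float = 0.0,
    size_px: int = 64,
) -> tuple[np.ndarray, HighMagTruth]:
    """Flat-field exposure of one hole at an optional in-hole offset and tilt.

    The image mean equals the hole's true gray level up to noise; the truth
    records the commanded offset and tilt so workflow tests can audit the
    acquisition.  Offsets beyond the hole radius are invalid acquisition
    points and raise ``ValueError``.
    """
    off = np.asarray(offset_um, dtype=float)
    if np.linalg.norm(off) > hole.radius_um + 1e-12:
        raise ValueError("acquisition offset falls outside the hole")
    rng = _rng(spec, 5, hole.id)
    img = np.full((size_px, size_px), hole.intensity, dtype=np.float32)
    img = _apply_noise(img, spec.noise_sigma, rng)
    truth = HighMagTruth(hole_id=hole.id, offset_um=(float(off[0]), float(off[1])), tilt_deg=float(tilt_deg), true_intensity=hole.intensity)
    return img, truth
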