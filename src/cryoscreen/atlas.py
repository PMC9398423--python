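"""Atlas stitching and coordinate bookkeeping.

Tiles are placed purely by their known stage positions (translation only);
overlapping pixels are resolved last-writer.  The stitched atlas carries an
invertible affine transform between pixel and stage coordinates and is
downsampled so its long side never exceeds ``MAX_ATLAS_PX`` before any
detection runs on it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from skimage.transform import resize

from .geometry import AffineTransform
from .simulate import Tile

MAX_ATLAS_PX = 2048


@dataclass
class GridAtlas:
    image: np.ndarray  # float32, (rows, cols)
    px_size_um: float
    transform: AffineTransform  # pixel (row, col) -> stage (x, y) um
    tiles: list[tuple[int, tuple[float, float]]] = field(default_factory=list)  # (tile id, stage center)

    def pixel_to_stage(self, rc) -> np.ndarray:
        return self.transform.pixel_to_stage(rc)

    def stage_to_pixel(self, xy) -> np.ndarray:
        return self.transform.stage_to_pixel(xy)

    def save(self, path_base: Path | str) -> None:
        """Persist as TIFF image plus a JSON sidecar with the transform."""
        base = Path(path_base)
        tifffile.imwrite(base.with_suffix(".tiff"), self.image.astype(np.float32))
        meta = {
            "px_size_um": self.px_size_um,
            "transform": {"matrix": self.transform.matrix, "offset": self.transform.offset},
            "tiles": [{"id": t, "center_um": list(c)} for t, c in self.tiles],
        }
        base.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path_base: Path | str) -> "GridAtlas":
        base = Path(path_base)
        image = tifffile.imread(base.with_suffix(".tiff"))
        meta = json.loads(base.with_suffix(".json").read_text())
        tr = AffineTransform(
            matrix=tuple(tuple(r) for r in meta["transform"]["matrix"]),
            offset=tuple(meta["transform"]["offset"]),
        )
        tiles = [(t["id"], tuple(t["center_um"])) for t in meta["tiles"]]
        return cls(image=image, px_size_um=meta["px_size_um"], transform=tr, tiles=tiles)


def stitch_tiles(tiles: list[Tile], max_px: int = MAX_ATLAS_PX) -> GridAtlas:
    """Stitch tiles into one atlas by their stage positions.

    All tiles must share a pixel size; the mosaic extent is the union of
    tile footprints.  The atlas is downsampled if its long side exceeds
    ``max_px``, with the transform rescaled to match.
    """
    if not tiles:
        raise ValueError("need at least one tile")
    px = tiles[0].px_size_um
    if any(abs(t.px_size_um - px) > 1e-12 for t in tiles):
        raise ValueError("tiles have inconsistent pixel sizes")

    half = {t.id: (t.image.shape[0] * px / 2.0, t.image.shape[1] * px / 2.0) for t in tiles}
    x_min = min(t.center_um[0] - half[t.id][1] for t in tiles)
    x_max = max(t.center_um[0] + half[t.id][1] for t in tiles)
    y_min = min(t.center_um[1] - half[t.id][0] for t in tiles)
    y_max = max(t.center_um[1] + half[t.id][0] for t in tiles)

    n_rows = int(round((y_max - y_min) / px))
    n_cols = int(round((x_max - x_min) / px))
    canvas = np.zeros((n_rows, n_cols), dtype=np.float32)
    for t in tiles:
        # top-left corner of the tile in stage um
        tx = t.center_um[0] - half[t.id][1]
        ty = t.center_um[1] + half[t.id][0]
        r0 = int(round((y_max - ty) / px))
        c0 = int(round((tx - x_min) / px))
        r0 = min(max(r0, 0), n_rows - t.image.shape[0])
        c0 = min(max(c0, 0), n_cols - t.image.shape[1])
        canvas[r0 : r0 + t.image.shape[0], c0 : c0 + t.image.shape[1]] = t.image

    transform = AffineTransform.from_pixel_size(px, (x_min + px / 2.0, y_max - px / 2.0))
    atlas = GridAtlas(
        image=canvas,
        px_size_um=px,
        transform=transform,
        tiles=[(t.id, t.center_um) for t in tiles],
    )
    long_side = max(canvas.shape)
    if long_side > max_px:
        factor = long_side / max_px
        new_shape = (int(round(canvas.shape[0] / factor)), int(round(canvas.shape[1] / factor)))
        atlas.image = resize(canvas, new_shape, order=1, anti_aliasing=True, preserve_range=True).astype(np.float32)
        real_factor = canvas.shape[0] / new_shape[0]
        atlas.px_size_um = px * real_factor
        atlas.transform = transform.scaled(real_factor)
    return atlas


def center_out_tile_order(tiles: list[Tile]) -> list[Tile]:
    """Order tiles by distance of their center from the mosaic center.

    Used for partial atlases: taking the first ``fraction * len(tiles)``
    tiles of this order yields a centered, roughly isotropic coverage.
    """
    cx = float(np.mean([t.center_um[0] for t in tiles]))
    cy = float(np.mean([t.center_um[1] for t in tiles]))
    return sorted(tiles, key=lambda t: ((t.center_um[0] - cx) ** 2 + (t.center_um[1] - cy) ** 2, t.id))


def partial_tiles(tiles: list[Tile], fraction: float) -> list[Tile]:
    """Center-out subset of tiles covering at least ``fraction`` of the mosaic."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    ordered = center_out_tile_order(tiles)
    n = max(1, int(np.ceil(fraction * len(tiles))))
    return ordered[:n]
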