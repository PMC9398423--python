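"""Pixel <-> stage coordinate transforms.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, col)`` with the origin at the
  top-left of the image;
* stage coordinates are right-handed micrometres with ``x`` pointing
  rightward and ``y`` pointing upward.

A raster stored top-to-bottom therefore has its row axis antiparallel to
the stage ``y`` axis, which the affine matrix encodes explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class AffineTransform:
    """Affine map from pixel ``(row, col)`` to stage ``(x, y)`` in um.

    ``stage = matrix @ (row, col) + offset``.  The matrix must be
    invertible; for the simple scaled/flipped rasters produced here it is
    ``[[0, s], [-s, 0]]`` with ``s`` the pixel size in um.
    """

    matrix: tuple[tuple[float, float], tuple[float, float]]
    offset: tuple[float, float]

    @classmethod
    def from_pixel_size(cls, px_size_um: float, top_left_stage_um: tuple[float, float]) -> "AffineTransform":
        """Transform for a raster whose pixel (0, 0) sits at ``top_left_stage_um``."""
        s = float(px_size_um)
        return cls(matrix=((0.0, s), (-s, 0.0)), offset=(float(top_left_stage_um[0]), float(top_left_stage_um[1])))

    def _m(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)

    def pixel_to_stage(self, rc) -> np.ndarray:
        """Map pixel ``(row, col)`` (or an (N, 2) array) to stage um."""
        rc = np.asarray(rc, dtype=float)
        return rc @ self._m().T + np.asarray(self.offset, dtype=float)

    def stage_to_pixel(self, xy) -> np.ndarray:
        """Inverse map; may return out-of-bounds (fractional) pixel coords."""
        xy = np.asarray(xy, dtype=float)
        inv = np.linalg.inv(self._m())
        return (xy - np.asarray(self.offset, dtype=float)) @ inv.T

    def scaled(self, factor: float) -> "AffineTransform":
        """Transform for the same stage frame after resampling pixels by ``factor``.

        ``factor > 1`` means coarser pixels (downsampling by that factor).
        """
        m = self._m() * factor
        return AffineTransform(matrix=((m[0, 0], m[0, 1]), (m[1, 0], m[1, 1])), offset=self.offset)
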