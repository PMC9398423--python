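"""Shared fixtures: one simulated grid, stitched atlas, and a square view.

Everything is generated at test time from a fixed seed; nothing is read
from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

import cryoscreen as cs


@pytest.fixture(scope="session")
def spec() -> cs.SyntheticSpec:
    return cs.SyntheticSpec(seed=0)


@pytest.fixture(scope="session")
def grid(spec):
    tiles, truth = cs.generate_atlas(spec)
    return tiles, truth


@pytest.fixture(scope="session")
def atlas(grid):
    tiles, _ = grid
    return cs.stitch_tiles(tiles)


@pytest.fixture(scope="session")
def good_square(grid):
    _, truth = grid
    return next(s for s in truth.squares if s.class_label == "good")


@pytest.fixture(scope="session")
def square_view(spec, good_square):
    return cs.generate_square_view(spec, good_square)


@pytest.fixture(scope="session")
def detected_holes(spec, square_view):
    view, truth = square_view
    holes = cs.detect_holes(view, spec.hole_pitch_um, spec.hole_diameter_um)
    for h in holes:
        try:
            cs.measure_median_intensity(view, h)
        except ValueError:
            h.median_intensity = float(np.median(view.image))
    cs.flag_contaminants(holes, view, None, spec.hole_pitch_um, spec.hole_diameter_um)
    return holes
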