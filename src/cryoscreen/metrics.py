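"""Detector benchmarking against simulator ground truth.

Runs the full detection stack over freshly simulated grids and scores it
against the generator's ground truth: square detection precision/recall,
per-class classification accuracy, hole recall and false-positive rate,
and contaminant-flagging recall.  Used by the test suite and the
reproduction script; every number is recomputed at call time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .atlas import stitch_tiles
from .holes import HoleFinderConfig, detect_holes, flag_contaminants, measure_median_intensity
from .simulate import SyntheticSpec, generate_atlas, generate_square_view
from .squares import SquareFinderConfig, classify_all, detect_squares


@dataclass
class DetectorBenchmark:
    n_grids: int = 0
    n_true_squares: int = 0
    square_matches: int = 0
    square_detections: int = 0
    square_false_positives: int = 0
    class_hits: dict[str, list[bool]] = field(default_factory=dict)
    n_true_holes: int = 0
    hole_matches: int = 0
    hole_detections: int = 0
    hole_false_positives: int = 0
    n_true_contaminants: int = 0
    contaminants_flagged: int = 0
    true_holes_flagged: int = 0

    @property
    def square_recall(self) -> float:
        return self.square_matches / max(self.n_true_squares, 1)

    @property
    def square_precision(self) -> float:
        return 1.0 - self.square_false_positives / max(self.square_detections, 1)

    @property
    def class_accuracy(self) -> dict[str, float]:
        return {k: float(np.mean(v)) for k, v in self.class_hits.items()}

    @property
    def min_class_accuracy(self) -> float:
        acc = self.class_accuracy
        return min(acc.values()) if acc else 0.0

    @property
    def hole_recall(self) -> float:
        return self.hole_matches / max(self.n_true_holes, 1)

    @property
    def hole_false_positive_rate(self) -> float:
        return self.hole_false_positives / max(self.hole_detections, 1)

    @property
    def contaminant_recall(self) -> float:
        return self.contaminants_flagged / max(self.n_true_contaminants, 1)

    @property
    def true_hole_flag_rate(self) -> float:
        return self.true_holes_flagged / max(self.n_true_holes, 1)


def benchmark_detectors(
    seeds,
    holes_squares_per_grid: int = 2,
    square_config: SquareFinderConfig | None = None,
    hole_config: HoleFinderConfig | None = None,
) -> DetectorBenchmark:
    """Score the detectors over one simulated grid per seed.

    Hole metrics are measured on ``holes_squares_per_grid`` good squares
    per grid, matched at a quarter hole diameter; contaminant flags are
    matched at 0.5 um (blobs have irregular, off-center peaks).
    """
    bench = DetectorBenchmark()
    for seed in seeds:
        spec = SyntheticSpec(seed=int(seed))
        tiles, truth = generate_atlas(spec)
        atlas = stitch_tiles(tiles)
        dets = detect_squares(atlas, square_config)
        nominal = (spec.square_size_um / atlas.px_size_um) ** 2
        classify_all(atlas, dets, nominal, square_config)
        bench.n_grids += 1
        sq_tol = spec.square_size_um / 2.0
        true_pts = np.array([s.center_um for s in truth.squares])
        bench.n_true_squares += len(true_pts)
        if dets:
            det_pts = np.array([s.center_um for s in dets])
            d_t, idx = cKDTree(det_pts).query(true_pts)
            bench.square_matches += int((d_t < sq_tol).sum())
            d_d, _ = cKDTree(true_pts).query(det_pts)
            bench.square_false_positives += int((d_d >= sq_tol).sum())
            bench.square_detections += len(dets)
            for i, t in enumerate(truth.squares):
                if d_t[i] < sq_tol:
                    bench.class_hits.setdefault(t.class_label, []).append(dets[idx[i]].class_label == t.class_label)

        goods = [s for s in truth.squares if s.class_label == "good"][:holes_squares_per_grid]
        for sq in goods:
            view, hole_truth = generate_square_view(spec, sq)
            cand = detect_holes(view, spec.hole_pitch_um, spec.hole_diameter_um, hole_config)
            for h in cand:
                try:
                    measure_median_intensity(view, h)
                except ValueError:
                    h.median_intensity = float(np.median(view.image))
            flag_contaminants(cand, view, hole_config, spec.hole_pitch_um, spec.hole_diameter_um)
            true_holes = np.array([h.center_um for h in hole_truth if not h.is_contaminant])
            conts = [h for h in hole_truth if h.is_contaminant]
            tol = 0.25 * spec.hole_diameter_um
            unflagged = [h for h in cand if not h.is_contaminant]
            flagged = [h for h in cand if h.is_contaminant]
            bench.n_true_holes += len(true_holes)
            bench.n_true_contaminants += len(conts)
            if unflagged:
                pos = np.array([h.center_um for h in unflagged])
                d, _ = cKDTree(pos).query(true_holes)
                bench.hole_matches += int((d < tol).sum())
                d2, _ = cKDTree(true_holes).query(pos)
                bench.hole_false_positives += int((d2 >= tol).sum())
                bench.hole_detections += len(unflagged)
            if flagged:
                fpos = np.array([h.center_um for h in flagged])
                if conts:
                    d3, _ = cKDTree(fpos).query(np.array([h.center_um for h in conts]))
                    bench.contaminants_flagged += int((d3 < 0.5).sum())
                d4, _ = cKDTree(true_holes).query(fpos)
                bench.true_holes_flagged += int((d4 < tol).sum())
    return bench
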