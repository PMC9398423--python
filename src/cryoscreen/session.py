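"""Screening / data-collection workflow engine with a mock microscope.

Drives the full unattended loop for a list of grids: atlas acquisition,
window detection/classification/selection, per-window hole finding and
ice-thickness clustering, beam-image-shift planning, and tilt-corrected
high-magnification acquisition — all against a narrow
:class:`MicroscopeInterface` whose only shipped implementation is the
simulator-backed mock.  Acquired images are handed to an asynchronous
FIFO processing queue so acquisition never blocks on analysis.

Everything that happens is appended to a timestamped event log; given
the same configuration and seed a session replays the identical sequence
of selections, plans and acquisitions (timestamps aside).
"""

from __future__ import annotations

import json
import queue
import threading
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import stario
from .atlas import GridAtlas, partial_tiles, stitch_tiles
from .bis import BISGroup, TiltGeometry, plan_bis_groups, tilted_target_correction
from .holes import HoleFinderConfig, detect_holes, flag_contaminants, measure_median_intensity
from .select import (
    SelectionPolicy,
    acquisition_offset,
    apply_default_exclusion,
    cluster_holes,
    cluster_squares,
    included_holes,
    rolling_defocus,
    select_holes,
    select_square_representatives,
)
from .simulate import GroundTruth, HoleTruth, SquareView, SyntheticSpec, Tile, generate_atlas, generate_highmag_view, generate_square_view
from .squares import SquareFinderConfig, classify_all, detect_squares, filter_suboptimal
from .targets import HoleTarget, SquareTarget


class MicroscopeLockedError(RuntimeError):
    """A second workflow tried to run on a locked microscope."""


class MicroscopeFault(RuntimeError):
    """Transient hardware failure on one target."""


class GridDescriptor(BaseModel):
    name: str
    spec: SyntheticSpec


class SessionConfig(BaseModel):
    """All tunable parameters of one screening or collection session."""

    grids: list[GridDescriptor]
    mode: str = "screening"  # "screening" | "collection"
    policy: SelectionPolicy = Field(default_factory=SelectionPolicy)
    bis_radius_um: float = 4.0
    min_group_size: int = 4
    tilt: TiltGeometry = Field(default_factory=TiltGeometry)
    atlas_fraction: float = 1.0
    pause_between_grids: bool = False
    drift_threshold_A_per_s: float = 1.0
    keep_square_classes: tuple[str, ...] = ("good",)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SessionConfig":
        if self.mode not in ("screening", "collection"):
            raise ValueError("mode must be 'screening' or 'collection'")
        if not 0.25 <= self.atlas_fraction <= 1.0:
            raise ValueError("atlas_fraction must be in [0.25, 1]")
        if self.drift_threshold_A_per_s <= 0:
            raise ValueError("drift_threshold_A_per_s must be positive")
        return self

    @classmethod
    def from_yaml(cls, path: Path | str) -> "SessionConfig":
        import yaml

        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# microscope interface + mock

class MicroscopeInterface:
    """Narrow hardware contract the workflow drives.

    The lock enforces single-client use: concurrent workflow execution
    against one microscope is refused.
    """

    def __init__(self) -> None:
        self._lock = threading.Lock()

    def acquire_lock(self) -> None:
        if not self._lock.acquire(blocking=False):
            raise MicroscopeLockedError("microscope is locked by another workflow")

    def release_lock(self) -> None:
        if self._lock.locked():
            self._lock.release()

    # hardware verbs — implemented by concrete microscopes
    def load_grid(self, grid: GridDescriptor) -> None: ...
    def move_stage(self, xy_um) -> None: ...
    def eucentric(self) -> None: ...
    def acquire_tile(self, tile_id: int) -> Tile: ...
    def acquire_square(self, sq: SquareTarget) -> SquareView: ...
    def acquire_view(self, hole: HoleTarget) -> np.ndarray: ...
    def autofocus(self) -> None: ...
    def measure_drift(self) -> float: ...
    def set_image_shift(self, xy_um) -> None: ...
    def set_defocus(self, defocus_um: float) -> None: ...
    def set_tilt(self, tilt_deg: float) -> None: ...
    def acquire_highmag(self, hole: HoleTarget, offset_um, tilt_deg: float) -> np.ndarray: ...


class MockMicroscope(MicroscopeInterface):
    """Simulator-backed microscope with configurable imperfections.

    ``positioning_error_um`` is the initial recentering error injected
    after each stage move; it shrinks by ``positioning_decay`` with every
    corrective move.  Drift after a stage move starts at
    ``drift_initial_A_per_s`` and halves with each poll (plus seeded
    noise).  ``fail_hole_ids`` makes high-magnification acquisition raise
    a :class:`MicroscopeFault` for those hole ids to exercise the
    failure path.
    """

    def __init__(
        self,
        positioning_error_um: float = 0.0,
        positioning_decay: float = 0.3,
        drift_initial_A_per_s: float = 4.0,
        drift_decay: float = 0.5,
        fail_hole_ids: frozenset[tuple[str, int, int]] = frozenset(),
        seed: int = 0,
    ) -> None:
        super().__init__()
        self.positioning_error_um = positioning_error_um
        self.positioning_decay = positioning_decay
        self.drift_initial = drift_initial_A_per_s
        self.drift_decay = drift_decay
        self.fail_hole_ids = fail_hole_ids
        self.rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 99]))
        self.grid: GridDescriptor | None = None
        self.tiles: list[Tile] = []
        self.truth: GroundTruth | None = None
        self.stage_um = (0.0, 0.0)
        self.tilt_deg = 0.0
        self.defocus_um = 0.0
        self.image_shift_um = (0.0, 0.0)
        self._pos_error = 0.0
        self._drift_polls = 0
        self._square_views: dict[int, SquareView] = {}

    def load_grid(self, grid: GridDescriptor) -> None:
        self.grid = grid
        self.tiles, self.truth = generate_atlas(grid.spec)
        self._square_views = {}

    def move_stage(self, xy_um) -> None:
        self.stage_um = (float(xy_um[0]), float(xy_um[1]))
        self._drift_polls = 0

    def eucentric(self) -> None:  # mocked: no optics
        pass

    def acquire_tile(self, tile_id: int) -> Tile:
        return self.tiles[tile_id]

    def _nearest_truth_square(self, center_um):
        assert self.truth is not None
        c = np.asarray(center_um, dtype=float)
        best = min(self.truth.squares, key=lambda s: float(np.linalg.norm(np.array(s.center_um) - c)))
        return best

    def acquire_square(self, sq: SquareTarget) -> SquareView:
        truth_sq = self._nearest_truth_square(sq.center_um)
        if truth_sq.id not in self._square_views:
            view, _ = generate_square_view(self.grid.spec, truth_sq)
            self._square_views[truth_sq.id] = view
        self._pos_error = self.positioning_error_um
        return self._square_views[truth_sq.id]

    def begin_target(self) -> None:
        """Stage settled on a new target: reset injected error and drift."""
        self._pos_error = self.positioning_error_um
        self._drift_polls = 0

    def apparent_offset(self, hole: HoleTarget) -> tuple[float, float]:
        """Offset of the target from the image center seen in a view image."""
        return (self._pos_error, 0.0)

    def acquire_view(self, hole: HoleTarget) -> np.ndarray:
        # a small centering view; the offset measurement is served by
        # apparent_offset, the raster itself is a flat field
        return np.full((32, 32), hole.median_intensity or 100.0, dtype=np.float32)

    def correct_position(self) -> None:
        self._pos_error *= self.positioning_decay

    def autofocus(self) -> None:
        pass

    def measure_drift(self) -> float:
        rate = self.drift_initial * (self.drift_decay**self._drift_polls)
        rate += abs(float(self.rng.normal(0.0, 0.02)))
        self._drift_polls += 1
        return float(rate)

    def set_image_shift(self, xy_um) -> None:
        self.image_shift_um = (float(xy_um[0]), float(xy_um[1]))

    def set_defocus(self, defocus_um: float) -> None:
        self.defocus_um = float(defocus_um)

    def set_tilt(self, tilt_deg: float) -> None:
        self.tilt_deg = float(tilt_deg)

    def acquire_highmag(self, hole: HoleTarget, offset_um, tilt_deg: float) -> np.ndarray:
        key = (self.grid.name if self.grid else "", hole.parent_square_id, hole.id)
        if key in self.fail_hole_ids:
            raise MicroscopeFault(f"injected fault on hole {key}")
        truth = HoleTruth(
            id=hole.id,
            center_um=hole.center_um,
            radius_um=hole.radius_um,
            intensity=hole.median_intensity if hole.median_intensity is not None else 100.0,
            is_contaminant=False,
        )
        img, _ = generate_highmag_view(self.grid.spec, truth, offset_um=offset_um, tilt_deg=tilt_deg)
        return img


# ---------------------------------------------------------------------------
# async processing queue

def default_processor(item: dict) -> dict:
    """Fill the record's processing stubs: image stats plus CTF placeholders."""
    img = item["image"]
    return {
        "image_mean": float(np.mean(img)),
        "image_std": float(np.std(img)),
        "ctf_defocus_um": None,  # external CTF fitting is out of scope
        "ctf_resolution_A": None,
    }


class ProcessingQueue:
    """FIFO queue processed sequentially on a separate thread.

    ``enqueue`` is O(1) and never blocks, so acquisition order is
    independent of processing speed.  A failure on one item marks that
    item failed without stopping the worker.
    """

    def __init__(self, processor: Callable[[dict], dict] = default_processor, delay_s: float = 0.0) -> None:
        self.processor = processor
        self.delay_s = delay_s
        self._q: queue.Queue = queue.Queue()
        self.results: list[dict] = []
        self._thread = threading.Thread(target=self._work, daemon=True)
        self._closed = False
        self._thread.start()

    def enqueue(self, item: dict) -> None:
        if self._closed:
            raise RuntimeError("queue already drained")
        self._q.put(item)

    def _work(self) -> None:
        while True:
            item = self._q.get()
            if item is None:
                break
            if self.delay_s:
                time.sleep(self.delay_s)
            out = {"key": item.get("key")}
            try:
                out.update(self.processor(item))
                out["processing_status"] = "ok"
            except Exception as exc:  # noqa: BLE001 - one bad item must not stop the queue
                out["processing_status"] = f"failed: {exc}"
            self.results.append(out)

    def drain(self) -> list[dict]:
        """Block until everything queued so far is processed; return results."""
        self._q.put(None)
        self._closed = True
        self._thread.join()
        return self.results


# ---------------------------------------------------------------------------
# session record

@dataclass
class GridRecord:
    name: str
    atlas: GridAtlas | None = None
    squares: list[SquareTarget] = field(default_factory=list)
    holes: dict[int, list[HoleTarget]] = field(default_factory=dict)  # square id -> holes
    bis_groups: dict[int, list[BISGroup]] = field(default_factory=dict)
    acquisitions: list[dict] = field(default_factory=list)
    processing: list[dict] = field(default_factory=list)


@dataclass
class SessionRecord:
    config: SessionConfig
    grids: list[GridRecord] = field(default_factory=list)
    events: list[dict] = field(default_factory=list)
    _seq: int = 0

    def log(self, event: str, **fields) -> None:
        self._seq += 1
        entry = {"seq": self._seq, "t": time.time(), "event": event}
        entry.update(fields)
        self.events.append(entry)

    def event_names(self) -> list[str]:
        return [e["event"] for e in self.events]

    def write_events(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            for e in self.events:
                fh.write(json.dumps(e) + "\n")


# ---------------------------------------------------------------------------
# workflow pieces

def recenter_on_target(
    microscope,
    hole: HoleTarget,
    max_iterations: int = 3,
    tolerance_fraction: float = 0.1,
) -> bool:
    """Iteratively recenter the imaging area on a hole.

    Acquires a view, measures the apparent offset of the hole from the
    image center and corrects the stage, stopping once the offset is
    below ``tolerance_fraction * radius``.  Returns ``False`` (target
    failed) if the offset has not converged after ``max_iterations``.
    """
    tol = tolerance_fraction * hole.radius_um
    for _ in range(max_iterations):
        microscope.acquire_view(hole)
        off = np.asarray(microscope.apparent_offset(hole), dtype=float)
        if float(np.linalg.norm(off)) <= tol:
            return True
        microscope.move_stage((hole.center_um[0] + off[0], hole.center_um[1] + off[1]))
        if hasattr(microscope, "correct_position"):
            microscope.correct_position()
    microscope.acquire_view(hole)
    off = np.asarray(microscope.apparent_offset(hole), dtype=float)
    return float(np.linalg.norm(off)) <= tol


def wait_for_drift(microscope, threshold_A_per_s: float, max_polls: int = 50) -> tuple[float, bool]:
    """Poll the drift rate until it settles below the threshold.

    Returns ``(final_rate, settled)``; ``settled`` is ``False`` on
    timeout after ``max_polls`` polls.
    """
    if threshold_A_per_s <= 0:
        raise ValueError("drift threshold must be positive")
    rate = float("inf")
    for _ in range(max_polls):
        rate = microscope.measure_drift()
        if rate <= threshold_A_per_s:
            return rate, True
    return rate, False


# ---------------------------------------------------------------------------
# the session loop

def run_session(
    config: SessionConfig,
    microscope: MicroscopeInterface | None = None,
    processing_delay_s: float = 0.0,
    pause_callback: Callable[[str], None] | None = None,
    square_config: SquareFinderConfig | None = None,
    hole_config: HoleFinderConfig | None = None,
) -> SessionRecord:
    """Run the whole multi-grid workflow and return its audit record.

    For each grid: atlas -> square detection/classification/clustering/
    selection -> per selected square: hole detection, contaminant
    flagging, intensity clustering, darkest-cluster rejection, hole
    selection -> BIS planning -> per group: stage move, recentering,
    autofocus + drift settling -> per member: image shift, tilt-corrected
    defocus, acquisition, enqueue for asynchronous processing.  Hardware
    faults on single targets mark them failed and the session continues.
    """
    microscope = microscope or MockMicroscope(seed=config.seed)
    microscope.acquire_lock()
    record = SessionRecord(config=config)
    sq_cfg = square_config or SquareFinderConfig(keep_classes=config.keep_square_classes)
    hl_cfg = hole_config or HoleFinderConfig()
    exposure_index = 0
    try:
        for g_idx, grid in enumerate(config.grids):
            record.log("grid_load", grid=grid.name)
            microscope.load_grid(grid)
            grec = GridRecord(name=grid.name)
            record.grids.append(grec)

            tiles = [microscope.acquire_tile(t.id) for t in partial_tiles(microscope.tiles, config.atlas_fraction)]
            atlas = stitch_tiles(tiles)
            grec.atlas = atlas
            record.log("atlas_done", grid=grid.name, n_tiles=len(tiles))

            squares = detect_squares(atlas, sq_cfg)
            nominal_area_px = (grid.spec.square_size_um / atlas.px_size_um) ** 2
            classify_all(atlas, squares, nominal_area_px, sq_cfg)
            kept, excluded = filter_suboptimal(squares, config.keep_square_classes)
            record.log(
                "squares_done",
                grid=grid.name,
                n_detected=len(squares),
                n_kept=len(kept),
                n_excluded=len(excluded),
            )
            grec.squares = squares
            if not kept:
                record.log("warning", grid=grid.name, message="no usable squares; empty target list")
                continue

            cluster_squares(kept, config.policy.square_criterion, config.policy.n_square_clusters, atlas.image)
            select_square_representatives(kept, config.policy.n_squares)
            selected_squares = [s for s in kept if s.selected]
            record.log("squares_selected", grid=grid.name, ids=[s.id for s in selected_squares])

            pq = ProcessingQueue(delay_s=processing_delay_s)
            n_holes = 0 if config.mode == "collection" else config.policy.n_holes_per_square
            for sq in selected_squares:
                sq.status = "queued"
                microscope.move_stage(sq.center_um)
                microscope.eucentric()
                view = microscope.acquire_square(sq)
                sq.status = "acquired"
                record.log("square_acquired", grid=grid.name, square=sq.id)

                holes = detect_holes(view, grid.spec.hole_pitch_um, grid.spec.hole_diameter_um, hl_cfg, parent_square_id=sq.id)
                for h in holes:
                    try:
                        measure_median_intensity(view, h, hl_cfg.measure_disk_factor, hl_cfg.intensity_stat)
                    except ValueError:
                        h.median_intensity = float(np.median(view.image))
                flag_contaminants(holes, view, hl_cfg, grid.spec.hole_pitch_um, grid.spec.hole_diameter_um)
                cluster_holes([h for h in holes if not h.is_contaminant], config.policy.n_intensity_clusters)
                apply_default_exclusion(holes, config.policy.reject_darkest)
                select_holes(holes, n_holes)
                grec.holes[sq.id] = holes
                selected = [h for h in holes if h.selected]
                record.log(
                    "holes_done",
                    grid=grid.name,
                    square=sq.id,
                    n_detected=len(holes),
                    n_contaminant=sum(h.is_contaminant for h in holes),
                    n_rejected=sum(h.status == "rejected" for h in holes),
                    n_selected=len(selected),
                )

                groups, leftovers = plan_bis_groups(selected, config.bis_radius_um, config.min_group_size)
                grec.bis_groups[sq.id] = groups
                record.log("bis_planned", grid=grid.name, square=sq.id, n_groups=len(groups), n_leftover=len(leftovers))
                for hid in leftovers:
                    h = next(hh for hh in selected if hh.id == hid)
                    h.selected = False

                by_id = {h.id: h for h in holes}
                microscope.set_tilt(config.tilt.tilt_deg)
                for group in groups:
                    center_hole = by_id[group.center_hole_id]
                    microscope.move_stage(center_hole.center_um)
                    if hasattr(microscope, "begin_target"):
                        microscope.begin_target()
                    centered = recenter_on_target(microscope, center_hole)
                    if not centered:
                        for hid in group.member_hole_ids:
                            by_id[hid].status = "failed"
                        record.log("group_failed", grid=grid.name, square=sq.id, group=group.id, reason="recentering")
                        continue
                    microscope.autofocus()
                    rate, settled = wait_for_drift(microscope, config.drift_threshold_A_per_s)
                    if not settled:
                        for hid in group.member_hole_ids:
                            by_id[hid].status = "failed"
                        record.log("group_failed", grid=grid.name, square=sq.id, group=group.id, reason="drift_timeout")
                        continue
                    for hid in group.member_hole_ids:
                        hole = by_id[hid]
                        hole.status = "queued"
                        shift = (
                            hole.center_um[0] - center_hole.center_um[0],
                            hole.center_um[1] - center_hole.center_um[1],
                        )
                        nominal = rolling_defocus(config.policy.defocus_range_um, exposure_index, config.policy.defocus_steps)
                        _, defocus = tilted_target_correction(hole.center_um, center_hole.center_um, config.tilt, nominal)
                        offset = acquisition_offset(hole, config.policy.random_offset_fraction, config.policy.seed)
                        microscope.set_image_shift(shift)
                        microscope.set_defocus(defocus)
                        try:
                            img = microscope.acquire_highmag(hole, offset, config.tilt.tilt_deg)
                        except MicroscopeFault as exc:
                            hole.status = "failed"
                            record.log("hole_failed", grid=grid.name, square=sq.id, hole=hid, reason=str(exc))
                            continue
                        exposure_index += 1
                        hole.status = "acquired"
                        hole.applied_offset_um = offset
                        hole.applied_defocus_um = defocus
                        hole.tilt_deg = config.tilt.tilt_deg
                        acq = {
                            "grid": grid.name,
                            "square_id": sq.id,
                            "hole_id": hid,
                            "stage_x_um": center_hole.center_um[0],
                            "stage_y_um": center_hole.center_um[1],
                            "image_shift_x_um": shift[0],
                            "image_shift_y_um": shift[1],
                            "offset_x_um": offset[0],
                            "offset_y_um": offset[1],
                            "defocus_um": defocus,
                            "tilt_deg": config.tilt.tilt_deg,
                            "drift_A_per_s": rate,
                            "bis_group_id": group.id,
                            "is_center": hid == group.center_hole_id,
                            "timestamp": time.time(),
                        }
                        grec.acquisitions.append(acq)
                        record.log("hole_acquired", grid=grid.name, square=sq.id, hole=hid, group=group.id)
                        pq.enqueue({"key": (grid.name, sq.id, hid), "image": img})
                sq.status = "completed"

            grec.processing = pq.drain()
            done_keys = {r["key"]: r for r in grec.processing if r.get("processing_status") == "ok"}
            for sq_id, holes in grec.holes.items():
                for h in holes:
                    if h.status == "acquired" and (grid.name, sq_id, h.id) in done_keys:
                        h.status = "completed"
            record.log("grid_done", grid=grid.name, n_acquisitions=len(grec.acquisitions))
            if config.pause_between_grids and g_idx < len(config.grids) - 1:
                record.log("pause", grid=grid.name)
                if pause_callback is not None:
                    pause_callback(grid.name)
    finally:
        microscope.release_lock()
    record.log("session_done")
    return record


# ---------------------------------------------------------------------------
# exports

def export_star(record: SessionRecord) -> str:
    """Serialize the session record as STAR loop tables.

    One block per level — squares, holes, acquisitions — with stable,
    documented columns; re-parsing and re-writing is byte-identical.
    """
    sq_rows = []
    for grec in record.grids:
        for s in grec.squares:
            sq_rows.append(
                {
                    "grid": grec.name,
                    "square_id": s.id,
                    "center_x_um": float(s.center_um[0]),
                    "center_y_um": float(s.center_um[1]),
                    "area_px": s.area_px,
                    "class_label": s.class_label or "unset",
                    "class_score": float(s.class_score),
                    "cluster_id": -1 if s.cluster_id is None else s.cluster_id,
                    "selected": int(s.selected),
                    "status": s.status,
                }
            )
    hole_rows = []
    for grec in record.grids:
        for sq_id, holes in grec.holes.items():
            for h in holes:
                hole_rows.append(
                    {
                        "grid": grec.name,
                        "square_id": sq_id,
                        "hole_id": h.id,
                        "center_x_um": float(h.center_um[0]),
                        "center_y_um": float(h.center_um[1]),
                        "radius_um": float(h.radius_um),
                        "median_intensity": float("nan") if h.median_intensity is None else float(h.median_intensity),
                        "is_contaminant": int(h.is_contaminant),
                        "intensity_cluster_id": -1 if h.intensity_cluster_id is None else h.intensity_cluster_id,
                        "bis_group_id": -1 if h.bis_group_id is None else h.bis_group_id,
                        "selected": int(h.selected),
                        "status": h.status,
                    }
                )
    acq_rows = []
    for grec in record.grids:
        for a in grec.acquisitions:
            row = {k: v for k, v in a.items() if k != "timestamp"}
            row["is_center"] = int(row["is_center"])
            acq_rows.append(row)
    blocks = {
        "squares": pd.DataFrame(sq_rows),
        "holes": pd.DataFrame(hole_rows),
        "acquisitions": pd.DataFrame(acq_rows),
    }
    return stario.write_star(blocks)


def export_report(record: SessionRecord) -> dict:
    """JSON-ready summary: per-class counts, clusters, selections, timings."""
    report: dict = {"mode": record.config.mode, "n_grids": len(record.grids), "grids": []}
    for grec in record.grids:
        class_counts: dict[str, int] = {}
        for s in grec.squares:
            class_counts[s.class_label or "unset"] = class_counts.get(s.class_label or "unset", 0) + 1
        holes = [h for hs in grec.holes.values() for h in hs]
        grid_events = [e for e in record.events if e.get("grid") == grec.name]
        report["grids"].append(
            {
                "name": grec.name,
                "n_squares_detected": len(grec.squares),
                "square_class_counts": class_counts,
                "n_squares_selected": sum(s.selected for s in grec.squares),
                "n_holes_detected": len(holes),
                "n_contaminants": sum(h.is_contaminant for h in holes),
                "n_holes_rejected": sum(h.status == "rejected" for h in holes),
                "n_holes_selected": sum(h.selected for h in holes),
                "n_bis_groups": sum(len(g) for g in grec.bis_groups.values()),
                "n_acquisitions": len(grec.acquisitions),
                "elapsed_s": (grid_events[-1]["t"] - grid_events[0]["t"]) if grid_events else 0.0,
            }
        )
    return report
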