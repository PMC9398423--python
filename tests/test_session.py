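"""Workflow engine: locking, recentering, drift, queue, exports, replay."""

import numpy as np
import pytest

import cryoscreen as cs
from cryoscreen import stario
from cryoscreen.session import ProcessingQueue, default_processor
from cryoscreen.targets import HoleTarget


def _session_config(seed=3, mode="collection", n_squares=1, **kw):
    spec = cs.SyntheticSpec(seed=seed, contaminant_density=2.0)
    return cs.SessionConfig(
        grids=[cs.GridDescriptor(name="g1", spec=spec)],
        mode=mode,
        policy=cs.SelectionPolicy(n_squares=n_squares, seed=7),
        seed=11,
        **kw,
    )


@pytest.fixture(scope="module")
def collection_run():
    cfg = _session_config()
    record = cs.run_session(cfg)
    return cfg, record


class TestRecentering:
    def test_zero_error_converges_immediately(self):
        scope = cs.MockMicroscope(positioning_error_um=0.0)
        hole = HoleTarget(id=0, parent_square_id=0, center_um=(0, 0), radius_um=0.6)
        assert cs.recenter_on_target(scope, hole)

    def test_decaying_error_converges_within_three_iterations(self):
        # 0.5 um error decaying by 0.3: 0.5 -> 0.15 -> 0.045 < 0.1 * 0.6
        scope = cs.MockMicroscope(positioning_error_um=0.5, positioning_decay=0.3)
        scope.begin_target()
        hole = HoleTarget(id=0, parent_square_id=0, center_um=(0, 0), radius_um=0.6)
        assert cs.recenter_on_target(scope, hole, max_iterations=3)

    def test_persistent_error_takes_failure_path(self):
        scope = cs.MockMicroscope(positioning_error_um=1.0, positioning_decay=1.0)
        scope.begin_target()
        hole = HoleTarget(id=0, parent_square_id=0, center_um=(0, 0), radius_um=0.6)
        assert not cs.recenter_on_target(scope, hole, max_iterations=3)


class TestDrift:
    def test_already_settled_returns_immediately(self):
        scope = cs.MockMicroscope(drift_initial_A_per_s=0.5)
        rate, settled = cs.wait_for_drift(scope, 1.0)
        assert settled and rate <= 1.0

    def test_decaying_drift_settles_in_finite_polls(self):
        scope = cs.MockMicroscope(drift_initial_A_per_s=10.0, drift_decay=0.5)
        rate, settled = cs.wait_for_drift(scope, 1.0)
        assert settled and rate <= 1.0

    def test_zero_threshold_rejected(self):
        with pytest.raises(ValueError):
            cs.wait_for_drift(cs.MockMicroscope(), 0.0)


class TestProcessingQueue:
    def test_fifo_order_preserved(self):
        pq = ProcessingQueue(processor=lambda item: {"v": item["v"]})
        for v in "ABC":
            pq.enqueue({"key": v, "v": v})
        results = pq.drain()
        assert [r["key"] for r in results] == ["A", "B", "C"]

    def test_failed_item_does_not_stop_queue(self):
        def flaky(item):
            if item["key"] == "B":
                raise RuntimeError("boom")
            return {}

        pq = ProcessingQueue(processor=flaky)
        for v in "ABC":
            pq.enqueue({"key": v})
        results = pq.drain()
        assert [r["key"] for r in results] == ["A", "B", "C"]
        assert results[1]["processing_status"].startswith("failed")
        assert results[0]["processing_status"] == "ok"

    def test_empty_drain_is_noop(self):
        assert ProcessingQueue().drain() == []

    def test_default_processor_fills_stub_fields(self):
        out = default_processor({"image": np.ones((4, 4))})
        assert out["image_mean"] == 1.0 and out["image_std"] == 0.0
        assert out["ctf_defocus_um"] is None


class TestSessionRuns:
    def test_collection_mode_one_acquisition_per_included_hole(self, collection_run):
        _, record = collection_run
        grec = record.grids[0]
        holes = [h for hs in grec.holes.values() for h in hs]
        included_selected = [h for h in holes if h.selected]
        assert len(grec.acquisitions) == len(included_selected)
        acq_keys = {(a["square_id"], a["hole_id"]) for a in grec.acquisitions}
        assert acq_keys == {(h.parent_square_id, h.id) for h in included_selected}
        # completed holes have exactly one acquisition record each
        completed = [h for h in holes if h.status == "completed"]
        assert len(completed) == len(grec.acquisitions)

    def test_every_hole_reaches_a_terminal_status(self, collection_run):
        _, record = collection_run
        terminal = {"rejected", "failed", "completed", "detected"}
        for grec in record.grids:
            for holes in grec.holes.values():
                assert all(h.status in terminal for h in holes)

    def test_event_log_is_append_only_and_ordered(self, collection_run):
        _, record = collection_run
        seqs = [e["seq"] for e in record.events]
        assert seqs == sorted(seqs) and len(set(seqs)) == len(seqs)
        times = [e["t"] for e in record.events]
        assert all(b >= a for a, b in zip(times, times[1:]))

    def test_star_export_roundtrips_and_counts(self, collection_run):
        _, record = collection_run
        text = cs.export_star(record)
        blocks = stario.parse_star(text)
        assert stario.write_star(blocks) == text
        grec = record.grids[0]
        assert len(blocks["acquisitions"]) == len(grec.acquisitions)
        assert len(blocks["squares"]) == len(grec.squares)
        # excluded squares appear with their status but never in acquisitions
        excl = blocks["squares"][blocks["squares"]["status"] == "excluded"]
        assert len(excl) == sum(s.status == "excluded" for s in grec.squares)
        assert set(blocks["acquisitions"]["square_id"]) <= {s.id for s in grec.squares if s.status != "excluded"}

    def test_lock_refuses_concurrent_session(self):
        cfg = _session_config()
        scope = cs.MockMicroscope(seed=1)
        scope.acquire_lock()
        with pytest.raises(cs.MicroscopeLockedError):
            cs.run_session(cfg, microscope=scope)
        scope.release_lock()

    def test_zero_good_squares_completes_with_warning(self):
        spec = cs.SyntheticSpec(seed=5, class_probabilities={"cracked": 1.0})
        cfg = cs.SessionConfig(grids=[cs.GridDescriptor(name="bad", spec=spec)], mode="collection", seed=1)
        record = cs.run_session(cfg)
        assert record.grids[0].acquisitions == []
        assert "warning" in record.event_names()

    def test_injected_fault_marks_hole_failed_and_continues(self):
        cfg = _session_config(seed=4)
        probe = cs.run_session(cfg, microscope=cs.MockMicroscope(seed=2))
        first_acq = probe.grids[0].acquisitions[0]
        key = ("g1", first_acq["square_id"], first_acq["hole_id"])
        scope = cs.MockMicroscope(seed=2, fail_hole_ids=frozenset([key]))
        record = cs.run_session(cfg, microscope=scope)
        assert "hole_failed" in record.event_names()
        grec = record.grids[0]
        failed = [h for hs in grec.holes.values() for h in hs if h.status == "failed"]
        assert len(failed) == 1
        assert len(grec.acquisitions) == len(probe.grids[0].acquisitions) - 1

    def test_two_grids_run_back_to_back_in_order(self):
        spec_a = cs.SyntheticSpec(seed=6)
        spec_b = cs.SyntheticSpec(seed=7)
        cfg = cs.SessionConfig(
            grids=[cs.GridDescriptor(name="a", spec=spec_a), cs.GridDescriptor(name="b", spec=spec_b)],
            mode="screening",
            policy=cs.SelectionPolicy(n_squares=1, n_holes_per_square=3, seed=1),
            pause_between_grids=False,
            seed=2,
        )
        record = cs.run_session(cfg)
        names = [(e["event"], e.get("grid")) for e in record.events]
        atlas_b = next(i for i, e in enumerate(names) if e == ("atlas_done", "b"))
        last_acq_a = max(i for i, e in enumerate(names) if e[1] == "a" and e[0] in ("hole_acquired", "grid_done"))
        assert atlas_b > last_acq_a


class TestReplayDeterminism:
    def test_identical_config_and_seed_replays_identically(self):
        cfg = _session_config(seed=8)
        rec_a = cs.run_session(cfg, microscope=cs.MockMicroscope(seed=5))
        rec_b = cs.run_session(cfg, microscope=cs.MockMicroscope(seed=5))
        strip = lambda events: [{k: v for k, v in e.items() if k != "t"} for e in events]
        assert strip(rec_a.events) == strip(rec_b.events)
        acq_a = [{k: v for k, v in a.items() if k != "timestamp"} for a in rec_a.grids[0].acquisitions]
        acq_b = [{k: v for k, v in a.items() if k != "timestamp"} for a in rec_b.grids[0].acquisitions]
        assert acq_a == acq_b

    def test_slow_worker_does_not_change_acquisition_order(self):
        cfg = _session_config(seed=9, n_squares=1)
        fast = cs.run_session(cfg, microscope=cs.MockMicroscope(seed=5), processing_delay_s=0.0)
        slow = cs.run_session(cfg, microscope=cs.MockMicroscope(seed=5), processing_delay_s=0.002)
        order = lambda rec: [(e["event"], e.get("hole")) for e in rec.events if e["event"] == "hole_acquired"]
        assert order(fast) == order(slow)
        # FIFO: processing results come back in enqueue order
        keys_fast = [r["key"] for r in fast.grids[0].processing]
        keys_slow = [r["key"] for r in slow.grids[0].processing]
        assert keys_fast == keys_slow
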