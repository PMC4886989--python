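import dataclasses

import numpy as np
import pytest

import sfxprep as sp
from sfxprep.dispatcher import (
    DispatchError,
    PipelineConfig,
    PipelineError,
    merged_log_samples,
    process_split,
)
from sfxprep.fixtures import mini_params
from sfxprep.monitor import read_log
from sfxprep.synthetic import write_raw_run

from conftest import clean_sim_params


# --------------------------------------------------------------------------
# TagTracker
# --------------------------------------------------------------------------

class TestTagTracker:
    def test_completeness_rule(self):
        t = sp.TagTracker()
        for m in range(7):
            assert t.advance(m, 10) == []
        assert t.advance(7, 9) == []
        assert t.advance(7, 10) == [10]
        assert t.dispatched == [10]

    def test_one_fast_module_dispatches_nothing(self):
        t = sp.TagTracker()
        for m in range(1, 8):
            t.advance(m, 5)
        assert t.advance(0, 10) == []  # others still at 5; tag 10 not complete
        assert t.dispatched == []

    def test_no_tag_dispatched_twice(self):
        t = sp.TagTracker()
        for tag in (1, 2):
            for m in range(8):
                t.advance(m, tag)
        assert t.dispatched == [1, 2]
        assert len(set(t.dispatched)) == len(t.dispatched)

    def test_watermark_regression_error(self):
        t = sp.TagTracker()
        t.advance(0, 10)
        with pytest.raises(DispatchError):
            t.advance(0, 9)

    def test_gap_tag_skipped(self):
        t = sp.TagTracker()
        # module 0 skips tag 2
        for m in range(8):
            t.advance(m, 1)
        for m in range(1, 8):
            t.advance(m, 2)
        for m in range(8):
            t.advance(m, 3)
        assert t.dispatched == [1, 3]
        assert t.skipped == [2]

    def test_min_watermark_oracle_random_interleavings(self):
        # brute-force oracle: after every advance, recompute the min
        # watermark and dispatch all complete tags it covers, in order
        rng = np.random.default_rng(0)
        n_tags = 5
        for _trial in range(300):
            ops = [(m, tag) for m in range(8) for tag in range(1, n_tags + 1)]
            # shuffle while keeping each module's tags in increasing order
            order = rng.permutation(len(ops))
            per_module = {m: [tag for tag in range(1, n_tags + 1)] for m in range(8)}
            seq = []
            for i in order:
                m = ops[i][0]
                seq.append((m, per_module[m].pop(0)))

            tracker = sp.TagTracker()
            got = []
            # independent oracle state
            marks = [0] * 8
            oracle_dispatched = []
            for m, tag in seq:
                got.extend(tracker.advance(m, tag))
                marks[m] = tag
                low = min(marks)
                for t in range(1, low + 1):
                    if t not in oracle_dispatched:
                        oracle_dispatched.append(t)
            assert got == oracle_dispatched
            assert tracker.dispatched == sorted(tracker.dispatched)

    def test_invalid_construction(self):
        with pytest.raises(ValueError):
            sp.TagTracker(n_modules=0)
        with pytest.raises(ValueError):
            sp.TagTracker().advance(8, 1)


# --------------------------------------------------------------------------
# split_run
# --------------------------------------------------------------------------

class TestSplitRun:
    def test_near_equal_partition(self):
        manifest = sp.RunManifest(n_dark=150, n_exposed=5000)
        ranges = sp.split_run(manifest, 3)
        sizes = sorted(hi - lo + 1 for lo, hi in ranges)
        assert sizes == [1666, 1667, 1667]

    def test_partition_is_contiguous_and_covering(self):
        manifest = sp.RunManifest(n_dark=10, n_exposed=103, first_tag=1000)
        ranges = sp.split_run(manifest, 4)
        covered = []
        for lo, hi in ranges:
            covered.extend(range(lo, hi + 1))
        assert covered == list(manifest.exposed_tags())

    def test_single_job_full_range(self):
        manifest = sp.RunManifest(n_dark=5, n_exposed=50, first_tag=100)
        assert sp.split_run(manifest, 1) == [(105, 154)]

    def test_errors(self):
        manifest = sp.RunManifest(n_dark=5, n_exposed=10)
        with pytest.raises(ValueError):
            sp.split_run(manifest, 0)
        with pytest.raises(ValueError):
            sp.split_run(manifest, 11)


# --------------------------------------------------------------------------
# process_run
# --------------------------------------------------------------------------

def _config(mini_geom, **sim_overrides):
    return PipelineConfig(geometry=mini_geom, sim=clean_sim_params(**sim_overrides))


class TestProcessRun:
    def test_zero_hit_fraction(self, mini_geom, tmp_path):
        manifest = sp.RunManifest(run_id=1, n_dark=5, n_exposed=20)
        summary, paths = sp.process_run(
            manifest, _config(mini_geom, hit_fraction=0.0), tmp_path / "run"
        )
        assert summary.n_hits == 0 and summary.hit_rate == 0.0
        assert sp.list_tags(paths["hits"]) == []
        assert summary.n_frames == 25

    def test_hits_match_ground_truth(self, mini_geom, tmp_path):
        # clean regime: found spots == planted spots per frame, so the hit
        # set is exactly the frames with >= 20 planted spots
        manifest = sp.RunManifest(run_id=2, n_dark=5, n_exposed=40)
        config = _config(mini_geom, seed=55, hit_fraction=0.6)
        summary, paths = sp.process_run(manifest, config, tmp_path / "run")
        _, truths = sp.simulate_run(manifest, config.sim, mini_geom)
        expected_hits = [t.tag for t in truths if len(t.spots) >= 20]
        assert sp.list_tags(paths["hits"]) == expected_hits
        assert summary.n_hits == len(expected_hits)
        # per-frame spot counts equal planted counts
        by_tag = {t.tag: len(t.spots) for t in truths[5:]}
        for s in read_log(paths["monitor"]):
            assert s.n_spots == by_tag[s.tag]

    def test_rerun_byte_identical(self, mini_geom, tmp_path):
        manifest = sp.RunManifest(run_id=3, n_dark=4, n_exposed=25)
        config = _config(mini_geom, seed=8)
        _, p1 = sp.process_run(manifest, config, tmp_path / "a")
        _, p2 = sp.process_run(manifest, config, tmp_path / "b")
        assert (p1["monitor"].read_bytes() == p2["monitor"].read_bytes())
        assert sp.list_tags(p1["hits"]) == sp.list_tags(p2["hits"])

    def test_pump_probe_routes_to_two_stores(self, mini_geom, tmp_path):
        manifest = sp.RunManifest(run_id=4, n_dark=4, n_exposed=30, pump_probe=True)
        config = _config(mini_geom, seed=5, hit_fraction=1.0)
        summary, paths = sp.process_run(manifest, config, tmp_path / "pp")
        light = sp.list_tags(paths["hits_light"])
        dark = sp.list_tags(paths["hits_dark"])
        assert summary.n_light + summary.n_dark == 30
        assert len(light) + len(dark) == summary.n_hits
        assert not set(light) & set(dark)
        _, truths = sp.simulate_run(manifest, config.sim, mini_geom)
        states = {t.tag: t.pump_state for t in truths}
        assert all(states[t] == "light" for t in light)
        assert all(states[t] == "dark" for t in dark)

    def test_missing_dark_block_aborts(self, mini_geom, tmp_path):
        manifest = sp.RunManifest(run_id=5, n_dark=3, n_exposed=5)
        frames, truths = sp.simulate_run(manifest, mini_params(seed=1), mini_geom)
        # corrupt the run: drop the dark block entirely
        raw = tmp_path / "raw.h5"
        write_raw_run(raw, zip(frames[3:], truths[3:]), manifest)
        config = dataclasses.replace(_config(mini_geom), input_path=str(raw))
        with pytest.raises(PipelineError, match="dark"):
            sp.process_run(manifest, config, tmp_path / "out")

    def test_truncated_dark_block_aborts(self, mini_geom, tmp_path):
        manifest = sp.RunManifest(run_id=6, n_dark=5, n_exposed=0)
        frames, truths = sp.simulate_run(
            sp.RunManifest(run_id=6, n_dark=2, n_exposed=0), mini_params(seed=1), mini_geom
        )
        raw = tmp_path / "raw.h5"
        write_raw_run(raw, zip(frames, truths), manifest)
        config = dataclasses.replace(_config(mini_geom), input_path=str(raw))
        with pytest.raises(PipelineError, match="truncated"):
            sp.process_run(manifest, config, tmp_path / "out")

    def test_raw_file_input_equals_in_process(self, mini_geom, tmp_path):
        manifest = sp.RunManifest(run_id=7, n_dark=3, n_exposed=15)
        config = _config(mini_geom, seed=17)
        raw = tmp_path / "raw.h5"
        write_raw_run(raw, sp.generate_run(manifest, config.sim, mini_geom), manifest)
        s1, p1 = sp.process_run(manifest, config, tmp_path / "sim")
        config2 = dataclasses.replace(config, input_path=str(raw))
        s2, p2 = sp.process_run(manifest, config2, tmp_path / "file")
        assert p1["monitor"].read_bytes() == p2["monitor"].read_bytes()
        assert s1 == s2


class TestSplitEquivalence:
    def test_split_equals_unsplit(self, mini_geom, tmp_path):
        manifest = sp.RunManifest(run_id=8, n_dark=4, n_exposed=30)
        config = _config(mini_geom, seed=21, hit_fraction=0.7)
        single, paths = sp.process_run(manifest, config, tmp_path / "single")
        merged, job_dirs = process_split(manifest, config, tmp_path / "split", n_jobs=3)
        ref = read_log(paths["monitor"])
        got = merged_log_samples(job_dirs)
        assert [s.tag for s in got] == [s.tag for s in ref]
        assert [(s.n_spots, s.is_hit) for s in got] == [(s.n_spots, s.is_hit) for s in ref]
        assert merged.n_hits == single.n_hits
        assert merged.n_frames == single.n_frames
        union_tags = sorted(
            t for d in job_dirs for t in sp.list_tags(d / "hits.h5")
        )
        assert union_tags == sp.list_tags(paths["hits"])


class TestResume:
    def test_crash_recovery_from_log(self, mini_geom, tmp_path):
        """Process half a run, discard in-memory state, resume from the log:
        final outputs equal a single uninterrupted pass."""
        manifest = sp.RunManifest(run_id=9, n_dark=4, n_exposed=24)
        config = _config(mini_geom, seed=33, hit_fraction=0.8)
        full, p_full = sp.process_run(manifest, config, tmp_path / "full")

        out = tmp_path / "resumed"
        lo = manifest.first_tag + manifest.n_dark
        half = dataclasses.replace(config, tag_range=(lo, lo + 11))
        sp.process_run(manifest, half, out)
        resumed, p_res = sp.process_run(manifest, config, out, resume=True)

        assert p_res["monitor"].read_bytes() == p_full["monitor"].read_bytes()
        assert sp.list_tags(p_res["hits"]) == sp.list_tags(p_full["hits"])
        assert resumed == full


class TestConfigYaml:
    def test_roundtrip(self, mini_geom, tmp_path):
        config = PipelineConfig(
            geometry=mini_geom,
            sim=mini_params(seed=3),
            llf_roi={"exclude_ring": {"radius_px": 60.0, "halfwidth_px": 12.0}},
            tag_range=(5, 10),
        )
        path = tmp_path / "c.yaml"
        config.to_yaml(path)
        back = PipelineConfig.from_yaml(path)
        assert back.geometry == config.geometry
        assert back.sim == config.sim
        assert back.llf_roi == config.llf_roi
        assert back.tag_range == (5, 10)
        assert back.spot == config.spot and back.hit == config.hit
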