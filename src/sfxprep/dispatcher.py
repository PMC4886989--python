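"""Run-level orchestration and the producer-consumer tag-completeness
contract.

:class:`TagTracker` is the sequential embodiment of the dispatch rule used
for multi-module frame assembly: one watermark per module records the latest
tag that module has delivered, and a tag may be dispatched if and only if
every module watermark has reached it.  Thread-safety contract (for an
optional threaded driver): each watermark has a single writer (its module's
acquisition thread); the dispatch check only reads watermarks, so no lock is
required around the array itself.

:func:`process_run` drives a full run: dark reference -> calibration ->
spot finding -> LLF + hit rule -> event store(s) -> monitor log/summary.
All artifacts are deterministic functions of (manifest, config).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import yaml

from . import monitor as monitor_mod
from .calibration import (
    CalibrationParams,
    CalibrationError,
    DarkReference,
    calibrate,
    compute_dark,
    saturation_level_dc,
    save_dark,
)
from .geometry import (
    DetectorGeometry,
    default_geometry,
    geometry_from_dict,
    geometry_to_dict,
)
from .hitfind import (
    HitParams,
    classify_hit,
    classify_pump_state,
    llf_prefilter,
    ring_exclusion_roi,
)
from .io_hdf5 import EventStoreWriter, StoreConfig, record_from
from .monitor import HitRateMonitor, RunSummary, summarize_run
from .spotfind import SpotFindParams, find_spots
from .synthetic import (
    GroundTruth,
    RawFrame,
    RunManifest,
    SimulationParams,
    generate_run,
    read_raw_run,
)

logger = logging.getLogger(__name__)


class DispatchError(RuntimeError):
    pass


class PipelineError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# tag-completeness tracker
# --------------------------------------------------------------------------

class TagTracker:
    """Per-module tag watermarks with the all-modules dispatch rule.

    ``advance(module, tag)`` records that ``module`` delivered ``tag``.
    Once the minimum watermark reaches a tag, the tag is resolved: it is
    dispatched if all modules delivered it, otherwise (some module jumped
    past it) it is marked skipped once the minimum watermark exceeds it by
    more than ``skip_lag``.
    """

    def __init__(self, n_modules: int = 8, skip_lag: int = 0) -> None:
        if n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if skip_lag < 0:
            raise ValueError("skip_lag must be >= 0")
        self.n_modules = n_modules
        self.skip_lag = skip_lag
        self.watermarks: list[int | None] = [None] * n_modules
        self.dispatched: list[int] = []
        self.skipped: list[int] = []
        self._pending: dict[int, set[int]] = {}

    def advance(self, module: int, tag: int) -> list[int]:
        """Update one module's watermark; return newly dispatchable tags."""
        if not 0 <= module < self.n_modules:
            raise ValueError(f"module {module} out of range")
        current = self.watermarks[module]
        if current is not None and tag < current:
            raise DispatchError(
                f"watermark regression: module {module} at {current}, got {tag}"
            )
        self.watermarks[module] = tag
        self._pending.setdefault(tag, set()).add(module)

        if any(w is None for w in self.watermarks):
            return []
        low = min(w for w in self.watermarks if w is not None)
        newly = []
        for t in sorted(self._pending):
            if t > low:
                break
            modules = self._pending[t]
            if len(modules) == self.n_modules:
                del self._pending[t]
                self.dispatched.append(t)
                newly.append(t)
            elif t <= low - self.skip_lag:
                del self._pending[t]
                self.skipped.append(t)
        return newly


# --------------------------------------------------------------------------
# pipeline configuration
# --------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    """Full parameter snapshot for one processing run."""

    geometry: DetectorGeometry = dataclasses.field(default_factory=default_geometry)
    sim: SimulationParams = dataclasses.field(default_factory=SimulationParams)
    input_path: str | None = None  # raw-run HDF5; None -> simulate in-process
    calib: CalibrationParams | None = None  # None -> derive from geometry/manifest
    spot: SpotFindParams = dataclasses.field(default_factory=SpotFindParams)
    hit: HitParams = dataclasses.field(default_factory=HitParams)
    store: StoreConfig = dataclasses.field(default_factory=StoreConfig)
    monitor_window: int = 100
    cumulative_rate: bool = False
    # ROI spec for the LLF, e.g. {"exclude_ring": {"radius_px": 150,
    # "halfwidth_px": 20}}; None -> all pixels
    llf_roi: dict | None = None
    n_jobs: int = 3
    tag_range: tuple[int, int] | None = None  # inclusive range of exposed tags

    def resolved_calib(self, manifest: RunManifest) -> CalibrationParams:
        if self.calib is not None:
            return self.calib
        return CalibrationParams(
            gains=self.geometry.gains,
            photon_energy_ev=manifest.photon_energy_ev,
        )

    def resolved_spot(self, calib: CalibrationParams) -> SpotFindParams:
        if self.spot.saturation_value is not None:
            return self.spot
        level = saturation_level_dc(
            calib, self.sim.saturation_adu, self.sim.pedestal_adu
        )
        return dataclasses.replace(self.spot, saturation_value=level)

    def resolved_roi(self) -> list[np.ndarray] | None:
        if self.llf_roi is None:
            return None
        spec = self.llf_roi.get("exclude_ring")
        if spec is None:
            raise PipelineError(f"unsupported llf_roi spec {self.llf_roi!r}")
        return ring_exclusion_roi(
            self.geometry,
            radius_px=spec["radius_px"],
            halfwidth_px=spec["halfwidth_px"],
            center_offset_px=tuple(spec.get("center_offset_px", (0.0, 0.0))),
        )

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "geometry": geometry_to_dict(self.geometry),
            "sim": dataclasses.asdict(self.sim),
            "input_path": self.input_path,
            "calib": dataclasses.asdict(self.calib) if self.calib else None,
            "spot": dataclasses.asdict(self.spot),
            "hit": dataclasses.asdict(self.hit),
            "store": dataclasses.asdict(self.store),
            "monitor_window": self.monitor_window,
            "cumulative_rate": self.cumulative_rate,
            "llf_roi": self.llf_roi,
            "n_jobs": self.n_jobs,
            "tag_range": list(self.tag_range) if self.tag_range else None,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        sim = d.get("sim") or {}
        if "ring_center_offset_px" in sim:
            sim["ring_center_offset_px"] = tuple(sim["ring_center_offset_px"])
        calib = d.get("calib")
        if calib and "gains" in calib:
            calib["gains"] = tuple(calib["gains"])
        return cls(
            geometry=geometry_from_dict(d["geometry"]),
            sim=SimulationParams(**sim),
            input_path=d.get("input_path"),
            calib=CalibrationParams(**calib) if calib else None,
            spot=SpotFindParams(**(d.get("spot") or {})),
            hit=HitParams(**(d.get("hit") or {})),
            store=StoreConfig(**(d.get("store") or {})),
            monitor_window=d.get("monitor_window", 100),
            cumulative_rate=d.get("cumulative_rate", False),
            llf_roi=d.get("llf_roi"),
            n_jobs=d.get("n_jobs", 3),
            tag_range=tuple(d["tag_range"]) if d.get("tag_range") else None,
        )


# --------------------------------------------------------------------------
# run splitting
# --------------------------------------------------------------------------

def split_run(manifest: RunManifest, n_jobs: int) -> list[tuple[int, int]]:
    """Partition the exposed tags into contiguous, disjoint, covering
    inclusive ranges of near-equal size (the dark block is shared)."""
    if n_jobs < 1:
        raise ValueError("n_jobs must be >= 1")
    if n_jobs > manifest.n_exposed:
        raise ValueError(
            f"n_jobs={n_jobs} exceeds the {manifest.n_exposed} exposed frames"
        )
    tags = manifest.exposed_tags()
    base, rem = divmod(len(tags), n_jobs)
    ranges = []
    start = tags.start
    for j in range(n_jobs):
        size = base + (1 if j < rem else 0)
        ranges.append((start, start + size - 1))
        start += size
    return ranges


# --------------------------------------------------------------------------
# full-run processing
# --------------------------------------------------------------------------

def _frame_stream(
    manifest: RunManifest, config: PipelineConfig
) -> Iterator[tuple[RawFrame, GroundTruth | None]]:
    if config.input_path is not None:
        for frame in read_raw_run(config.input_path, config.geometry):
            yield frame, None
    else:
        yield from generate_run(manifest, config.sim, config.geometry)


def process_run(
    manifest: RunManifest,
    config: PipelineConfig,
    out_dir: str | Path,
    resume: bool = False,
) -> tuple[RunSummary, dict[str, Path]]:
    """Process one run end to end, writing all artifacts under ``out_dir``.

    Artifacts: ``dark.h5``, ``hits.h5`` (or ``hits_light.h5`` +
    ``hits_dark.h5`` for pump-probe runs), ``monitor.tsv``, ``summary.json``
    and ``config.yaml``.  With ``resume=True`` the monitor log is consulted
    and already-processed tags are skipped, appending to existing stores —
    the dispatcher's state is fully reconstructible from its log.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dark": out_dir / "dark.h5",
        "monitor": out_dir / "monitor.tsv",
        "summary": out_dir / "summary.json",
        "config": out_dir / "config.yaml",
    }
    if manifest.pump_probe:
        paths["hits_light"] = out_dir / "hits_light.h5"
        paths["hits_dark"] = out_dir / "hits_dark.h5"
    else:
        paths["hits"] = out_dir / "hits.h5"

    config.to_yaml(paths["config"])
    calib = config.resolved_calib(manifest)
    spot_params = config.resolved_spot(calib)
    roi = config.resolved_roi()

    done_tags: set[int] = set()
    prior_samples: list[monitor_mod.MonitorSample] = []
    if resume and paths["monitor"].exists():
        prior_samples = monitor_mod.read_log(paths["monitor"])
        done_tags = {s.tag for s in prior_samples}

    stream = _frame_stream(manifest, config)

    # ---- dark block -------------------------------------------------------
    dark_frames: list[RawFrame] = []
    first_exposed: tuple[RawFrame, GroundTruth | None] | None = None
    for frame, truth in stream:
        if frame.shutter_open:
            first_exposed = (frame, truth)
            break
        dark_frames.append(frame)
        if len(dark_frames) == manifest.n_dark:
            break
    if not dark_frames:
        raise PipelineError(
            f"run {manifest.run_id}: no dark block — first frame "
            f"(tag {first_exposed[0].tag if first_exposed else '?'}) is shutter-open"
        )
    if len(dark_frames) < manifest.n_dark:
        raise PipelineError(
            f"run {manifest.run_id}: dark block truncated "
            f"({len(dark_frames)}/{manifest.n_dark} frames)"
        )
    dark = compute_dark(dark_frames, run_id=manifest.run_id)
    save_dark(paths["dark"], dark)
    del dark_frames

    # ---- exposed block ----------------------------------------------------
    mode = "a" if resume else "w"
    log_exists = resume and paths["monitor"].exists()
    store_meta = {"run_id": manifest.run_id, "sfxprep": "0.1.0"}
    writers: dict[str, EventStoreWriter] = {}
    if manifest.pump_probe:
        writers["light"] = EventStoreWriter(
            paths["hits_light"], config.store, {**store_meta, "pump_state": "light"}, mode
        )
        writers["dark"] = EventStoreWriter(
            paths["hits_dark"], config.store, {**store_meta, "pump_state": "dark"}, mode
        )
    else:
        writers["all"] = EventStoreWriter(paths["hits"], config.store, store_meta, mode)

    lo, hi = config.tag_range if config.tag_range else (None, None)
    try:
        with open(paths["monitor"], "a" if log_exists else "w") as log:
            mon = HitRateMonitor(
                window=config.monitor_window,
                cumulative=config.cumulative_rate,
                log=log,
                write_header=not log_exists,
            )
            mon.replay(prior_samples)

            if first_exposed is not None:
                pending: Iterable[tuple[RawFrame, GroundTruth | None]] = (
                    x for x in (first_exposed,)
                )
                frames = _chain(pending, stream)
            else:
                frames = stream
            for frame, _truth in frames:
                if not frame.shutter_open:
                    raise PipelineError(
                        f"shutter-closed frame tag={frame.tag} inside the exposed block"
                    )
                if frame.tag in done_tags:
                    continue
                if lo is not None and not (lo <= frame.tag <= hi):
                    continue
                cal = calibrate(frame, dark, calib)
                llf_passed, llf_value = llf_prefilter(cal, config.hit, roi)
                spots = find_spots(cal, spot_params)
                pump = (
                    classify_pump_state(frame.photodiode, config.hit.pump_threshold)
                    if manifest.pump_probe
                    else "n/a"
                )
                decision = classify_hit(
                    spots, config.hit, llf_passed, llf_value, pump
                )
                mon.update(decision, spots)
                if decision.is_hit:
                    record = record_from(cal, spots, config.geometry.slow_extent)
                    if manifest.pump_probe:
                        key = pump if pump in writers else "dark"
                        writers[key].append(record)
                    else:
                        writers["all"].append(record)
    except Exception:
        for w in writers.values():
            w.abort()
        raise
    for w in writers.values():
        w.close()

    samples = monitor_mod.read_log(paths["monitor"])
    summary = summarize_run(
        samples, run_id=manifest.run_id, n_dark_frames=dark.n_frames_used
    )
    monitor_mod.write_summary(summary, paths["summary"])
    logger.info(
        "run %d: %d frames, %d hits (rate %.3f)",
        manifest.run_id,
        summary.n_frames,
        summary.n_hits,
        summary.hit_rate,
    )
    return summary, paths


def _chain(*iterables):
    for it in iterables:
        yield from it


def process_split(
    manifest: RunManifest,
    config: PipelineConfig,
    out_dir: str | Path,
    n_jobs: int | None = None,
) -> tuple[RunSummary, list[Path]]:
    """Process a run as ``n_jobs`` sequential split jobs (each over a
    contiguous tag range, each rebuilding the shared dark block) and merge
    the per-job summaries."""
    out_dir = Path(out_dir)
    n_jobs = n_jobs if n_jobs is not None else config.n_jobs
    job_dirs = []
    summaries = []
    for j, (lo, hi) in enumerate(split_run(manifest, n_jobs)):
        job_dir = out_dir / f"job-{j}"
        job_config = dataclasses.replace(config, tag_range=(lo, hi))
        summary, _ = process_run(manifest, job_config, job_dir)
        job_dirs.append(job_dir)
        summaries.append(summary)
    # dark-block frames are shared, count them once
    merged = monitor_mod.combine_summaries(summaries, run_id=manifest.run_id)
    merged.n_frames = manifest.n_dark + merged.n_exposed
    monitor_mod.write_summary(merged, out_dir / "summary.json")
    return merged, job_dirs


def merged_log_samples(job_dirs: Sequence[Path]) -> list[monitor_mod.MonitorSample]:
    """Concatenate per-job monitor logs in ascending tag order."""
    samples: list[monitor_mod.MonitorSample] = []
    for d in job_dirs:
        samples.extend(monitor_mod.read_log(Path(d) / "monitor.tsv"))
    return sorted(samples, key=lambda s: s.tag)
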