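"""Synthetic raw-run generator with per-frame ground truth.

A run is a dark block (shutter closed, pedestal + read noise only) followed
by exposed frames.  Exposed frames carry an optional carrier-medium
scattering ring plus, on a fraction of shots, planted Bragg-like spots with
2-D Gaussian profiles and Poisson photon statistics.  The generator works in
photons -> electrons (photon_energy / 3.65 eV per photon) -> ADU
(divide by the per-module gain), so the calibration stage inverts it exactly
in expectation.

Everything is driven by one ``numpy.random.Generator`` seeded from
``SimulationParams.seed``: identical (manifest, params, geometry) inputs
produce bit-identical frames and ground truth.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import h5py
import numpy as np

from .geometry import (
    N_MODULES,
    DetectorGeometry,
    default_geometry,
    panel_radius_maps,
    split_stacked,
    stack_panels,
)

PAIR_ENERGY_EV = 3.65  # energy to create one electron-hole pair in silicon

#: spot footprint half-width, in units of the spot Gaussian sigma
_SPOT_BOX_SIGMAS = 4.0
#: spots are kept this many sigmas away from panel edges
_EDGE_MARGIN_SIGMAS = 2.0

ADU_MAX = np.iinfo(np.uint16).max


class SimulationError(ValueError):
    """Raised for invalid run manifests or simulation parameters."""


@dataclasses.dataclass(frozen=True)
class RunManifest:
    """Layout of one acquisition run: a dark block then exposed frames."""

    run_id: int = 1
    n_dark: int = 150
    n_exposed: int = 5000
    first_tag: int = 100_000
    repetition_rate_hz: float = 30.0
    photon_energy_ev: float = 7300.0
    pump_probe: bool = False

    def __post_init__(self) -> None:
        if self.n_dark < 1:
            raise SimulationError("n_dark must be >= 1")
        if self.n_exposed < 0:
            raise SimulationError("n_exposed must be >= 0")
        if self.photon_energy_ev <= 0:
            raise SimulationError("photon_energy_ev must be positive")
        if self.first_tag < 0:
            raise SimulationError("first_tag must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.n_dark + self.n_exposed

    def tags(self) -> range:
        """All tags of the run, dark block first, strictly increasing."""
        return range(self.first_tag, self.first_tag + self.n_frames)

    def exposed_tags(self) -> range:
        return range(self.first_tag + self.n_dark, self.first_tag + self.n_frames)


@dataclasses.dataclass(frozen=True)
class SimulationParams:
    """Knobs of the generative model.  All defaults are documented stand-ins."""

    pedestal_adu: float = 200.0
    read_noise_adu: float = 4.0
    hit_fraction: float = 0.3
    spots_per_hit_mean: float = 30.0
    spots_per_hit_dispersion: float = 0.0  # 0 -> Poisson, >0 -> neg. binomial
    spot_sigma_px: float = 1.5
    spot_photons_mean: float = 2000.0
    spot_photons_sd: float = 1500.0  # 0 -> every spot carries exactly the mean
    ring_radius_px: float = 150.0
    ring_width_px: float = 5.0
    ring_photons: float = 2.0  # expected photons/pixel at the ring crest
    ring_center_offset_px: tuple[float, float] = (0.0, 0.0)
    saturation_adu: float = 65000.0
    min_spot_separation_px: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pedestal_adu",
            "read_noise_adu",
            "spot_sigma_px",
            "spot_photons_mean",
            "ring_radius_px",
            "ring_width_px",
            "ring_photons",
            "min_spot_separation_px",
        ):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be non-negative")
        if not 0.0 <= self.hit_fraction <= 1.0:
            raise SimulationError("hit_fraction must be in [0, 1]")
        if not 0 < self.saturation_adu <= ADU_MAX:
            raise SimulationError(f"saturation_adu must be in (0, {ADU_MAX}]")
        if self.hit_fraction > 0 and self.spots_per_hit_mean <= 0:
            raise SimulationError(
                "spots_per_hit_mean must be > 0 when hit_fraction > 0"
            )


@dataclasses.dataclass
class RawFrame:
    """One shot: eight raw uint16 panels plus shot metadata."""

    tag: int
    panels: list[np.ndarray]
    shutter_open: bool
    photon_energy_ev: float
    photodiode: float
    spectrum_mean_ev: float

    def stacked(self) -> np.ndarray:
        return stack_panels(self.panels)


@dataclasses.dataclass(frozen=True)
class PlantedSpot:
    module: int
    fast: float
    slow: float
    integrated_photons: int
    is_saturated: bool


@dataclasses.dataclass
class GroundTruth:
    """Per-frame oracle emitted by the generator."""

    tag: int
    is_hit: bool
    spots: list[PlantedSpot]
    has_ring: bool
    pump_state: str = "n/a"  # "light" | "dark" | "n/a"


@dataclasses.dataclass(frozen=True)
class ScheduleEntry:
    tag: int
    state: str  # "light" | "dark"
    photodiode: float


# --------------------------------------------------------------------------
# pump-probe schedule
# --------------------------------------------------------------------------

def pump_probe_schedule(
    manifest: RunManifest,
    pattern: str | float | Sequence[str] = "alternate",
    rng: np.random.Generator | None = None,
    light_level: float = 1.0,
    dark_level: float = 0.0,
    jitter: float = 0.05,
) -> list[ScheduleEntry]:
    """Assign a light/dark pump state and a photodiode readout per exposed tag.

    ``pattern`` may be ``"alternate"`` (default: even exposed index -> light),
    ``"all_light"``, ``"all_dark"``, a probability of light in [0, 1], or an
    explicit sequence of ``"light"``/``"dark"`` states cycled over the run.
    Photodiode values are drawn from well-separated Gaussians so a simple
    threshold recovers the state.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    tags = list(manifest.exposed_tags())

    if isinstance(pattern, str):
        if pattern == "alternate":
            states = ["light" if i % 2 == 0 else "dark" for i in range(len(tags))]
        elif pattern == "all_light":
            states = ["light"] * len(tags)
        elif pattern == "all_dark":
            states = ["dark"] * len(tags)
        else:
            raise SimulationError(f"unknown pump-probe pattern {pattern!r}")
    elif isinstance(pattern, (int, float)):
        p = float(pattern)
        if not 0.0 <= p <= 1.0:
            raise SimulationError("light probability must be in [0, 1]")
        states = ["light" if u < p else "dark" for u in rng.random(len(tags))]
    else:
        cycle = list(pattern)
        if not cycle:
            raise SimulationError("pump-probe pattern must have at least one state")
        if any(s not in ("light", "dark") for s in cycle):
            raise SimulationError("pattern states must be 'light' or 'dark'")
        states = [cycle[i % len(cycle)] for i in range(len(tags))]

    out = []
    for tag, state in zip(tags, states):
        mean = light_level if state == "light" else dark_level
        pd = float(mean + rng.normal(0.0, jitter))
        out.append(ScheduleEntry(tag=tag, state=state, photodiode=pd))
    return out


# --------------------------------------------------------------------------
# frame generation
# --------------------------------------------------------------------------

def _ring_bands(
    geometry: DetectorGeometry, params: SimulationParams
) -> list[tuple[np.ndarray, np.ndarray] | None]:
    """Per panel: (flat indices, expected photons) of the ring band, or None."""
    if params.ring_photons <= 0:
        return [None] * N_MODULES
    dx, dy = params.ring_center_offset_px
    center = (
        geometry.beam_center_mm[0] + dx * geometry.pixel_size,
        geometry.beam_center_mm[1] + dy * geometry.pixel_size,
    )
    bands: list[tuple[np.ndarray, np.ndarray] | None] = []
    for rmap in panel_radius_maps(geometry, center):
        d = rmap - params.ring_radius_px
        sel = np.abs(d) <= 4.0 * params.ring_width_px
        idx = np.flatnonzero(sel)
        if idx.size == 0:
            bands.append(None)
            continue
        lam = params.ring_photons * np.exp(
            -0.5 * (d.ravel()[idx] / params.ring_width_px) ** 2
        )
        bands.append((idx, lam))
    return bands


def _sample_spot_count(rng: np.random.Generator, params: SimulationParams) -> int:
    m = params.spots_per_hit_mean
    d = params.spots_per_hit_dispersion
    if d <= 0:
        return int(rng.poisson(m))
    # negative binomial with mean m and variance m * (1 + d)
    p = 1.0 / (1.0 + d)
    n = m * p / (1.0 - p)
    return int(rng.negative_binomial(n, p))


def _sample_spot_photons(rng: np.random.Generator, params: SimulationParams) -> float:
    m, s = params.spot_photons_mean, params.spot_photons_sd
    if s <= 0:
        return m
    shape = (m / s) ** 2
    return float(rng.gamma(shape, m / shape))


def generate_run(
    manifest: RunManifest,
    params: SimulationParams,
    geometry: DetectorGeometry | None = None,
    pump_pattern: str | float | Sequence[str] = "alternate",
) -> Iterator[tuple[RawFrame, GroundTruth]]:
    """Yield ``(RawFrame, GroundTruth)`` for every frame of the run.

    The dark block comes first (shutter closed, no spots, no ring), then the
    exposed block.  Deterministic: the same inputs yield bit-identical output.
    """
    if geometry is None:
        geometry = default_geometry()
    rng = np.random.default_rng(params.seed)
    e_per_photon = manifest.photon_energy_ev / PAIR_ENERGY_EV
    bands = _ring_bands(geometry, params)
    has_ring = params.ring_photons > 0
    sigma = params.spot_sigma_px
    margin = _EDGE_MARGIN_SIGMAS * sigma
    box_r = max(1, int(math.ceil(_SPOT_BOX_SIGMAS * sigma)))
    shape = geometry.panel_shape  # (slow, fast)

    schedule: dict[int, ScheduleEntry] = {}
    if manifest.pump_probe:
        schedule = {
            e.tag: e for e in pump_probe_schedule(manifest, pump_pattern, rng=rng)
        }

    def noise_panels() -> list[np.ndarray]:
        return [
            params.pedestal_adu + rng.normal(0.0, params.read_noise_adu, shape)
            for _ in range(N_MODULES)
        ]

    def finalize(panels_f: list[np.ndarray]) -> list[np.ndarray]:
        return [
            np.clip(np.rint(p), 0, params.saturation_adu).astype(np.uint16)
            for p in panels_f
        ]

    for tag in range(manifest.first_tag, manifest.first_tag + manifest.n_dark):
        frame = RawFrame(
            tag=tag,
            panels=finalize(noise_panels()),
            shutter_open=False,
            photon_energy_ev=manifest.photon_energy_ev,
            photodiode=0.0,
            spectrum_mean_ev=manifest.photon_energy_ev,
        )
        yield frame, GroundTruth(tag=tag, is_hit=False, spots=[], has_ring=False)

    for tag in manifest.exposed_tags():
        is_hit_draw = rng.random() < params.hit_fraction
        spots: list[PlantedSpot] = []
        photon_panels = [np.zeros(shape, dtype=np.float64) for _ in range(N_MODULES)]

        if is_hit_draw:
            n_spots = _sample_spot_count(rng, params)
            placed: dict[int, list[tuple[float, float]]] = {m: [] for m in range(N_MODULES)}
            for _ in range(n_spots):
                module = int(rng.integers(N_MODULES))
                lo_f, hi_f = margin, shape[1] - 1 - margin
                lo_s, hi_s = margin, shape[0] - 1 - margin
                if hi_f <= lo_f or hi_s <= lo_s:
                    raise SimulationError("panel too small for spot margin")
                for _attempt in range(100):
                    f0 = float(rng.uniform(lo_f, hi_f))
                    s0 = float(rng.uniform(lo_s, hi_s))
                    if all(
                        math.hypot(f0 - f1, s0 - s1) >= params.min_spot_separation_px
                        for f1, s1 in placed[module]
                    ):
                        break
                placed[module].append((f0, s0))

                expected = _sample_spot_photons(rng, params)
                fi = int(round(f0))
                si = int(round(s0))
                f_lo, f_hi = max(0, fi - box_r), min(shape[1], fi + box_r + 1)
                s_lo, s_hi = max(0, si - box_r), min(shape[0], si + box_r + 1)
                F = np.arange(f_lo, f_hi, dtype=np.float64)
                S = np.arange(s_lo, s_hi, dtype=np.float64)
                wf = np.exp(-0.5 * ((F - f0) / sigma) ** 2)
                ws = np.exp(-0.5 * ((S - s0) / sigma) ** 2)
                w = np.outer(ws, wf)
                w /= w.sum()
                counts = rng.poisson(expected * w)
                photon_panels[module][s_lo:s_hi, f_lo:f_hi] += counts
                peak_adu = (
                    params.pedestal_adu
                    + expected * w.max() * e_per_photon / geometry.gains[module]
                )
                spots.append(
                    PlantedSpot(
                        module=module,
                        fast=f0,
                        slow=s0,
                        integrated_photons=int(counts.sum()),
                        is_saturated=bool(peak_adu >= params.saturation_adu),
                    )
                )

        for m, band in enumerate(bands):
            if band is None:
                continue
            idx, lam = band
            photon_panels[m].ravel()[idx] += rng.poisson(lam)

        panels_f = noise_panels()
        for m in range(N_MODULES):
            panels_f[m] += photon_panels[m] * (e_per_photon / geometry.gains[m])

        spectrum_mean = float(manifest.photon_energy_ev + rng.normal(0.0, 2.0))
        entry = schedule.get(tag)
        frame = RawFrame(
            tag=tag,
            panels=finalize(panels_f),
            shutter_open=True,
            photon_energy_ev=manifest.photon_energy_ev,
            photodiode=entry.photodiode if entry else 0.0,
            spectrum_mean_ev=spectrum_mean,
        )
        yield frame, GroundTruth(
            tag=tag,
            is_hit=len(spots) > 0,
            spots=spots,
            has_ring=has_ring,
            pump_state=entry.state if entry else "n/a",
        )


def simulate_run(
    manifest: RunManifest,
    params: SimulationParams,
    geometry: DetectorGeometry | None = None,
    pump_pattern: str | float | Sequence[str] = "alternate",
) -> tuple[list[RawFrame], list[GroundTruth]]:
    """Materialize a whole run (convenience for small runs and tests)."""
    frames, truths = [], []
    for frame, truth in generate_run(manifest, params, geometry, pump_pattern):
        frames.append(frame)
        truths.append(truth)
    return frames, truths


# --------------------------------------------------------------------------
# raw-run persistence (HDF5 + ground-truth TSV)
# --------------------------------------------------------------------------

def write_raw_run(
    path: str | Path,
    stream: Iterable[tuple[RawFrame, GroundTruth]],
    manifest: RunManifest,
    compression_level: int = 3,
) -> list[GroundTruth]:
    """Write raw frames to an HDF5 file (group ``tag-N`` per frame).

    Returns the ground-truth list (for separate TSV persistence)."""
    truths = []
    with h5py.File(path, "w") as f:
        meta = f.create_group("metadata")
        meta.attrs["run_id"] = manifest.run_id
        meta.attrs["n_dark"] = manifest.n_dark
        meta.attrs["n_exposed"] = manifest.n_exposed
        meta.attrs["first_tag"] = manifest.first_tag
        meta.attrs["photon_energy_ev"] = manifest.photon_energy_ev
        meta.attrs["pump_probe"] = manifest.pump_probe
        for frame, truth in stream:
            g = f.create_group(f"tag-{frame.tag}")
            g.create_dataset(
                "panels",
                data=frame.stacked(),
                compression="gzip",
                compression_opts=compression_level,
            )
            g.attrs["shutter_open"] = frame.shutter_open
            g.attrs["photon_energy_ev"] = frame.photon_energy_ev
            g.attrs["photodiode"] = frame.photodiode
            g.attrs["spectrum_mean_ev"] = frame.spectrum_mean_ev
            truths.append(truth)
    return truths


def read_raw_run(
    path: str | Path, geometry: DetectorGeometry
) -> Iterator[RawFrame]:
    """Iterate raw frames from a file written by :func:`write_raw_run`,
    in ascending tag order."""
    with h5py.File(path, "r") as f:
        tags = sorted(
            int(name.split("-", 1)[1])
            for name in f.keys()
            if name.startswith("tag-")
        )
        for tag in tags:
            g = f[f"tag-{tag}"]
            stacked = g["panels"][()]
            yield RawFrame(
                tag=tag,
                panels=split_stacked(geometry, stacked),
                shutter_open=bool(g.attrs["shutter_open"]),
                photon_energy_ev=float(g.attrs["photon_energy_ev"]),
                photodiode=float(g.attrs["photodiode"]),
                spectrum_mean_ev=float(g.attrs["spectrum_mean_ev"]),
            )


def write_ground_truth_tsv(path: str | Path, truths: Iterable[GroundTruth]) -> None:
    with open(path, "w") as f:
        f.write("tag\tis_hit\tn_spots\tn_saturated\thas_ring\tpump_state\n")
        for t in truths:
            n_sat = sum(1 for s in t.spots if s.is_saturated)
            f.write(
                f"{t.tag}\t{int(t.is_hit)}\t{len(t.spots)}\t{n_sat}\t"
                f"{int(t.has_ring)}\t{t.pump_state}\n"
            )


def read_ground_truth_tsv(path: str | Path) -> list[dict]:
    rows = []
    with open(path) as f:
        header = f.readline().strip().split("\t")
        for line in f:
            vals = line.rstrip("\n").split("\t")
            row = dict(zip(header, vals))
            for k in ("tag", "is_hit", "n_spots", "n_saturated", "has_ring"):
                row[k] = int(row[k])
            rows.append(row)
    return rows
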