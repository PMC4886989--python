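"""Named, seeded run fixtures.

Fixtures are generated (never shipped): ``make_fixture`` writes the run's
ground-truth table, an expected-summary JSON (frame/hit counts plus a
checksum of the tag set) and, for the small fixtures, the raw-run HDF5.
Regenerating a fixture from its seed reproduces the expected summary
exactly.

The mini geometry (8 panels of 64x128 pixels) keeps exhaustive tests fast;
the full-size 512x1024 geometry is exercised by a handful of dedicated
full-scale tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Callable

from .geometry import DetectorGeometry, default_geometry
from .synthetic import (
    RunManifest,
    SimulationParams,
    generate_run,
    write_ground_truth_tsv,
    write_raw_run,
)

MINI_FAST_EXTENT = 64
MINI_SLOW_EXTENT = 128


def mini_geometry(**kwargs) -> DetectorGeometry:
    """8-module geometry with 64x128-pixel panels (for fast tests)."""
    return default_geometry(
        fast_extent=MINI_FAST_EXTENT, slow_extent=MINI_SLOW_EXTENT, **kwargs
    )


#: generator defaults re-scaled for the mini panels: the default 150 px ring
#: radius still intersects the mini detector (stacked 1024x64, center col 32),
#: but a tighter ring keeps more of it on-panel.
MINI_RING_RADIUS_PX = 60.0


def mini_params(**overrides) -> SimulationParams:
    base = dict(ring_radius_px=MINI_RING_RADIUS_PX, ring_width_px=3.0)
    base.update(overrides)
    return SimulationParams(**base)


@dataclasses.dataclass(frozen=True)
class FixtureDef:
    name: str
    manifest: RunManifest
    params: SimulationParams
    geometry_factory: Callable[[], DetectorGeometry]
    write_raw: bool


@dataclasses.dataclass
class Fixture:
    name: str
    manifest: RunManifest
    params: SimulationParams
    seed: int
    summary: dict
    files: dict[str, Path]


_REGISTRY: dict[str, FixtureDef] = {
    "mini-run": FixtureDef(
        name="mini-run",
        manifest=RunManifest(run_id=1, n_dark=15, n_exposed=200, first_tag=10_000),
        params=mini_params(seed=7),
        geometry_factory=mini_geometry,
        write_raw=True,
    ),
    # the standard run layout (150 dark + 5000 exposed = 5150 frames) on the
    # mini geometry: the frame counts are the fixture's claim and are
    # independent of panel size; a full-size raw file would be ~42 GB.
    "standard-run": FixtureDef(
        name="standard-run",
        manifest=RunManifest(run_id=2, n_dark=150, n_exposed=5000, first_tag=200_000),
        params=mini_params(seed=11),
        geometry_factory=mini_geometry,
        write_raw=False,
    ),
    "pump-probe-run": FixtureDef(
        name="pump-probe-run",
        manifest=RunManifest(
            run_id=3, n_dark=15, n_exposed=200, first_tag=30_000, pump_probe=True
        ),
        params=mini_params(seed=13),
        geometry_factory=mini_geometry,
        write_raw=True,
    ),
}


def available_fixtures() -> list[str]:
    return sorted(_REGISTRY)


def make_fixture(name: str, out_dir: str | Path) -> Fixture:
    """Deterministically generate a named fixture under ``out_dir``."""
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(available_fixtures())}"
        )
    spec = _REGISTRY[name]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geometry = spec.geometry_factory()
    files: dict[str, Path] = {}

    stream = generate_run(spec.manifest, spec.params, geometry)
    if spec.write_raw:
        files["raw"] = out_dir / f"{name}.raw.h5"
        truths = write_raw_run(files["raw"], stream, spec.manifest)
    else:
        truths = [truth for _frame, truth in stream]

    files["truth"] = out_dir / f"{name}.truth.tsv"
    write_ground_truth_tsv(files["truth"], truths)

    tags = sorted(t.tag for t in truths)
    checksum = hashlib.sha256(",".join(map(str, tags)).encode()).hexdigest()
    summary = {
        "name": name,
        "seed": spec.params.seed,
        "n_frames": len(truths),
        "n_dark": spec.manifest.n_dark,
        "n_exposed": spec.manifest.n_exposed,
        "n_hits": sum(1 for t in truths if t.is_hit),
        "n_light": sum(1 for t in truths if t.pump_state == "light"),
        "n_dark_state": sum(1 for t in truths if t.pump_state == "dark"),
        "tag_checksum": checksum,
    }
    files["summary"] = out_dir / f"{name}.expected.json"
    files["summary"].write_text(json.dumps(summary, indent=2) + "\n")
    return Fixture(
        name=name,
        manifest=spec.manifest,
        params=spec.params,
        seed=spec.params.seed,
        summary=summary,
        files=files,
    )
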