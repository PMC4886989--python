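"""Shared fixtures: mini geometry, seeded synthetic runs, hand-planted frames."""

from __future__ import annotations

import numpy as np
import pytest

import sfxprep as sp
from sfxprep.fixtures import mini_geometry, mini_params


@pytest.fixture(scope="session")
def mini_geom():
    return mini_geometry()


@pytest.fixture(scope="session")
def mini_calib(mini_geom):
    return sp.CalibrationParams(gains=mini_geom.gains)


def clean_sim_params(**overrides):
    """Generator settings producing unambiguous, well-separated constant
    brightness spots on a flat background (no ring)."""
    base = dict(
        seed=42,
        hit_fraction=1.0,
        spots_per_hit_mean=25.0,
        spot_photons_mean=2000.0,
        spot_photons_sd=0.0,
        ring_photons=0.0,
        min_spot_separation_px=12.0,
    )
    base.update(overrides)
    return mini_params(**base)


@pytest.fixture(scope="session")
def clean_pairs(mini_geom, mini_calib):
    """30 calibrated exposed frames with ground truth (clean regime)."""
    manifest = sp.RunManifest(n_dark=5, n_exposed=30)
    frames, truths = sp.simulate_run(manifest, clean_sim_params(), mini_geom)
    dark = sp.compute_dark(frames[:5])
    return [
        (sp.calibrate(f, dark, mini_calib), t)
        for f, t in zip(frames[5:], truths[5:])
    ]


def plant_frame(geom, positions, amplitude=1000.0, sigma=1.5, tag=0):
    """Hand-built calibrated frame: Gaussian blobs of peak ``amplitude``
    (deci-photons) at (module, fast, slow) positions on a zero background."""
    panels = [np.zeros(geom.panel_shape, dtype=np.float64) for _ in range(8)]
    for module, fast, slow in positions:
        r = int(np.ceil(4 * sigma))
        f = np.arange(max(0, fast - r), min(geom.fast_extent, fast + r + 1))
        s = np.arange(max(0, slow - r), min(geom.slow_extent, slow + r + 1))
        w = np.exp(-0.5 * ((s[:, None] - slow) ** 2 + (f[None, :] - fast) ** 2) / sigma**2)
        panels[module][np.ix_(s, f)] += amplitude * w
    panels = [np.rint(p).astype(np.int16) for p in panels]
    return sp.CalibratedFrame(
        tag=tag,
        panels=panels,
        photon_energy_ev=7300.0,
        photodiode=0.0,
        spectrum_mean_ev=7300.0,
    )
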