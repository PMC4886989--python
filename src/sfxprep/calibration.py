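"""Dark-reference construction and conversion of raw ADU frames to
16-bit integer "deci-photon" images (ten units = one photon).

Per pixel:

    value = round( (ADU - dark_mean) * gain * 3.65 / photon_energy * 10 )

where ``gain`` is the per-module electrons-per-ADU constant, 3.65 eV is the
energy to create one electron-hole pair in silicon, and the result is
clipped to the signed 16-bit range.  Rounding is half-away-from-zero
(symmetric around zero); negative values after dark subtraction are kept so
that downstream SNR estimation sees unbiased noise.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np

from .geometry import N_MODULES, DEFAULT_GAIN_E_PER_ADU, stack_panels
from .synthetic import PAIR_ENERGY_EV, RawFrame

INT16_MIN = np.iinfo(np.int16).min
INT16_MAX = np.iinfo(np.int16).max

#: calibrated-unit scale: ten units correspond to one photon
UNITS_PER_PHOTON = 10


class CalibrationError(ValueError):
    """Raised for invalid calibration inputs or parameters."""


@dataclasses.dataclass(frozen=True)
class CalibrationParams:
    gains: tuple[float, ...] = (DEFAULT_GAIN_E_PER_ADU,) * N_MODULES
    photon_energy_ev: float = 7300.0
    pair_energy_ev: float = PAIR_ENERGY_EV
    units_per_photon: int = UNITS_PER_PHOTON

    def __post_init__(self) -> None:
        object.__setattr__(self, "gains", tuple(float(g) for g in self.gains))
        if len(self.gains) != N_MODULES:
            raise CalibrationError(f"expected {N_MODULES} gains")
        if any(g <= 0 for g in self.gains):
            raise CalibrationError("gains must be positive")
        if self.photon_energy_ev <= 0:
            raise CalibrationError("photon_energy_ev must be positive")
        if self.pair_energy_ev <= 0:
            raise CalibrationError("pair_energy_ev must be positive")
        if self.units_per_photon <= 0:
            raise CalibrationError("units_per_photon must be positive")


@dataclasses.dataclass
class DarkReference:
    """Per-pixel mean of the run's dark block (float64, in ADU)."""

    panel_means: list[np.ndarray]
    n_frames_used: int
    run_id: int | None = None


@dataclasses.dataclass
class CalibratedFrame:
    """Dark-subtracted, photon-normalized int16 image in deci-photon units."""

    tag: int
    panels: list[np.ndarray]
    photon_energy_ev: float
    photodiode: float
    spectrum_mean_ev: float

    def stacked(self) -> np.ndarray:
        return stack_panels(self.panels)


def compute_dark(frames: Iterable[RawFrame], run_id: int | None = None) -> DarkReference:
    """Per-pixel arithmetic mean over a sequence of shutter-closed frames."""
    sums: list[np.ndarray] | None = None
    n = 0
    for frame in frames:
        if frame.shutter_open:
            raise CalibrationError(
                f"frame tag={frame.tag} has shutter_open=True inside the dark block"
            )
        if sums is None:
            sums = [p.astype(np.float64) for p in frame.panels]
        else:
            for acc, p in zip(sums, frame.panels):
                acc += p
        n += 1
    if sums is None:
        raise CalibrationError("cannot build a dark reference from zero frames")
    return DarkReference(
        panel_means=[s / n for s in sums], n_frames_used=n, run_id=run_id
    )


def round_half_away(x: np.ndarray | float) -> np.ndarray:
    """Round to nearest integer, ties away from zero."""
    x = np.asarray(x, dtype=np.float64)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def calibrate(
    raw: RawFrame, dark: DarkReference, params: CalibrationParams
) -> CalibratedFrame:
    """Convert one exposed raw frame to deci-photon units (int16)."""
    if not raw.shutter_open:
        raise CalibrationError(
            f"frame tag={raw.tag} is shutter-closed; only exposed frames are calibrated"
        )
    if len(raw.panels) != len(dark.panel_means):
        raise CalibrationError("panel count mismatch between frame and dark reference")
    scale_base = (
        params.pair_energy_ev / params.photon_energy_ev * params.units_per_photon
    )
    panels = []
    for m, (p, d) in enumerate(zip(raw.panels, dark.panel_means)):
        if p.shape != d.shape:
            raise CalibrationError(
                f"module {m}: shape {p.shape} does not match dark {d.shape}"
            )
        x = (p.astype(np.float64) - d) * (params.gains[m] * scale_base)
        # symmetric clip to +/-(2^15 - 1): values are clipped, never wrapped
        panels.append(
            np.clip(round_half_away(x), -INT16_MAX, INT16_MAX).astype(np.int16)
        )
    return CalibratedFrame(
        tag=raw.tag,
        panels=panels,
        photon_energy_ev=raw.photon_energy_ev,
        photodiode=raw.photodiode,
        spectrum_mean_ev=raw.spectrum_mean_ev,
    )


def photons(frame: CalibratedFrame) -> list[np.ndarray]:
    """Per-pixel photon estimate: calibrated value / 10 (sign preserved)."""
    return [p.astype(np.float64) / UNITS_PER_PHOTON for p in frame.panels]


def saturation_level_dc(
    params: CalibrationParams,
    saturation_adu: float,
    pedestal_adu: float,
    margin: float = 2.0,
) -> float:
    """Deci-photon value at which a pixel at the detector full well lands,
    minus a small margin, suitable as a spot-finder saturation flag level.

    With per-module gains the smallest module level is used (conservative).
    """
    scale_base = (
        params.pair_energy_ev / params.photon_energy_ev * params.units_per_photon
    )
    levels = [
        (saturation_adu - pedestal_adu) * g * scale_base for g in params.gains
    ]
    return float(np.floor(min(levels)) - margin)


# --------------------------------------------------------------------------
# dark reference persistence
# --------------------------------------------------------------------------

def save_dark(path: str | Path, dark: DarkReference) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["n_frames_used"] = dark.n_frames_used
        if dark.run_id is not None:
            f.attrs["run_id"] = dark.run_id
        for m, p in enumerate(dark.panel_means):
            f.create_dataset(f"module-{m}", data=p, compression="gzip", compression_opts=3)


def load_dark(path: str | Path) -> DarkReference:
    with h5py.File(path, "r") as f:
        n_panels = sum(1 for k in f.keys() if k.startswith("module-"))
        panels = [f[f"module-{m}"][()] for m in range(n_panels)]
        run_id = int(f.attrs["run_id"]) if "run_id" in f.attrs else None
        return DarkReference(
            panel_means=panels,
            n_frames_used=int(f.attrs["n_frames_used"]),
            run_id=run_id,
        )
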