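"""Blank rejection (ROI max/mean pre-filter), the spot-count hit rule and
pump-probe light/dark classification."""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np

from .calibration import CalibratedFrame, photons
from .geometry import DetectorGeometry, panel_radius_maps
from .spotfind import SpotList

logger = logging.getLogger(__name__)


class HitFindError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class HitParams:
    min_spots: int = 20
    llf_mode: str = "max"  # "max" | "mean" over the ROI
    llf_threshold_photons: float = 50.0
    pump_threshold: float = 0.5  # photodiode level separating light from dark

    def __post_init__(self) -> None:
        if self.min_spots < 1:
            raise HitFindError("min_spots must be >= 1")
        if self.llf_threshold_photons < 0:
            raise HitFindError("llf_threshold_photons must be >= 0")
        if self.llf_mode not in ("max", "mean"):
            raise HitFindError("llf_mode must be 'max' or 'mean'")


@dataclasses.dataclass
class HitDecision:
    tag: int
    passed_llf: bool
    n_spots: int
    is_hit: bool
    pump_state: str = "n/a"  # "light" | "dark" | "n/a"
    llf_value: float = math.nan


def ring_exclusion_roi(
    geometry: DetectorGeometry,
    radius_px: float,
    halfwidth_px: float,
    center_offset_px: tuple[float, float] = (0.0, 0.0),
) -> list[np.ndarray]:
    """Per-panel boolean ROI masking out an annular band around the beam
    center (True = pixel included)."""
    dx, dy = center_offset_px
    center = (
        geometry.beam_center_mm[0] + dx * geometry.pixel_size,
        geometry.beam_center_mm[1] + dy * geometry.pixel_size,
    )
    rois = []
    for rmap in panel_radius_maps(geometry, center):
        rois.append(np.abs(rmap - radius_px) > halfwidth_px)
    return rois


def llf_prefilter(
    frame: CalibratedFrame,
    params: HitParams,
    roi: Sequence[np.ndarray] | None = None,
) -> tuple[bool, float]:
    """Low-level blank rejection: max or mean photon value over the ROI.

    Returns ``(passed, llf_value_photons)``; passed iff value >= threshold.
    """
    phot = photons(frame)
    if roi is None:
        selected = phot
    else:
        selected = [p[m] for p, m in zip(phot, roi)]
    total = sum(int(s.size) for s in selected)
    if total == 0:
        raise HitFindError("LLF ROI selects no pixels")
    if params.llf_mode == "max":
        value = max(float(s.max()) for s in selected if s.size)
    else:
        value = sum(float(s.sum()) for s in selected) / total
    return value >= params.llf_threshold_photons, value


def classify_hit(
    spots: SpotList,
    params: HitParams,
    llf_passed: bool = True,
    llf_value: float = math.nan,
    pump_state: str = "n/a",
) -> HitDecision:
    """Spot-count rule: a frame is a hit iff it passed the pre-filter and
    has at least ``min_spots`` accepted spots (inclusive)."""
    n = len(spots.accepted)
    return HitDecision(
        tag=spots.tag,
        passed_llf=llf_passed,
        n_spots=n,
        is_hit=bool(llf_passed and n >= params.min_spots),
        pump_state=pump_state,
        llf_value=llf_value,
    )


def classify_pump_state(photodiode: float | None, threshold: float = 0.5) -> str:
    """Light iff the photodiode readout is at or above the threshold."""
    if photodiode is None or (isinstance(photodiode, float) and math.isnan(photodiode)):
        logger.warning("missing photodiode readout; pump state classified as n/a")
        return "n/a"
    return "light" if photodiode >= threshold else "dark"
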