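"""Bragg spot finding on calibrated frames.

Scheme: binarize each panel by an inclusive threshold, decompose strong
pixels into connected components (4- or 8-connectivity), then filter the
candidates by area and by signal-to-noise ratio.  The SNR of a candidate is
(peak - background) / noise, with background the median and noise the
MAD-based robust sigma of an annulus around the component's bounding box
(strong pixels excluded; noise floor of 1 deci-photon).  Components never
cross panel boundaries.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .calibration import CalibratedFrame

MAD_SIGMA = 1.4826  # robust sigma = MAD_SIGMA * median(|x - median|)
NOISE_FLOOR = 1.0  # deci-photons


class SpotFindError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class SpotFindParams:
    pixel_threshold: float = 50.0  # deci-photons (5 photons)
    connectivity: int = 8  # 4 or 8
    min_area: int = 1
    max_area: int = 100
    min_snr: float = 5.0
    annulus_inner: int = 2  # pixels beyond the bounding box, inclusive
    annulus_outer: int = 5
    saturation_value: float | None = None  # deci-photons; None -> never flagged

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise SpotFindError("connectivity must be 4 or 8")
        if not 1 <= self.min_area <= self.max_area:
            raise SpotFindError("need 1 <= min_area <= max_area")
        if self.min_snr < 0:
            raise SpotFindError("min_snr must be >= 0")
        if not 1 <= self.annulus_inner < self.annulus_outer:
            raise SpotFindError("need 1 <= annulus_inner < annulus_outer")


@dataclasses.dataclass
class SpotCandidate:
    module: int
    fast: float  # intensity-weighted centroid, sub-pixel
    slow: float
    area: int
    peak_value: float
    integrated_intensity: float  # background-subtracted sum, deci-photons
    snr: float
    is_saturated: bool
    background: float = 0.0
    noise: float = NOISE_FLOOR
    bg_fallback: bool = False  # annulus unusable; whole-panel statistics used


@dataclasses.dataclass
class SpotList:
    tag: int
    accepted: list[SpotCandidate]
    n_rejected_area: int = 0
    n_rejected_snr: int = 0

    @property
    def n_saturated(self) -> int:
        return sum(1 for c in self.accepted if c.is_saturated)


def _panels_of(frame: CalibratedFrame | Sequence[np.ndarray]) -> list[np.ndarray]:
    if isinstance(frame, CalibratedFrame):
        return frame.panels
    return list(frame)


def binarize(
    frame: CalibratedFrame | Sequence[np.ndarray], threshold: float
) -> list[np.ndarray]:
    """Per-panel boolean masks: True where value >= threshold (inclusive)."""
    return [np.asarray(p) >= threshold for p in _panels_of(frame)]


_STRUCT_4 = ndimage.generate_binary_structure(2, 1)
_STRUCT_8 = ndimage.generate_binary_structure(2, 2)


def connected_components(mask: np.ndarray, connectivity: int = 8) -> tuple[np.ndarray, int]:
    """Label maximal connected regions of a binary panel mask."""
    if connectivity not in (4, 8):
        raise SpotFindError("connectivity must be 4 or 8")
    structure = _STRUCT_8 if connectivity == 8 else _STRUCT_4
    labels, n = ndimage.label(mask, structure=structure)
    return labels, int(n)


def _annulus_stats(
    panel: np.ndarray,
    strong: np.ndarray,
    bbox: tuple[slice, slice],
    inner: int,
    outer: int,
) -> tuple[float, float, bool]:
    """(background, noise, fallback) from the annulus around a bounding box.

    The annulus is the set of pixels whose Chebyshev distance from the
    bounding box is in [inner, outer]; above-threshold (strong) pixels are
    excluded so neighbouring spots do not inflate the background.
    """
    sl_s, sl_f = bbox
    rows, cols = panel.shape
    os_lo, os_hi = max(0, sl_s.start - outer), min(rows, sl_s.stop + outer)
    of_lo, of_hi = max(0, sl_f.start - outer), min(cols, sl_f.stop + outer)
    window = panel[os_lo:os_hi, of_lo:of_hi]
    w_strong = strong[os_lo:os_hi, of_lo:of_hi]

    keep = np.ones(window.shape, dtype=bool)
    # carve out everything closer than `inner` to the bbox (the bbox itself
    # plus a guard band of inner-1 pixels)
    gs_lo, gs_hi = max(0, sl_s.start - (inner - 1)), min(rows, sl_s.stop + (inner - 1))
    gf_lo, gf_hi = max(0, sl_f.start - (inner - 1)), min(cols, sl_f.stop + (inner - 1))
    keep[gs_lo - os_lo : gs_hi - os_lo, gf_lo - of_lo : gf_hi - of_lo] = False
    keep &= ~w_strong

    values = window[keep]
    if values.size == 0:
        # fallback: whole-panel statistics excluding strong pixels
        values = panel[~strong]
        if values.size == 0:
            return 0.0, NOISE_FLOOR, True
        bg = float(np.median(values))
        mad = float(np.median(np.abs(values - bg)))
        return bg, max(MAD_SIGMA * mad, NOISE_FLOOR), True
    bg = float(np.median(values))
    mad = float(np.median(np.abs(values - bg)))
    return bg, max(MAD_SIGMA * mad, NOISE_FLOOR), False


def score_candidate(
    panel: np.ndarray,
    labels: np.ndarray,
    label_id: int,
    bbox: tuple[slice, slice],
    strong: np.ndarray,
    params: SpotFindParams,
    module: int,
) -> SpotCandidate:
    """Measure one connected component: centroid, area, intensity, SNR."""
    region = labels[bbox] == label_id
    values = panel[bbox][region].astype(np.float64)
    ss, ff = np.nonzero(region)
    slow = ss + bbox[0].start
    fast = ff + bbox[1].start

    background, noise, fallback = _annulus_stats(
        panel, strong, bbox, params.annulus_inner, params.annulus_outer
    )
    peak = float(values.max())
    wsum = values.sum()
    if wsum > 0:
        cf = float((fast * values).sum() / wsum)
        cs = float((slow * values).sum() / wsum)
    else:
        cf = float(fast.mean())
        cs = float(slow.mean())
    sat_level = params.saturation_value
    return SpotCandidate(
        module=module,
        fast=cf,
        slow=cs,
        area=int(values.size),
        peak_value=peak,
        integrated_intensity=float((values - background).sum()),
        snr=float((peak - background) / noise),
        is_saturated=bool(sat_level is not None and peak >= sat_level),
        background=background,
        noise=noise,
        bg_fallback=fallback,
    )


def find_spots(
    frame: CalibratedFrame,
    params: SpotFindParams,
    roi: Sequence[np.ndarray] | None = None,
) -> SpotList:
    """Run the full threshold -> components -> area/SNR filter pipeline.

    ``roi``, when given, is a per-panel boolean mask of pixels eligible for
    spot candidates (used e.g. to exclude a carrier-ring band).
    """
    panels = frame.panels
    result = SpotList(tag=frame.tag, accepted=[])
    for module, panel in enumerate(panels):
        panelf = panel.astype(np.float64)
        strong = panelf >= params.pixel_threshold
        search = strong if roi is None else (strong & roi[module])
        labels, n = connected_components(search, params.connectivity)
        if n == 0:
            continue
        objects = ndimage.find_objects(labels)
        for label_id, bbox in enumerate(objects, start=1):
            if bbox is None:
                continue
            area = int(np.count_nonzero(labels[bbox] == label_id))
            if not params.min_area <= area <= params.max_area:
                result.n_rejected_area += 1
                continue
            cand = score_candidate(
                panelf, labels, label_id, bbox, strong, params, module
            )
            if cand.snr < params.min_snr:
                result.n_rejected_snr += 1
                continue
            result.accepted.append(cand)
    return result


# --------------------------------------------------------------------------
# text output
# --------------------------------------------------------------------------

def spots_to_tsv(spots: SpotList, path: str | Path | None = None) -> str:
    """Tabular spot list (one row per accepted candidate)."""
    buf = io.StringIO()
    buf.write("tag\tpanel\tfast\tslow\tarea\tpeak\tintensity\tsnr\tsaturated\n")
    for c in spots.accepted:
        buf.write(
            f"{spots.tag}\t{c.module}\t{c.fast:.3f}\t{c.slow:.3f}\t{c.area}\t"
            f"{c.peak_value:.1f}\t{c.integrated_intensity:.1f}\t{c.snr:.3f}\t"
            f"{int(c.is_saturated)}\n"
        )
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def crystfel_peaks_block(spots: SpotList, slow_extent: int) -> str:
    """Stream-style text block (fs/px ss/px panel intensity), with ss given
    in stacked-array coordinates."""
    lines = ["Peaks from peak search", " fs/px   ss/px  panel  intensity"]
    for c in spots.accepted:
        ss = c.slow + c.module * slow_extent
        lines.append(
            f"{c.fast:8.2f} {ss:8.2f}  p{c.module}  {c.integrated_intensity:10.2f}"
        )
    lines.append("End of peak list")
    return "\n".join(lines) + "\n"
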