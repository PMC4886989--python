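"""Multi-event HDF5 store: one group ``tag-N`` per event.

Each group holds the stacked calibrated image (int16, deflate-compressed,
one chunk per module panel) and shot metadata.  The group name is derived
from the pulse tag so re-processing a run reproduces identical names.

Schema (documented here; readers tolerate unknown extra members)::

    /metadata                 group: file-level attributes
        run_id, pump_state, sfxprep_version, <parameter snapshot...>
    /tag-N/data               int16 (rows, cols), deflate
    /tag-N/peaks              float64 (n_spots, 5): fast, ss, panel, intensity, snr
    /tag-N@photon_energy_ev   float
    /tag-N@spectrum_mean_ev   float
    /tag-N@photodiode         float
    /tag-N@n_spots            int
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import h5py
import numpy as np

from .calibration import CalibratedFrame
from .spotfind import SpotList

_TAG_RE = re.compile(r"^tag-(\d+)$")

PEAK_COLUMNS = ("fast", "ss", "panel", "intensity", "snr")


class StoreError(ValueError):
    pass


class TagNotFoundError(KeyError):
    pass


@dataclasses.dataclass(frozen=True)
class StoreConfig:
    compression_level: int = 5  # deflate level, 0-9
    chunk_panels: int = 8  # chunk = image rows / chunk_panels (one panel)

    def __post_init__(self) -> None:
        if not 0 <= self.compression_level <= 9:
            raise StoreError("compression_level must be in [0, 9]")
        if self.chunk_panels < 1:
            raise StoreError("chunk_panels must be >= 1")


@dataclasses.dataclass
class EventRecord:
    tag: int
    image: np.ndarray  # stacked panels, int16
    photon_energy_ev: float
    spectrum_mean_ev: float
    photodiode: float
    n_spots: int
    peaks: np.ndarray  # (n_spots, 5) float64, columns PEAK_COLUMNS


def record_from(frame: CalibratedFrame, spots: SpotList, slow_extent: int) -> EventRecord:
    """Build an event record from a calibrated frame and its spot list."""
    peaks = np.array(
        [
            [
                c.fast,
                c.slow + c.module * slow_extent,
                float(c.module),
                c.integrated_intensity,
                c.snr,
            ]
            for c in spots.accepted
        ],
        dtype=np.float64,
    ).reshape(-1, len(PEAK_COLUMNS))
    return EventRecord(
        tag=frame.tag,
        image=frame.stacked(),
        photon_energy_ev=frame.photon_energy_ev,
        spectrum_mean_ev=frame.spectrum_mean_ev,
        photodiode=frame.photodiode,
        n_spots=len(spots.accepted),
        peaks=peaks,
    )


class EventStoreWriter:
    """Incremental writer for the multi-event store.

    Used as a context manager; on an exception the partial file is removed.
    ``mode="a"`` appends to an existing store (duplicate tags still refused).
    """

    def __init__(
        self,
        path: str | Path,
        config: StoreConfig = StoreConfig(),
        metadata: dict | None = None,
        mode: str = "w",
    ) -> None:
        if mode not in ("w", "a"):
            raise StoreError("mode must be 'w' or 'a'")
        self.path = Path(path)
        self.config = config
        existing = mode == "a" and self.path.exists()
        self._file = h5py.File(self.path, "a" if existing else "w")
        self._tags: set[int] = set()
        if existing:
            self._tags = {
                int(m.group(1))
                for name in self._file.keys()
                if (m := _TAG_RE.match(name))
            }
        if "metadata" not in self._file:
            meta = self._file.create_group("metadata")
            for key, value in (metadata or {}).items():
                meta.attrs[key] = value

    def append(self, record: EventRecord) -> None:
        if record.tag in self._tags:
            raise StoreError(f"duplicate tag {record.tag}")
        image = np.ascontiguousarray(record.image)
        rows, cols = image.shape
        chunk_rows = max(1, rows // self.config.chunk_panels)
        g = self._file.create_group(f"tag-{record.tag}")
        g.create_dataset(
            "data",
            data=image,
            chunks=(min(chunk_rows, rows), cols),
            compression="gzip",
            compression_opts=self.config.compression_level,
        )
        peaks = g.create_dataset("peaks", data=record.peaks)
        peaks.attrs["columns"] = ",".join(PEAK_COLUMNS)
        g.attrs["photon_energy_ev"] = record.photon_energy_ev
        g.attrs["spectrum_mean_ev"] = record.spectrum_mean_ev
        g.attrs["photodiode"] = record.photodiode
        g.attrs["n_spots"] = record.n_spots
        self._tags.add(record.tag)

    def close(self) -> None:
        self._file.close()

    def abort(self) -> None:
        self._file.close()
        self.path.unlink(missing_ok=True)

    def __enter__(self) -> "EventStoreWriter":
        return self

    def __exit__(self, exc_type, exc, tb) -> None:
        if exc_type is None:
            self.close()
        else:
            self.abort()


def write_events(
    path: str | Path,
    events: Iterable[EventRecord],
    config: StoreConfig = StoreConfig(),
    metadata: dict | None = None,
) -> None:
    """Write a complete event store; duplicate tags are rejected before any
    write touches the disk."""
    events = list(events)
    tags = [e.tag for e in events]
    if len(tags) != len(set(tags)):
        dup = sorted({t for t in tags if tags.count(t) > 1})
        raise StoreError(f"duplicate tags {dup}")
    with EventStoreWriter(path, config, metadata, mode="w") as writer:
        for event in events:
            writer.append(event)


def _read_record(g: h5py.Group, tag: int) -> EventRecord:
    return EventRecord(
        tag=tag,
        image=g["data"][()],
        photon_energy_ev=float(g.attrs["photon_energy_ev"]),
        spectrum_mean_ev=float(g.attrs["spectrum_mean_ev"]),
        photodiode=float(g.attrs["photodiode"]),
        n_spots=int(g.attrs["n_spots"]),
        peaks=g["peaks"][()],
    )


def read_event(path: str | Path, tag: int) -> EventRecord:
    """Read one event; decompression is transparent."""
    with h5py.File(path, "r") as f:
        name = f"tag-{tag}"
        if name not in f:
            raise TagNotFoundError(f"tag-{tag} not found in {path}")
        return _read_record(f[name], tag)


def list_tags(path: str | Path) -> list[int]:
    """Ascending unique tags parsed from group names; non-conforming group
    names are ignored with a warning."""
    tags = []
    with h5py.File(path, "r") as f:
        for name in f.keys():
            m = _TAG_RE.match(name)
            if m:
                tags.append(int(m.group(1)))
            elif name != "metadata":
                warnings.warn(f"ignoring non-event group {name!r} in {path}")
    return sorted(tags)


def iter_events(path: str | Path) -> Iterator[EventRecord]:
    with h5py.File(path, "r") as f:
        for tag in sorted(
            int(m.group(1)) for name in f.keys() if (m := _TAG_RE.match(name))
        ):
            yield _read_record(f[f"tag-{tag}"], tag)


def read_metadata(path: str | Path) -> dict:
    with h5py.File(path, "r") as f:
        if "metadata" not in f:
            return {}
        return dict(f["metadata"].attrs)
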