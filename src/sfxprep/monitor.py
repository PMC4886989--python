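"""Streaming run statistics: per-frame spot counts, rolling hit rate and
per-run summary tables.

The monitor log is an append-only TSV with one line per exposed frame
(tag, llf_value, n_spots, n_saturated, is_hit, pump_state, rolling rate).
Lines carry no timestamps so that re-running a deterministic pipeline
reproduces the log byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import math
from collections import deque
from pathlib import Path
from typing import IO, Iterable, Sequence

from .hitfind import HitDecision
from .spotfind import SpotList

LOG_COLUMNS = (
    "tag",
    "llf_value",
    "n_spots",
    "n_saturated",
    "is_hit",
    "pump_state",
    "rolling_hit_rate",
)


@dataclasses.dataclass
class MonitorSample:
    tag: int
    n_spots: int
    n_saturated: int
    is_hit: bool
    rolling_hit_rate: float
    llf_value: float = math.nan
    pump_state: str = "n/a"


@dataclasses.dataclass
class RunSummary:
    run_id: int
    n_frames: int  # dark block + exposed
    n_exposed: int
    n_hits: int
    hit_rate: float  # n_hits / n_exposed
    n_saturated_frames: int  # exposed frames with >= 1 saturated accepted spot
    n_light: int
    n_dark: int  # pump-probe dark (not the shutter-closed block)
    no_exposed: bool = False


class HitRateMonitor:
    """Incremental monitor over the exposed-frame stream.

    ``window`` is the count-based rolling window (default 100 exposed
    frames); ``cumulative=True`` switches to an all-history rate.
    """

    def __init__(
        self,
        window: int = 100,
        cumulative: bool = False,
        log: IO[str] | None = None,
        write_header: bool = True,
    ) -> None:
        if window < 1:
            raise ValueError("window must be >= 1")
        self.window = window
        self.cumulative = cumulative
        self.samples: list[MonitorSample] = []
        self._recent: deque[bool] = deque(maxlen=window)
        self._n_hits = 0
        self._log = log
        if log is not None and write_header:
            log.write("\t".join(LOG_COLUMNS) + "\n")

    def update(self, decision: HitDecision, spots: SpotList) -> MonitorSample:
        """Fold one exposed-frame decision into the statistics."""
        self._recent.append(decision.is_hit)
        self._n_hits += int(decision.is_hit)
        if self.cumulative:
            rate = self._n_hits / (len(self.samples) + 1)
        else:
            rate = sum(self._recent) / len(self._recent)
        sample = MonitorSample(
            tag=decision.tag,
            n_spots=decision.n_spots,
            n_saturated=spots.n_saturated,
            is_hit=decision.is_hit,
            rolling_hit_rate=rate,
            llf_value=decision.llf_value,
            pump_state=decision.pump_state,
        )
        self.samples.append(sample)
        if self._log is not None:
            self._log.write(format_log_line(sample))
        return sample

    def replay(self, samples: Iterable[MonitorSample]) -> None:
        """Rebuild internal state from previously logged samples (without
        re-writing them), e.g. when resuming an interrupted run."""
        for s in samples:
            self._recent.append(s.is_hit)
            self._n_hits += int(s.is_hit)
            self.samples.append(s)


def format_log_line(s: MonitorSample) -> str:
    return (
        f"{s.tag}\t{s.llf_value:.3f}\t{s.n_spots}\t{s.n_saturated}\t"
        f"{int(s.is_hit)}\t{s.pump_state}\t{s.rolling_hit_rate:.6f}\n"
    )


def read_log(path: str | Path) -> list[MonitorSample]:
    samples = []
    with open(path) as f:
        header = f.readline().rstrip("\n").split("\t")
        assert tuple(header) == LOG_COLUMNS, f"unexpected log header {header}"
        for line in f:
            tag, llf, n_spots, n_sat, is_hit, pump, rate = line.rstrip("\n").split("\t")
            samples.append(
                MonitorSample(
                    tag=int(tag),
                    n_spots=int(n_spots),
                    n_saturated=int(n_sat),
                    is_hit=bool(int(is_hit)),
                    rolling_hit_rate=float(rate),
                    llf_value=float(llf),
                    pump_state=pump,
                )
            )
    return samples


def summarize_run(
    samples: Sequence[MonitorSample],
    run_id: int = 0,
    n_dark_frames: int = 0,
) -> RunSummary:
    """Totals over a completed run; shutter-closed dark frames count toward
    n_frames but never enter the hit-rate denominator."""
    n_exposed = len(samples)
    n_hits = sum(1 for s in samples if s.is_hit)
    return RunSummary(
        run_id=run_id,
        n_frames=n_dark_frames + n_exposed,
        n_exposed=n_exposed,
        n_hits=n_hits,
        hit_rate=(n_hits / n_exposed) if n_exposed else 0.0,
        n_saturated_frames=sum(1 for s in samples if s.n_saturated > 0),
        n_light=sum(1 for s in samples if s.pump_state == "light"),
        n_dark=sum(1 for s in samples if s.pump_state == "dark"),
        no_exposed=n_exposed == 0,
    )


def combine_summaries(summaries: Sequence[RunSummary], run_id: int = -1) -> RunSummary:
    """Additive roll-up across runs (or across splits of one run)."""
    n_frames = sum(s.n_frames for s in summaries)
    n_exposed = sum(s.n_exposed for s in summaries)
    n_hits = sum(s.n_hits for s in summaries)
    return RunSummary(
        run_id=run_id,
        n_frames=n_frames,
        n_exposed=n_exposed,
        n_hits=n_hits,
        hit_rate=(n_hits / n_exposed) if n_exposed else 0.0,
        n_saturated_frames=sum(s.n_saturated_frames for s in summaries),
        n_light=sum(s.n_light for s in summaries),
        n_dark=sum(s.n_dark for s in summaries),
        no_exposed=n_exposed == 0,
    )


def write_summary(summary: RunSummary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(summary), indent=2) + "\n")


def read_summary(path: str | Path) -> RunSummary:
    return RunSummary(**json.loads(Path(path).read_text()))


def plot_trace(samples: Sequence[MonitorSample], path: str | Path) -> None:
    """Render the spots / saturated-spots / hit-rate trace to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = range(len(samples))
    fig, ax = plt.subplots(figsize=(9, 4))
    ax.plot(x, [s.n_spots for s in samples], ".", color="red", ms=2, label="spots")
    ax.plot(
        x,
        [s.n_saturated for s in samples],
        ".",
        color="blue",
        ms=2,
        label="saturated spots",
    )
    ax.set_xlabel("exposed frame")
    ax.set_ylabel("count")
    ax2 = ax.twinx()
    ax2.plot(
        x, [s.rolling_hit_rate for s in samples], "-", color="blue", label="hit rate"
    )
    ax2.set_ylabel("hit rate")
    ax2.set_ylim(0, 1)
    ax.legend(loc="upper left")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
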