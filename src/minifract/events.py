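"""Event-train containers and binning.

The unit of analysis throughout the package is an :class:`EventSeries`: an
ordered list of event times (spontaneous vesicle-fusion times, detected mini
onsets, simulated release events, ...) together with the observation span
``L``.  Count series derived from it by binning underlie both the count-based
periodogram and the Allan factor.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventSeries",
    "CountSeries",
    "bin_counts",
    "superpose",
    "read_events",
    "write_events",
]


@dataclass(frozen=True)
class EventSeries:
    """Ordered event times on ``[0, span]``.

    Parameters
    ----------
    times:
        Event times in seconds, strictly increasing, all within ``[0, span]``.
    span:
        Observation length ``L`` in seconds (at least the last event time).
    """

    times: np.ndarray
    span: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValueError("event times must be one-dimensional")
        if self.span <= 0:
            raise ValueError("span must be positive")
        if t.size:
            if np.any(np.diff(t) < 0):
                raise ValueError("event times must be sorted ascending")
            if t[0] < 0 or t[-1] > self.span:
                raise ValueError("event times must lie within [0, span]")

    @property
    def n_events(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        """Mean event rate in Hz."""
        return self.n_events / self.span


@dataclass(frozen=True)
class CountSeries:
    """Binned event counts with a fixed bin width.

    ``counts[k]`` is the number of events in ``[origin + k*w, origin + (k+1)*w)``
    with ``w = bin_width``; boundary events belong to the later bin.
    """

    counts: np.ndarray
    bin_width: float
    origin: float = 0.0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if c.size and (np.any(c < 0) or not np.issubdtype(c.dtype, np.integer)):
            c = c.astype(np.int64)
            if np.any(c < 0):
                raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", np.asarray(c, dtype=np.int64))

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)


def bin_counts(
    events: EventSeries,
    bin_width: float,
    interval: tuple[float, float] | None = None,
) -> CountSeries:
    """Count events in contiguous half-open bins over ``interval``.

    The interval defaults to ``[0, span)``; only full bins are formed, so the
    covered stretch is ``floor((end - start)/bin_width)`` bins long.  Events on
    a bin boundary are assigned to the later bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    start, end = interval if interval is not None else (0.0, events.span)
    if not (0.0 <= start < end <= events.span + 1e-12):
        raise ValueError("interval must satisfy 0 <= start < end <= span")
    n_bins = int(np.floor((end - start) / bin_width + 1e-9))
    if n_bins < 1:
        raise ValueError("interval shorter than one bin")
    edges = start + bin_width * np.arange(n_bins + 1)
    # np.histogram treats the last bin as closed; use searchsorted for
    # strictly half-open bins throughout.
    t = events.times
    sel = t[(t >= start) & (t < edges[-1])]
    idx = np.floor((sel - start) / bin_width).astype(np.int64)
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return CountSeries(counts=counts, bin_width=bin_width, origin=start)


def superpose(series: Sequence[EventSeries]) -> EventSeries:
    """Merge event trains from independent release sites into one series.

    All inputs must share the same span; the result is the sorted union of
    event times (ties preserved), modelling simultaneous observation of ``N``
    independent sites.
    """
    if not series:
        raise ValueError("need at least one series")
    span = series[0].span
    for s in series[1:]:
        if abs(s.span - span) > 1e-9:
            raise ValueError("all series must share the same span")
    merged = np.sort(np.concatenate([s.times for s in series]))
    return EventSeries(times=merged, span=span)


def read_events(path: str | Path) -> EventSeries:
    """Read an event series from text.

    Accepts a single-column file or a CSV with a ``time_s`` column (and an
    optional ``site_id`` column, ignored here).  A header line is required for
    CSV input.  The span is taken as the last event time unless a comment line
    ``# span_s = <value>`` is present.
    """
    path = Path(path)
    span = None
    with open(path) as fh:
        head = fh.readline()
    if head.startswith("#") and "span_s" in head:
        span = float(head.split("=")[1])
        df = pd.read_csv(path, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    if "time_s" in df.columns:
        times = df["time_s"].to_numpy(dtype=float)
    elif df.shape[1] == 1:
        times = df.iloc[:, 0].to_numpy(dtype=float)
    else:
        raise ValueError(
            f"{path}: expected a 'time_s' column or a single column of times; "
            f"got columns {list(df.columns)}"
        )
    order = np.argsort(times, kind="stable")
    times = times[order]
    if span is None:
        span = float(times[-1]) if times.size else 1.0
    return EventSeries(times=times, span=span)


def write_events(events: EventSeries, path: str | Path) -> None:
    """Write an event series as CSV with a span comment and header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# span_s = {float(events.span)!r}\n")
        fh.write("time_s\n")
        for t in events.times:
            fh.write(f"{float(t)!r}\n")
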