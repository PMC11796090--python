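"""Unified TTTR event data model and stream selection algorithms.

A time-tagged time-resolved (TTTR) measurement is a sequence of events.
Each event carries a *macro time* (coarse clock ticks, in pulsed
experiments synchronised to the laser), a *micro time* (TCSPC channel:
the fine delay relative to the last sync pulse), a *routing channel*
(detector / electronics input id) and an event type distinguishing
photons from scan markers.  :class:`EventStream` stores these as four
parallel arrays plus a :class:`HeaderInfo` with the clock calibration.

Macro times are always absolute, overflow-corrected ticks; readers
resolve hardware counter overflows before constructing a stream, so
every algorithm here may assume a non-decreasing macro-time axis.

All indexing is 0-based and all ranges are half-open ``[lo, hi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

from .errors import CompatibilityError, ParameterError

__all__ = [
    "EventType",
    "HeaderInfo",
    "EventStream",
    "IndexSelection",
    "slice_stream",
    "merge_streams",
    "select_channels",
    "select_time_window",
    "microtime_gate",
    "intensity_trace",
]


class EventType(IntEnum):
    """Event kinds carried in a stream; markers encode scan geometry."""

    PHOTON = 0
    MARKER = 1


@dataclass
class HeaderInfo:
    """Clock calibration and free-form metadata of a TTTR stream.

    Parameters
    ----------
    macro_time_resolution
        Seconds per macro clock tick (> 0).  In a pulsed experiment this
        is the laser repetition period.
    micro_time_resolution
        Seconds per TCSPC micro-time channel (> 0).
    n_microtime_channels
        Number of TCSPC channels; every micro time is below this.
    source_format
        Tag naming the container the stream was read from.
    metadata
        Ordered key/value map of preserved vendor or user fields.  It
        round-trips losslessly through the supported containers.
    """

    macro_time_resolution: float
    micro_time_resolution: float
    n_microtime_channels: int
    source_format: str = "memory"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.macro_time_resolution <= 0:
            raise ParameterError("macro_time_resolution must be > 0")
        if self.micro_time_resolution <= 0:
            raise ParameterError("micro_time_resolution must be > 0")
        if self.n_microtime_channels < 1:
            raise ParameterError("n_microtime_channels must be >= 1")

    @property
    def micro_time_span(self) -> float:
        """Seconds covered by the full TCSPC range."""
        return self.micro_time_resolution * self.n_microtime_channels

    def is_pulsed_consistent(self, rtol: float = 0.01) -> bool:
        """Whether the TCSPC range fits in one macro period (within rtol)."""
        return self.micro_time_span <= self.macro_time_resolution * (1.0 + rtol)

    def copy(self) -> "HeaderInfo":
        return replace(self, metadata=dict(self.metadata))

    def compatible_with(self, other: "HeaderInfo") -> bool:
        return (
            self.micro_time_resolution == other.micro_time_resolution
            and self.n_microtime_channels == other.n_microtime_channels
            and self.macro_time_resolution == other.macro_time_resolution
        )


@dataclass
class EventStream:
    """Parallel-array container for a TTTR photon/marker stream."""

    macro_times: np.ndarray
    micro_times: np.ndarray
    routing_channels: np.ndarray
    event_types: np.ndarray
    header: HeaderInfo

    def __post_init__(self) -> None:
        self.macro_times = np.asarray(self.macro_times, dtype=np.uint64)
        self.micro_times = np.asarray(self.micro_times, dtype=np.uint32)
        self.routing_channels = np.asarray(self.routing_channels, dtype=np.uint16)
        self.event_types = np.asarray(self.event_types, dtype=np.uint8)
        n = len(self.macro_times)
        for arr, name in (
            (self.micro_times, "micro_times"),
            (self.routing_channels, "routing_channels"),
            (self.event_types, "event_types"),
        ):
            if len(arr) != n:
                raise ParameterError(f"{name} length {len(arr)} != {n}")

    def validate(self) -> None:
        """Check the container invariants; raises ParameterError on violation."""
        if self.n_events and np.any(np.diff(self.macro_times.astype(np.int64)) < 0):
            raise ParameterError("macro_times must be non-decreasing")
        if self.n_events and int(self.micro_times.max()) >= self.header.n_microtime_channels:
            raise ParameterError("micro time exceeds n_microtime_channels")
        if self.n_events and int(self.event_types.max()) > 1:
            raise ParameterError("unknown event type")

    # -- basic introspection -------------------------------------------------

    @property
    def n_events(self) -> int:
        return len(self.macro_times)

    def __len__(self) -> int:
        return self.n_events

    @property
    def photon_mask(self) -> np.ndarray:
        return self.event_types == EventType.PHOTON

    @property
    def marker_mask(self) -> np.ndarray:
        return self.event_types == EventType.MARKER

    def times(self) -> np.ndarray:
        """Absolute event times in seconds (macro ticks x resolution)."""
        return self.macro_times.astype(np.float64) * self.header.macro_time_resolution

    @property
    def duration(self) -> float:
        """Span between first and last event, seconds (0 if < 2 events)."""
        if self.n_events < 2:
            return 0.0
        t = self.macro_times
        return float(t[-1] - t[0]) * self.header.macro_time_resolution

    def equal(self, other: "EventStream") -> bool:
        """Field-by-field equality of event arrays, clocks and metadata."""
        return (
            np.array_equal(self.macro_times, other.macro_times)
            and np.array_equal(self.micro_times, other.micro_times)
            and np.array_equal(self.routing_channels, other.routing_channels)
            and np.array_equal(self.event_types, other.event_types)
            and self.header.macro_time_resolution == other.header.macro_time_resolution
            and self.header.micro_time_resolution == other.header.micro_time_resolution
            and self.header.n_microtime_channels == other.header.n_microtime_channels
            and self.header.metadata == other.header.metadata
        )

    def take(self, indices: np.ndarray) -> "EventStream":
        """New stream holding the events at ``indices`` (order preserved)."""
        idx = np.asarray(indices, dtype=np.int64)
        return EventStream(
            self.macro_times[idx],
            self.micro_times[idx],
            self.routing_channels[idx],
            self.event_types[idx],
            self.header.copy(),
        )

    @classmethod
    def empty(cls, header: HeaderInfo) -> "EventStream":
        z = np.zeros(0, dtype=np.uint64)
        return cls(z, z.astype(np.uint32), z.astype(np.uint16), z.astype(np.uint8), header.copy())


@dataclass
class IndexSelection:
    """Strictly increasing event indices plus a provenance note."""

    indices: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ParameterError("selection indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)

    def intersect(self, other: "IndexSelection") -> "IndexSelection":
        common = np.intersect1d(self.indices, other.indices, assume_unique=True)
        return IndexSelection(common, f"({self.provenance}) & ({other.provenance})")


# ---------------------------------------------------------------------------
# stream manipulation
# ---------------------------------------------------------------------------


def slice_stream(stream: EventStream, start: int, stop: int) -> EventStream:
    """Events in the half-open index range ``[start, stop)`` as a new stream."""
    if not (0 <= start <= stop <= stream.n_events):
        raise ParameterError(
            f"slice [{start}, {stop}) out of range for {stream.n_events} events"
        )
    return EventStream(
        stream.macro_times[start:stop].copy(),
        stream.micro_times[start:stop].copy(),
        stream.routing_channels[start:stop].copy(),
        stream.event_types[start:stop].copy(),
        stream.header.copy(),
    )


def merge_streams(a: EventStream, b: EventStream) -> EventStream:
    """Time-sorted union of two streams.

    The merge is stable: events keep their relative order, and at equal
    macro times events from ``a`` precede events from ``b``.  Headers
    must agree on both clock resolutions and the TCSPC channel count.
    """
    if not a.header.compatible_with(b.header):
        raise CompatibilityError("streams have incompatible clock/TCSPC headers")
    macro = np.concatenate([a.macro_times, b.macro_times])
    order = np.argsort(macro, kind="stable")
    return EventStream(
        macro[order],
        np.concatenate([a.micro_times, b.micro_times])[order],
        np.concatenate([a.routing_channels, b.routing_channels])[order],
        np.concatenate([a.event_types, b.event_types])[order],
        a.header.copy(),
    )


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------


def select_channels(stream, channels, types=(EventType.PHOTON,)) -> IndexSelection:
    """Indices of events on the given routing channels and event types."""
    ch = np.isin(stream.routing_channels, np.asarray(sorted(channels), dtype=np.uint16))
    ty = np.isin(stream.event_types, np.asarray([int(t) for t in types], dtype=np.uint8))
    idx = np.flatnonzero(ch & ty)
    return IndexSelection(idx, f"channels={sorted(channels)} types={sorted(int(t) for t in types)}")


def select_time_window(
    stream: EventStream,
    window: float,
    n_min: int,
    n_max: int | None = None,
    invert: bool = False,
) -> IndexSelection:
    """Photons whose local count rate passes an intensity threshold.

    A photon at time ``t`` is selected iff the number of photons (any
    routing channel, the photon itself included) with macro time in the
    closed, centred window ``[t - window/2, t + window/2]`` lies in
    ``[n_min, n_max]``.  ``invert`` complements the rule over photons;
    markers are never selected either way.
    """
    if window <= 0:
        raise ParameterError("window must be > 0")
    if n_min < 1:
        raise ParameterError("n_min must be >= 1")
    photon_idx = np.flatnonzero(stream.photon_mask)
    t = stream.macro_times[photon_idx].astype(np.float64) * stream.header.macro_time_resolution
    half = window / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    counts = hi - lo
    ok = counts >= n_min
    if n_max is not None:
        ok &= counts <= n_max
    if invert:
        ok = ~ok
    return IndexSelection(
        photon_idx[ok],
        f"time_window(window={window}, n_min={n_min}, n_max={n_max}, invert={invert})",
    )


def microtime_gate(stream: EventStream, lo: int, hi: int) -> IndexSelection:
    """Photon indices with micro time in the half-open gate ``[lo, hi)``."""
    if not (0 <= lo <= hi <= stream.header.n_microtime_channels):
        raise ParameterError(f"invalid micro-time gate [{lo}, {hi})")
    mask = stream.photon_mask & (stream.micro_times >= lo) & (stream.micro_times < hi)
    return IndexSelection(np.flatnonzero(mask), f"microtime_gate[{lo},{hi})")


def intensity_trace(
    stream: EventStream,
    bin_width: float,
    selection: IndexSelection | None = None,
):
    """Binned photon-count time trace.

    Returns ``(bin_starts, counts)`` in seconds/counts.  Bins of width
    ``bin_width`` tile ``[t_first, t_last]`` of the selected photons;
    the final photon is counted in the last bin.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    if selection is None:
        idx = np.flatnonzero(stream.photon_mask)
    else:
        idx = selection.indices[stream.photon_mask[selection.indices]]
    if idx.size == 0:
        return np.zeros(0), np.zeros(0, dtype=np.int64)
    t = stream.macro_times[idx].astype(np.float64) * stream.header.macro_time_resolution
    t0 = t[0]
    n_bins = max(1, int(np.ceil((t[-1] - t0) / bin_width)))
    which = np.minimum(((t - t0) / bin_width).astype(np.int64), n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    starts = t0 + bin_width * np.arange(n_bins)
    return starts, counts
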