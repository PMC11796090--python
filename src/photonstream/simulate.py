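"""Synthetic TTTR photon streams with known ground truth.

Three generators cover the inputs the analysis layers need:

* :func:`simulate_background` — homogeneous Poisson photons per detector
  channel with uniform micro times (uncorrelated background light).
* :func:`simulate_bursts` — single-molecule FRET burst trains: bursts are
  rectangular intensity epochs (Poisson starts, exponential durations);
  within a burst each photon goes to the acceptor channel with
  probability E, otherwise to the donor.  Micro times follow the
  standard kinetic picture: the donor decay is quenched to
  ``tau_d * (1 - E)`` and an acceptor photon is emitted after a
  donor-residence delay plus its own ``tau_a`` decay.  Gaussian IRF
  jitter is added and the delay wrapped into the repetition period.
* :func:`simulate_clsm_scan` — a raster scan: per frame a frame marker,
  then per line a start marker, W pixel dwell intervals emitting
  photons at that pixel's rate with that pixel's mono-exponential
  lifetime, and a stop marker.

Diffusion, triplet blinking and polarisation are deliberately absent:
bursts are rectangular and rates are constant within an epoch, which is
what makes recovery by the analysis layers exactly scorable.

All randomness flows through one ``numpy.random.Generator`` seeded per
call; the same seed reproduces the same stream bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EventStream, EventType, HeaderInfo
from .errors import ParameterError

__all__ = [
    "SimGroundTruth",
    "default_header",
    "simulate_background",
    "simulate_bursts",
    "simulate_clsm_scan",
]

DONOR_CHANNEL = 0
ACCEPTOR_CHANNEL = 1


@dataclass
class SimGroundTruth:
    """What the generator actually drew, for scoring downstream recovery."""

    seed: int
    burst_intervals: np.ndarray | None = None      # (n_bursts, 2) seconds
    burst_efficiency: np.ndarray | None = None     # per burst, true E
    donor_lifetime: float | None = None            # quenched, seconds
    acceptor_lifetime: float | None = None         # seconds
    background_rates: dict = field(default_factory=dict)  # channel -> Hz
    rate_map: np.ndarray | None = None             # (H, W) Hz
    lifetime_map: np.ndarray | None = None         # (H, W) seconds
    pixel_photon_counts: np.ndarray | None = None  # (n_frames, H, W) drawn signal photons
    burst_photon_count: int = 0


def default_header(
    rep_period: float = 50e-9,
    n_microtime_channels: int = 256,
    source_format: str = "simulated",
) -> HeaderInfo:
    """Pulsed-experiment header: one macro tick per laser period."""
    return HeaderInfo(
        macro_time_resolution=rep_period,
        micro_time_resolution=rep_period / n_microtime_channels,
        n_microtime_channels=n_microtime_channels,
        source_format=source_format,
    )


def _assemble(header, t_seconds, micro_channels, channels, etypes) -> EventStream:
    """Quantise absolute times to macro ticks and time-sort (stable)."""
    macro = np.floor(t_seconds / header.macro_time_resolution).astype(np.uint64)
    order = np.argsort(macro, kind="stable")
    return EventStream(
        macro[order],
        np.asarray(micro_channels, dtype=np.uint32)[order],
        np.asarray(channels, dtype=np.uint16)[order],
        np.asarray(etypes, dtype=np.uint8)[order],
        header,
    )


def _micro_channel(header: HeaderInfo, delay_seconds: np.ndarray) -> np.ndarray:
    wrapped = np.mod(delay_seconds, header.macro_time_resolution)
    ch = np.floor(wrapped / header.micro_time_resolution).astype(np.int64)
    return np.minimum(ch, header.n_microtime_channels - 1)


def _poisson_times(rng, rate: float, duration: float) -> np.ndarray:
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def simulate_background(
    rate_per_channel: dict,
    duration: float,
    rep_period: float = 50e-9,
    header: HeaderInfo | None = None,
    seed: int = 0,
) -> EventStream:
    """Homogeneous Poisson background, uniform micro times, per channel."""
    if duration <= 0:
        raise ParameterError("duration must be > 0")
    if header is None:
        header = default_header(rep_period)
    rng = np.random.default_rng(seed)
    times, micros, chans = [], [], []
    for ch in sorted(rate_per_channel):
        rate = rate_per_channel[ch]
        if rate < 0:
            raise ParameterError("rates must be >= 0")
        t = _poisson_times(rng, rate, duration)
        times.append(t)
        micros.append(rng.integers(0, header.n_microtime_channels, size=len(t)))
        chans.append(np.full(len(t), ch))
    if not times:
        return EventStream.empty(header)
    t = np.concatenate(times)
    return _assemble(
        header,
        t,
        np.concatenate(micros),
        np.concatenate(chans),
        np.zeros(len(t), dtype=np.uint8),
    )


def simulate_bursts(
    burst_rate: float = 2.0,
    mean_duration: float = 4e-3,
    brightness: float = 50e3,
    E: float = 0.5,
    lifetimes: tuple = (4e-9, 2e-9),
    irf_sigma: float = 0.2e-9,
    rep_period: float = 50e-9,
    background: dict | None = None,
    duration: float = 60.0,
    seed: int = 0,
    header: HeaderInfo | None = None,
):
    """Single-molecule FRET burst train plus its ground truth.

    Defaults emulate a dilute diffusing-molecule experiment: ~2 bursts/s
    of ~4 ms and 50 kHz molecular brightness over a 0.5-1 kHz background,
    donor lifetime 4 ns quenched by FRET, acceptor 2 ns, 20 MHz laser.

    Returns ``(stream, SimGroundTruth)``.  Overlapping burst drawings are
    discarded so the recorded intervals are disjoint and sorted.
    """
    if not 0.0 <= E <= 1.0:
        raise ParameterError("E must lie in [0, 1]")
    tau_d, tau_a = lifetimes
    if header is None:
        header = default_header(rep_period)
    rng = np.random.default_rng(seed)
    background = dict(background or {})

    starts = _poisson_times(rng, burst_rate, duration)
    durs = rng.exponential(mean_duration, size=len(starts))
    intervals = []
    prev_stop = -np.inf
    for t0, d in zip(starts, durs):
        t1 = min(t0 + d, duration)
        if t0 >= prev_stop and t1 > t0:
            intervals.append((t0, t1))
            prev_stop = t1
    intervals = np.asarray(intervals, dtype=float).reshape(-1, 2)

    tau_q = tau_d * (1.0 - E)
    times, micros, chans = [], [], []
    for t0, t1 in intervals:
        n = rng.poisson(brightness * (t1 - t0))
        t = np.sort(rng.uniform(t0, t1, size=n))
        is_acceptor = rng.random(n) < E
        residence = rng.exponential(tau_q, size=n) if tau_q > 0 else np.zeros(n)
        delay = residence.copy()
        delay[is_acceptor] += rng.exponential(tau_a, size=int(is_acceptor.sum()))
        if irf_sigma > 0:
            delay += rng.normal(0.0, irf_sigma, size=n)
        times.append(t)
        micros.append(_micro_channel(header, delay))
        chans.append(np.where(is_acceptor, ACCEPTOR_CHANNEL, DONOR_CHANNEL))

    n_signal = sum(len(t) for t in times)
    if times:
        stream = _assemble(
            header,
            np.concatenate(times),
            np.concatenate(micros),
            np.concatenate(chans),
            np.zeros(n_signal, dtype=np.uint8),
        )
    else:
        stream = EventStream.empty(header)
    if background:
        from .core import merge_streams

        bg = simulate_background(
            background, duration, header=header.copy(), seed=int(rng.integers(2**31))
        )
        stream = merge_streams(stream, bg)

    truth = SimGroundTruth(
        seed=seed,
        burst_intervals=intervals,
        burst_efficiency=np.full(len(intervals), E),
        donor_lifetime=tau_q,
        acceptor_lifetime=tau_a,
        background_rates=background,
        burst_photon_count=n_signal,
    )
    return stream, truth


def simulate_clsm_scan(
    rate_map: np.ndarray,
    lifetime_map: np.ndarray,
    dwell_time: float = 10e-6,
    n_frames: int = 1,
    marker_config: tuple = (4, 1, 2),
    rep_period: float = 50e-9,
    background: float = 0.0,
    retrace_time: float | None = None,
    channel: int = 0,
    seed: int = 0,
    header: HeaderInfo | None = None,
):
    """Raster-scan photon stream with frame/line markers plus ground truth.

    ``marker_config`` is ``(frame_marker_id, line_start_id, line_stop_id)``;
    markers carry the id as routing channel.  Pixel dwell boundaries are
    snapped to macro ticks so that every signal photon's drawn pixel is
    exactly recoverable from the marker times.  ``retrace_time`` is the
    dead time after each line (default: 4 pixel dwells); background
    photons are emitted over the whole scan, including retrace.
    """
    rate_map = np.asarray(rate_map, dtype=float)
    lifetime_map = np.asarray(lifetime_map, dtype=float)
    if rate_map.shape != lifetime_map.shape or rate_map.ndim != 2:
        raise ParameterError("rate_map and lifetime_map must share an (H, W) shape")
    if dwell_time <= 0:
        raise ParameterError("dwell_time must be > 0")
    if header is None:
        header = default_header(rep_period)
    res = header.macro_time_resolution
    H, W = rate_map.shape
    frame_id, line_start_id, line_stop_id = marker_config

    dwell_ticks = max(1, round(dwell_time / res))
    dwell = dwell_ticks * res
    if retrace_time is None:
        retrace_ticks = 4 * dwell_ticks
    else:
        retrace_ticks = max(0, round(retrace_time / res))

    rng = np.random.default_rng(seed)
    ticks, micros, chans, etypes = [], [], [], []
    counts = np.zeros((n_frames, H, W), dtype=np.int64)

    # all event times are integer macro ticks: pixel boundaries fall on
    # ticks, so the drawn pixel of every signal photon is exactly
    # recoverable from the marker times by integer arithmetic
    def emit(u, micro, ch, et):
        u = np.atleast_1d(np.asarray(u, dtype=np.int64))
        n = len(u)
        ticks.append(u)
        micros.append(np.broadcast_to(np.asarray(micro, dtype=np.int64), n).copy())
        chans.append(np.broadcast_to(np.asarray(ch, dtype=np.int64), n).copy())
        etypes.append(np.broadcast_to(np.asarray(et, dtype=np.uint8), n).copy())

    tick = 0
    for f in range(n_frames):
        emit(tick, 0, frame_id, EventType.MARKER)
        for line in range(H):
            emit(tick, 0, line_start_id, EventType.MARKER)
            line_start_tick = tick
            for px in range(W):
                n = rng.poisson(rate_map[line, px] * dwell)
                if n:
                    offs = np.floor(rng.uniform(0.0, dwell, size=n) / res).astype(np.int64)
                    offs = np.minimum(offs, dwell_ticks - 1)
                    u = np.sort(line_start_tick + px * dwell_ticks + offs)
                    tau = lifetime_map[line, px]
                    delay = rng.exponential(tau, size=n) if tau > 0 else np.zeros(n)
                    emit(u, _micro_channel(header, delay), channel, EventType.PHOTON)
                    counts[f, line, px] = n
            tick = line_start_tick + W * dwell_ticks
            emit(tick, 0, line_stop_id, EventType.MARKER)
            tick += retrace_ticks
    total_ticks = tick

    if background > 0:
        n = rng.poisson(background * total_ticks * res)
        u = np.sort(rng.integers(0, total_ticks, size=n))
        emit(
            u,
            rng.integers(0, header.n_microtime_channels, size=n),
            np.full(n, channel),
            np.full(n, EventType.PHOTON, dtype=np.uint8),
        )

    all_ticks = np.concatenate(ticks)
    order = np.argsort(all_ticks, kind="stable")
    stream = EventStream(
        all_ticks[order].astype(np.uint64),
        np.concatenate(micros)[order].astype(np.uint32),
        np.concatenate(chans)[order].astype(np.uint16),
        np.concatenate(etypes)[order],
        header,
    )
    truth = SimGroundTruth(
        seed=seed,
        rate_map=rate_map,
        lifetime_map=lifetime_map,
        pixel_photon_counts=counts,
        background_rates={channel: background},
    )
    return stream, truth
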