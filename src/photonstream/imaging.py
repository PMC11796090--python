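"""Image reconstruction and per-pixel spectroscopy for CLSM photon streams.

A laser-scanning microscope emits marker events interleaved with
photons: a frame marker at each frame start and a start/stop marker pair
around every scanned line.  :func:`build_image_stack` turns that into a
frame -> line -> pixel hierarchy by splitting each line's time span into
``n_pixels`` equal dwell intervals; photons falling outside any line are
discarded with a counted tally, never silently.

On top of the stack:

* :func:`intensity_image` — photon counts per pixel;
* :func:`mean_microtime_image` — "fast FLIM": per-pixel mean TCSPC delay
  minus an offset, in seconds;
* :func:`segment_pixels` / :func:`class_decay` — pixel classes by
  threshold or quantile bands and their pooled fluorescence decays for
  sub-ensemble analysis;
* :func:`phasor_transform` / :func:`phasor_image` — the model-free
  phasor representation ``g = <cos(w t)>, s = <sin(w t)>`` at the
  repetition (or a higher harmonic) frequency.  Single-exponential
  decays lie on the universal semicircle at
  ``(1/(1+(w tau)^2), w tau/(1+(w tau)^2))``; a measured reference of
  known lifetime calibrates away the instrument response as a
  rotation/scale in the phasor plane.  Phasors are photon-wise sums
  (no histogram binning), so pooling photon sets is exactly linear;
* :func:`ics_autocorrelation` — image correlation spectroscopy: the
  normalized spatial autocorrelation of the intensity fluctuations,
  computed with the periodic (circular) FFT convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EventStream, EventType
from .errors import DegenerateInputError, ParameterError

__all__ = [
    "CLSMImageStack",
    "PhasorImage",
    "DecayHistogram",
    "build_image_stack",
    "intensity_image",
    "mean_microtime_image",
    "segment_pixels",
    "class_decay",
    "phasor_reference_point",
    "phasor_transform",
    "phasor_image",
    "ics_autocorrelation",
]


@dataclass
class CLSMImageStack:
    """Photon-index hierarchy of a reconstructed scan.

    ``assignment`` holds, per selected photon, its (frame, line, pixel)
    or -1 where the photon fell outside every line.
    """

    stream: EventStream
    n_frames: int
    n_lines: int
    n_pixels: int
    photon_indices: np.ndarray       # event indices of the selected photons
    assignment: np.ndarray           # (n_selected, 3) int32; -1 = discarded
    line_spans: np.ndarray           # (n_frames, n_lines, 2) macro ticks
    n_discarded: int
    marker_config: tuple

    def pixel_photons(self, frame: int, line: int, pixel: int) -> np.ndarray:
        """Event indices of the photons in one pixel."""
        m = (
            (self.assignment[:, 0] == frame)
            & (self.assignment[:, 1] == line)
            & (self.assignment[:, 2] == pixel)
        )
        return self.photon_indices[m]

    def counts(self) -> np.ndarray:
        """Photon counts per (frame, line, pixel)."""
        ok = self.assignment[:, 0] >= 0
        flat = (
            self.assignment[ok, 0] * self.n_lines * self.n_pixels
            + self.assignment[ok, 1] * self.n_pixels
            + self.assignment[ok, 2]
        )
        c = np.bincount(flat, minlength=self.n_frames * self.n_lines * self.n_pixels)
        return c.reshape(self.n_frames, self.n_lines, self.n_pixels)


@dataclass
class PhasorImage:
    """Per-pixel phasor coordinates at one harmonic."""

    g: np.ndarray
    s: np.ndarray
    harmonic: int
    omega: float                      # rad/s
    calibration: tuple = (0.0, 1.0)   # (phase offset, modulation factor)
    n_photons: np.ndarray | None = None


@dataclass
class DecayHistogram:
    """Pooled micro-time histogram of a photon sub-ensemble."""

    bin_edges: np.ndarray     # micro-time channels, length n_bins + 1
    counts: np.ndarray
    n_photons: int
    channels: tuple
    provenance: str = ""


def build_image_stack(
    stream: EventStream,
    marker_config: tuple,
    n_pixels: int,
    channels=None,
) -> CLSMImageStack:
    """Sort a marker-bearing photon stream into frames, lines and pixels.

    ``marker_config = (frame_id, line_start_id, line_stop_id)``.  The
    pixel of a photon at macro tick u inside a line spanning [u0, u1] is
    ``floor(n_pixels * (u - u0) / (u1 - u0))``, clamped to the last
    pixel at the exact stop tick (integer arithmetic throughout).  Lines
    seen before the first frame marker belong to frame 0.  Photons
    outside every line are counted in ``n_discarded``.
    """
    frame_id, start_id, stop_id = marker_config
    if n_pixels < 1:
        raise ParameterError("n_pixels must be >= 1")
    markers = stream.marker_mask
    mk_idx = np.flatnonzero(markers)
    mk_ch = stream.routing_channels[mk_idx]
    mk_t = stream.macro_times[mk_idx].astype(np.int64)

    is_start = mk_ch == start_id
    is_stop = mk_ch == stop_id
    is_frame = mk_ch == frame_id
    if not np.any(is_start) or not np.any(is_stop):
        raise ParameterError("stream contains no line start/stop markers")

    # walk markers in order, building (frame, line) spans
    spans = []          # (frame, u0, u1)
    frame = 0
    lines_in_frame = 0
    open_start = None
    for ch, t in zip(mk_ch, mk_t):
        if ch == frame_id:
            if lines_in_frame > 0:
                frame += 1
                lines_in_frame = 0
        elif ch == start_id:
            if open_start is not None:
                raise ParameterError(
                    f"line start marker at tick {t} before previous line closed"
                )
            open_start = t
        elif ch == stop_id:
            if open_start is None:
                raise ParameterError(f"line stop marker at tick {t} without a start")
            spans.append((frame, open_start, t))
            open_start = None
            lines_in_frame += 1
    if open_start is not None:
        raise ParameterError("unmatched line start marker at end of stream")

    n_frames = spans[-1][0] + 1 if spans else 0
    lines_per_frame = np.bincount([f for f, _, _ in spans], minlength=n_frames)
    n_lines = int(lines_per_frame.max()) if n_frames else 0
    line_spans = np.zeros((n_frames, n_lines, 2), dtype=np.int64)
    counter = [0] * n_frames
    span_rows = []
    for f, u0, u1 in spans:
        ln = counter[f]
        counter[f] += 1
        line_spans[f, ln] = (u0, u1)
        span_rows.append((f, ln, u0, u1))

    ph_mask = stream.photon_mask.copy()
    if channels is not None:
        ph_mask &= np.isin(
            stream.routing_channels, np.asarray(sorted(channels), dtype=np.uint16)
        )
    ph_idx = np.flatnonzero(ph_mask)
    ph_t = stream.macro_times[ph_idx].astype(np.int64)

    assignment = np.full((len(ph_idx), 3), -1, dtype=np.int64)
    starts = np.array([r[2] for r in span_rows], dtype=np.int64)
    stops = np.array([r[3] for r in span_rows], dtype=np.int64)
    # photons are time sorted and lines do not overlap: locate each
    # photon's candidate line with one sorted search
    which = np.searchsorted(starts, ph_t, side="right") - 1
    ok = which >= 0
    ok[ok] &= ph_t[ok] <= stops[which[ok]]
    rows = np.asarray(span_rows, dtype=np.int64).reshape(-1, 4)
    w = which[ok]
    u0, u1 = rows[w, 2], rows[w, 3]
    span = np.maximum(u1 - u0, 1)
    px = np.minimum((n_pixels * (ph_t[ok] - u0)) // span, n_pixels - 1)
    assignment[ok, 0] = rows[w, 0]
    assignment[ok, 1] = rows[w, 1]
    assignment[ok, 2] = px
    n_discarded = int(len(ph_idx) - ok.sum())
    return CLSMImageStack(
        stream=stream,
        n_frames=n_frames,
        n_lines=n_lines,
        n_pixels=n_pixels,
        photon_indices=ph_idx,
        assignment=assignment,
        line_spans=line_spans,
        n_discarded=n_discarded,
        marker_config=marker_config,
    )


def intensity_image(stack: CLSMImageStack, frames=None) -> np.ndarray:
    """Photon counts per (line, pixel), summed over the frame range."""
    counts = stack.counts()
    if frames is None:
        return counts.sum(axis=0)
    frames = list(frames)
    if not frames:
        return np.zeros((stack.n_lines, stack.n_pixels), dtype=np.int64)
    return counts[frames].sum(axis=0)


def _per_pixel_micro(stack: CLSMImageStack):
    ok = stack.assignment[:, 0] >= 0
    flat = (
        stack.assignment[ok, 0] * stack.n_lines * stack.n_pixels
        + stack.assignment[ok, 1] * stack.n_pixels
        + stack.assignment[ok, 2]
    )
    micro = stack.stream.micro_times[stack.photon_indices[ok]].astype(float)
    return flat, micro


def mean_microtime_image(
    stack: CLSMImageStack,
    t0: float = 0.0,
    min_photons: int = 1,
    per_frame: bool = False,
) -> np.ndarray:
    """Fast-FLIM image: per-pixel mean micro time minus ``t0``, seconds.

    ``t0`` is an offset in micro-time channels (e.g. the IRF centroid);
    pixels with fewer than ``min_photons`` photons are NaN.
    """
    n_px = stack.n_frames * stack.n_lines * stack.n_pixels
    flat, micro = _per_pixel_micro(stack)
    count = np.bincount(flat, minlength=n_px).astype(float)
    total = np.bincount(flat, weights=micro, minlength=n_px)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count >= max(min_photons, 1), total / count, np.nan)
    mean = (mean - t0) * stack.stream.header.micro_time_resolution
    img = mean.reshape(stack.n_frames, stack.n_lines, stack.n_pixels)
    if per_frame:
        return img
    # frame-summed fast FLIM: recompute on pooled counts
    count_f = count.reshape(stack.n_frames, -1).sum(axis=0)
    total_f = total.reshape(stack.n_frames, -1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count_f >= max(min_photons, 1), total_f / count_f, np.nan)
    mean = (mean - t0) * stack.stream.header.micro_time_resolution
    return mean.reshape(stack.n_lines, stack.n_pixels)


def segment_pixels(
    image: np.ndarray,
    thresholds=None,
    quantiles=None,
) -> np.ndarray:
    """Deterministic pixel classes from threshold or quantile bands.

    ``thresholds=[t1, t2, ...]`` labels pixels 0 (< t1), 1 ([t1, t2)),
    ...; ``quantiles=[q1, ...]`` converts quantiles of the finite pixel
    values into thresholds first.  NaN pixels get label -1.
    """
    image = np.asarray(image, dtype=float)
    if (thresholds is None) == (quantiles is None):
        raise ParameterError("give exactly one of thresholds or quantiles")
    finite = np.isfinite(image)
    if quantiles is not None:
        if len(quantiles) == 0:
            raise ParameterError("empty quantile band spec")
        thresholds = np.quantile(image[finite], quantiles)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ParameterError("empty threshold band spec")
    labels = np.full(image.shape, -1, dtype=np.int64)
    labels[finite] = np.searchsorted(thresholds, image[finite], side="right")
    return labels


def class_decay(
    stack: CLSMImageStack,
    labels: np.ndarray,
    class_id: int,
    n_bins: int | None = None,
    frames=None,
) -> DecayHistogram:
    """Pooled micro-time histogram of all photons in one pixel class."""
    labels = np.asarray(labels)
    if labels.shape != (stack.n_lines, stack.n_pixels):
        raise ParameterError("label image does not match stack geometry")
    if not np.any(labels == class_id):
        raise ParameterError(f"no pixels carry class id {class_id}")
    n_ch = stack.stream.header.n_microtime_channels
    if n_bins is None:
        n_bins = n_ch
    ok = stack.assignment[:, 0] >= 0
    if frames is not None:
        ok &= np.isin(stack.assignment[:, 0], list(frames))
    lab = labels[stack.assignment[ok, 1], stack.assignment[ok, 2]]
    micro = stack.stream.micro_times[stack.photon_indices[ok]][lab == class_id]
    edges = np.linspace(0, n_ch, n_bins + 1)
    counts, _ = np.histogram(micro, bins=edges)
    return DecayHistogram(
        bin_edges=edges,
        counts=counts,
        n_photons=int(len(micro)),
        channels=tuple(),
        provenance=f"class_decay(class_id={class_id})",
    )


# ---------------------------------------------------------------------------
# phasor analysis
# ---------------------------------------------------------------------------


def phasor_reference_point(omega: float, tau: float) -> tuple:
    """Analytic phasor of a single-exponential decay of lifetime tau."""
    d = 1.0 + (omega * tau) ** 2
    return 1.0 / d, omega * tau / d


def phasor_transform(
    micro_seconds: np.ndarray,
    rep_period: float,
    harmonic: int = 1,
    reference: tuple | None = None,
) -> tuple:
    """Photon-wise phasor ``(g, s)`` at harmonic ``n`` of the laser rate.

    ``reference = (reference_micro_seconds, tau_ref)`` calibrates the
    result: the measured reference phasor is rotated/scaled onto the
    analytic point of a ``tau_ref`` single exponential, and the same
    complex factor is applied to the sample.
    """
    micro_seconds = np.asarray(micro_seconds, dtype=float)
    if micro_seconds.size == 0:
        raise DegenerateInputError("phasor of zero photons is undefined")
    if rep_period <= 0 or harmonic < 1:
        raise ParameterError("rep_period must be > 0 and harmonic >= 1")
    omega = 2.0 * np.pi * harmonic / rep_period
    z = complex(np.mean(np.cos(omega * micro_seconds)), np.mean(np.sin(omega * micro_seconds)))
    if reference is not None:
        ref_micro, tau_ref = reference
        ref_micro = np.asarray(ref_micro, dtype=float)
        if ref_micro.size == 0:
            raise DegenerateInputError("empty phasor reference")
        zr = complex(
            np.mean(np.cos(omega * ref_micro)), np.mean(np.sin(omega * ref_micro))
        )
        g0, s0 = phasor_reference_point(omega, tau_ref)
        z = z * complex(g0, s0) / zr
    return z.real, z.imag


def phasor_image(
    stack: CLSMImageStack,
    rep_period: float | None = None,
    harmonic: int = 1,
    reference: tuple | None = None,
    min_photons: int = 1,
) -> PhasorImage:
    """Per-pixel phasor image (frames pooled); NaN below ``min_photons``."""
    header = stack.stream.header
    if rep_period is None:
        rep_period = header.micro_time_span
    omega = 2.0 * np.pi * harmonic / rep_period
    flat, micro = _per_pixel_micro(stack)
    micro_s = micro * header.micro_time_resolution
    n_px = stack.n_frames * stack.n_lines * stack.n_pixels
    count = np.bincount(flat, minlength=n_px).astype(float)
    cg = np.bincount(flat, weights=np.cos(omega * micro_s), minlength=n_px)
    cs = np.bincount(flat, weights=np.sin(omega * micro_s), minlength=n_px)
    count = count.reshape(stack.n_frames, -1).sum(axis=0)
    cg = cg.reshape(stack.n_frames, -1).sum(axis=0)
    cs = cs.reshape(stack.n_frames, -1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(count >= max(min_photons, 1), cg / count, np.nan)
        s = np.where(count >= max(min_photons, 1), cs / count, np.nan)
    cal = (0.0, 1.0)
    if reference is not None:
        ref_micro, tau_ref = reference
        ref_micro = np.asarray(ref_micro, dtype=float)
        zr = complex(np.mean(np.cos(omega * ref_micro)), np.mean(np.sin(omega * ref_micro)))
        g0, s0 = phasor_reference_point(omega, tau_ref)
        factor = complex(g0, s0) / zr
        z = (g + 1j * s) * factor
        g, s = z.real, z.imag
        cal = (float(np.angle(factor)), float(abs(factor)))
    shape = (stack.n_lines, stack.n_pixels)
    return PhasorImage(
        g=g.reshape(shape),
        s=s.reshape(shape),
        harmonic=harmonic,
        omega=omega,
        calibration=cal,
        n_photons=count.reshape(shape),
    )


# ---------------------------------------------------------------------------
# image correlation spectroscopy
# ---------------------------------------------------------------------------


def ics_autocorrelation(image: np.ndarray) -> np.ndarray:
    """Normalized spatial autocorrelation map (periodic convention).

    ``G(xi, eta) = <dI(x, y) dI(x+xi, y+eta)> / <I>^2`` with circular
    shifts, evaluated by FFT.  ``G[0, 0]`` equals ``var(I)/mean(I)^2``
    (population variance) exactly.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 2:
        raise ParameterError("image must be at least 2x2")
    mean = image.mean()
    if mean <= 0:
        raise DegenerateInputError("image mean must be positive")
    delta = image - mean
    f = np.fft.fft2(delta)
    corr = np.fft.ifft2(f * np.conj(f)).real / image.size
    corr[0, 0] = np.mean(delta**2)  # same quantity, free of FFT roundoff
    return corr / mean**2
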