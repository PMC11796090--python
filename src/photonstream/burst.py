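"""Single-molecule FRET burst pipeline.

A *burst* is the contiguous run of photons emitted while one molecule
transits the confocal volume.  Bursts are found by intensity
thresholding: a photon is a candidate when at least ``n_min`` photons
fall in a centred time window around it (the same primitive as
:func:`photonstream.core.select_time_window`), and maximal runs of
consecutive candidates with at least ``L_min`` photons become bursts.

Per burst the module computes:

* the proximity ratio ``E_raw = S_R / (S_G + S_R)`` and the corrected
  FRET efficiency ``E_corr = F_R / (F_R + gamma * F_G)`` after
  background (``b_G``, ``b_R``), spectral crosstalk (``alpha``) and
  detection-efficiency ratio (``gamma``) corrections;
* a fluorescence lifetime from the mean micro time, inverting the mean
  of an exponential decay truncated to the observation window ``T``:
  ``mean - t0 = tau - T / (exp(T / tau) - 1)``.  This estimator is
  robust at the tens-of-photons level typical of bursts;
* burst variance analysis (BVA): the standard deviation of the proximity
  ratio over consecutive photon windows, compared with the binomial
  shot-noise expectation ``sqrt(PR (1 - PR) / n_window)`` — excess
  variance flags dynamics within the burst.

Photon distribution analysis (PDA) lives here too: an exact forward
model for the shot-noise-limited joint histogram of green/red counts
per burst (or time bin), mixing species of fixed efficiency with
Poisson backgrounds, plus a Pearson goodness-of-fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import EventStream, select_channels, select_time_window
from .errors import DegenerateInputError, ParameterError

__all__ = [
    "Burst",
    "PdaModel",
    "PdaTable",
    "burst_search",
    "burst_indicators",
    "burst_lifetime",
    "lifetime_from_microtimes",
    "bva",
    "pda_forward",
    "pda_chi2",
    "burst_dataframe",
    "burst_histogram",
    "select_bursts",
]


@dataclass
class Burst:
    """One single-molecule event: an index range plus derived indicators."""

    start: int                 # first event index (inclusive)
    stop: int                  # past-the-end event index
    t_start: float = 0.0       # seconds
    duration: float = 0.0      # seconds
    s_g: int = 0               # raw green (donor) photon count
    s_r: int = 0               # raw red (acceptor) photon count
    e_raw: float = np.nan      # proximity ratio
    e_corr: float = np.nan     # corrected FRET efficiency
    f_g: float = np.nan        # background/crosstalk-corrected green signal
    f_r: float = np.nan
    tau_hat: float | None = None   # burst lifetime estimate, seconds
    bva_mean: float = np.nan
    bva_sd: float = np.nan
    bva_shot: float = np.nan
    flags: set = field(default_factory=set)

    @property
    def n_photons(self) -> int:
        return self.s_g + self.s_r


def burst_search(
    stream: EventStream,
    channels,
    window: float,
    n_min: int,
    L_min: int,
) -> list[Burst]:
    """All-photon sliding-window burst search.

    Candidates are photons on ``channels`` with at least ``n_min``
    photons of those channels within ``+-window/2``; maximal runs of
    consecutive candidate photons with ``>= L_min`` members become
    bursts.  Returns bursts ordered in time.
    """
    if L_min < 1:
        raise ParameterError("L_min must be >= 1")
    sel = select_channels(stream, channels)
    if len(sel) == 0:
        return []
    sub = stream.take(sel.indices)
    cand_local = select_time_window(sub, window, n_min).indices
    if cand_local.size == 0:
        return []
    # maximal runs of photons that are *consecutive in the channel
    # selection* (no non-candidate selected photon in between)
    breaks = np.flatnonzero(np.diff(cand_local) > 1)
    run_starts = np.concatenate([[0], breaks + 1])
    run_stops = np.concatenate([breaks + 1, [len(cand_local)]])
    res = stream.header.macro_time_resolution
    bursts = []
    for a, b in zip(run_starts, run_stops):
        if b - a < L_min:
            continue
        first = int(sel.indices[cand_local[a]])
        last = int(sel.indices[cand_local[b - 1]])
        t0 = float(stream.macro_times[first]) * res
        t1 = float(stream.macro_times[last]) * res
        bursts.append(Burst(start=first, stop=last + 1, t_start=t0, duration=t1 - t0))
    return bursts


def _group_channels(stream, burst, green_channels, red_channels):
    ch = stream.routing_channels[burst.start : burst.stop]
    ph = stream.event_types[burst.start : burst.stop] == 0
    is_g = ph & np.isin(ch, np.asarray(sorted(green_channels), dtype=ch.dtype))
    is_r = ph & np.isin(ch, np.asarray(sorted(red_channels), dtype=ch.dtype))
    return is_g, is_r


def burst_indicators(
    burst: Burst,
    stream: EventStream,
    green_channels,
    red_channels,
    b_g: float = 0.0,
    b_r: float = 0.0,
    alpha: float = 0.0,
    gamma: float = 1.0,
) -> Burst:
    """Fill in counts, proximity ratio and corrected FRET efficiency.

    Corrections: ``F_G = S_G - b_G * duration``,
    ``F_R = S_R - b_R * duration - alpha * F_G``; negative corrected
    counts are floored at 0 (flag ``neg_signal``); ``E_corr`` is clamped
    to [-0.1, 1.1] (flag ``clamped``) rather than discarded, so analysts
    can filter on the flags downstream.
    """
    is_g, is_r = _group_channels(stream, burst, green_channels, red_channels)
    burst.s_g = int(is_g.sum())
    burst.s_r = int(is_r.sum())
    total = burst.s_g + burst.s_r
    if total == 0:
        raise DegenerateInputError("burst has no photons in the channel groups")
    burst.e_raw = burst.s_r / total
    f_g = burst.s_g - b_g * burst.duration
    f_r = burst.s_r - b_r * burst.duration - alpha * f_g
    if f_g < 0 or f_r < 0:
        burst.flags.add("neg_signal")
        f_g, f_r = max(f_g, 0.0), max(f_r, 0.0)
    burst.f_g, burst.f_r = f_g, f_r
    denom = f_r + gamma * f_g
    if denom <= 0:
        burst.flags.add("no_signal")
        burst.e_corr = np.nan
        return burst
    e = f_r / denom
    if e < -0.1 or e > 1.1:
        burst.flags.add("clamped")
        e = min(max(e, -0.1), 1.1)
    burst.e_corr = e
    return burst


def lifetime_from_microtimes(
    micro_seconds: np.ndarray,
    T: float,
    t0: float = 0.0,
    rtol: float = 1e-9,
) -> float | None:
    """Mean-arrival lifetime of an exponential decay truncated to [t0, t0+T].

    Solves ``mean - t0 = tau - T / (exp(T/tau) - 1)`` for tau; the right
    side rises monotonically from 0 (tau -> 0) to T/2 (tau -> inf), so a
    sample mean outside ``(t0, t0 + T/2)`` has no solution and ``None``
    is returned.  In the ``T >> tau`` limit the equation reduces to
    ``tau = mean - t0``.
    """
    m = float(np.mean(micro_seconds)) - t0
    # at m -> T/2 the implied tau diverges; treat the boundary (within
    # float roundoff) as unsolvable rather than returning garbage
    if not (0.0 < m < (T / 2) * (1.0 - 1e-12)):
        return None

    def f(tau):
        x = T / tau
        if x > 700:
            return tau - m
        return tau - T / np.expm1(x) - m

    lo, hi = m * (1 - 1e-12), T * 1e6
    try:
        return float(optimize.brentq(f, lo, hi, rtol=rtol))
    except ValueError:
        return None


def burst_lifetime(
    burst: Burst,
    stream: EventStream,
    channels,
    T: float,
    t0: float = 0.0,
) -> Burst:
    """Attach the truncated-exponential lifetime estimate for one channel group."""
    ph = stream.event_types[burst.start : burst.stop] == 0
    ch = stream.routing_channels[burst.start : burst.stop]
    mask = ph & np.isin(ch, np.asarray(sorted(channels), dtype=ch.dtype))
    micro = stream.micro_times[burst.start : burst.stop][mask]
    if len(micro) < 10:
        burst.flags.add("low_count")
    if len(micro) == 0:
        burst.tau_hat = None
        return burst
    tau = lifetime_from_microtimes(
        micro.astype(float) * stream.header.micro_time_resolution, T, t0
    )
    if tau is None:
        burst.flags.add("no_solution")
    burst.tau_hat = tau
    return burst


def bva(
    burst: Burst,
    stream: EventStream,
    green_channels,
    red_channels,
    n_window: int = 5,
) -> Burst:
    """Burst variance analysis over consecutive photon windows.

    Splits the burst's (green+red) photons into consecutive
    non-overlapping windows of exactly ``n_window`` photons (the
    remainder is dropped) and records the mean and standard deviation of
    the per-window proximity ratio next to the binomial shot-noise
    expectation.
    """
    if n_window < 2:
        raise ParameterError("n_window must be >= 2")
    is_g, is_r = _group_channels(stream, burst, green_channels, red_channels)
    red_seq = np.where(is_r[is_g | is_r], 1.0, 0.0)
    n_windows = len(red_seq) // n_window
    if n_windows < 2:
        burst.flags.add("bva_insufficient")
        return burst
    pr = red_seq[: n_windows * n_window].reshape(n_windows, n_window).mean(axis=1)
    burst.bva_mean = float(pr.mean())
    burst.bva_sd = float(pr.std(ddof=1))
    burst.bva_shot = float(np.sqrt(burst.bva_mean * (1 - burst.bva_mean) / n_window))
    return burst


# ---------------------------------------------------------------------------
# photon distribution analysis
# ---------------------------------------------------------------------------


@dataclass
class PdaModel:
    """Mixture model behind a green/red photon-count histogram.

    ``species`` is a list of ``(amplitude, efficiency)`` pairs with
    amplitudes summing to 1.  ``p_f`` is the fluorescence-count
    distribution P(F) over F = 0..F_max (shot-noise broadening beyond
    Poisson enters through it).  ``epsilon_k``, the probability that a
    fluorescence photon of species k is detected in the red group,
    folds in crosstalk ``alpha`` and detection ratio ``gamma``.
    """

    species: list                 # [(x_k, E_k), ...]
    p_f: np.ndarray               # P(F), F = 0..F_max
    bg_green: float = 0.0         # Hz
    bg_red: float = 0.0           # Hz
    bin_duration: float = 1e-3    # seconds
    alpha: float = 0.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        self.p_f = np.asarray(self.p_f, dtype=float)
        x = np.array([x for x, _ in self.species], dtype=float)
        if np.any(x < 0) or abs(x.sum() - 1.0) > 1e-9:
            raise ParameterError("species amplitudes must be >= 0 and sum to 1")
        if np.any([not 0 <= e <= 1 for _, e in self.species]):
            raise ParameterError("efficiencies must lie in [0, 1]")
        if abs(self.p_f.sum() - 1.0) > 1e-9 or np.any(self.p_f < 0):
            raise ParameterError("P(F) must be a probability distribution")

    def epsilon(self, E: float) -> float:
        if E >= 1.0:
            return 1.0
        r = self.alpha + self.gamma * E / (1.0 - E)
        return r / (1.0 + r)


@dataclass
class PdaTable:
    """Truncated joint probability table P(S_G, S_R), S_G + S_R <= S_max."""

    P: np.ndarray             # (S_max+1, S_max+1), zero outside the triangle
    S_max: int
    truncation_mass: float    # probability outside the triangle before renorm
    model: PdaModel


def pda_forward(model: PdaModel, S_max: int | None = None) -> PdaTable:
    """Exact forward PDA histogram.

    For each species the fluorescence photons F ~ P(F) split binomially
    into red (prob. epsilon_k) and green; independent Poisson
    backgrounds add to each channel; species are mixed by amplitude.
    When ``S_max`` is omitted it is grown until the truncated mass falls
    below 1e-6; an explicit ``S_max`` that leaves more mass outside the
    triangle raises a ParameterError.
    """
    explicit = S_max is not None
    f_max = len(model.p_f) - 1
    mu_g = model.bg_green * model.bin_duration
    mu_r = model.bg_red * model.bin_duration
    if S_max is None:
        S_max = int(f_max + np.ceil(mu_g + mu_r + 10 * np.sqrt(mu_g + mu_r + 1)) + 10)
    while True:
        P = _pda_table(model, S_max, mu_g, mu_r)
        trunc = float(max(0.0, 1.0 - P.sum()))
        if trunc <= 1e-6:
            break
        if explicit:
            raise ParameterError(
                f"S_max={S_max} leaves truncation mass {trunc:.3g} > 1e-6"
            )
        S_max *= 2
    P = P / P.sum()
    return PdaTable(P=P, S_max=S_max, truncation_mass=trunc, model=model)


def _pda_table(model: PdaModel, S_max: int, mu_g: float, mu_r: float) -> np.ndarray:
    n = S_max + 1
    f_max = len(model.p_f) - 1
    F = np.arange(f_max + 1)
    k = np.arange(n)
    pois_g = stats.poisson.pmf(k, mu_g) if mu_g > 0 else (k == 0).astype(float)
    pois_r = stats.poisson.pmf(k, mu_r) if mu_r > 0 else (k == 0).astype(float)
    out = np.zeros((n, n))
    for x_k, E_k in model.species:
        eps = model.epsilon(E_k)
        # fluorescence-only table over (G, R)
        fl = np.zeros((n, n))
        for f, pf in zip(F, model.p_f):
            if pf == 0 or f > 2 * S_max:
                continue
            r = np.arange(0, min(f, S_max) + 1)
            pr = stats.binom.pmf(r, f, eps)
            g = f - r
            ok = g <= S_max
            fl[g[ok], r[ok]] += pf * pr[ok]
        # add independent Poisson background on each axis (2-D convolution
        # separable: along G with pois_g, along R with pois_r), truncated
        tbl = np.apply_along_axis(lambda col: np.convolve(col, pois_g)[:n], 0, fl)
        tbl = np.apply_along_axis(lambda row: np.convolve(row, pois_r)[:n], 1, tbl)
        out += x_k * tbl
    # zero outside the triangular domain S_G + S_R <= S_max
    sg, sr = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    out[sg + sr > S_max] = 0.0
    return out


def pda_chi2(table: PdaTable, observed: np.ndarray, n_free_params: int = 0) -> float:
    """Reduced Pearson chi-square of an observed 2-D count histogram.

    Cells with model-expected count >= 5 enter individually; all others
    are pooled into one cell.  Degrees of freedom:
    ``n_cells - 1 - n_free_params``.
    """
    observed = np.asarray(observed, dtype=float)
    if observed.shape != table.P.shape:
        raise ParameterError("observed histogram shape must match the model table")
    n_total = observed.sum()
    expected = table.P * n_total
    big = expected >= 5
    cells_o = [observed[big]]
    cells_e = [expected[big]]
    pooled_e = expected[~big].sum()
    if pooled_e > 0:
        cells_o.append([observed[~big].sum()])
        cells_e.append([pooled_e])
    o = np.concatenate(cells_o)
    e = np.concatenate(cells_e)
    n_cells = len(e)
    dof = n_cells - 1 - n_free_params
    if n_cells < n_free_params + 2 or dof < 1:
        raise ParameterError(
            f"{n_cells} usable cells cannot constrain {n_free_params} parameters"
        )
    chi2 = float(np.sum((o - e) ** 2 / e))
    return chi2 / dof


# ---------------------------------------------------------------------------
# burst tables, histograms and sub-ensemble gates
# ---------------------------------------------------------------------------

_COLUMNS = [
    "start_idx", "stop_idx", "t_start_s", "duration_s", "S_G", "S_R",
    "E_raw", "E_corr", "tau_hat_s", "bva_mean", "bva_sd", "bva_shot", "flags",
]


def burst_dataframe(bursts: list) -> pd.DataFrame:
    """Burst table with one row per burst and documented columns."""
    rows = [
        (
            b.start, b.stop, b.t_start, b.duration, b.s_g, b.s_r,
            b.e_raw, b.e_corr,
            np.nan if b.tau_hat is None else b.tau_hat,
            b.bva_mean, b.bva_sd, b.bva_shot,
            ";".join(sorted(b.flags)),
        )
        for b in bursts
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


_INDICATOR = {
    "E_raw": lambda b: b.e_raw,
    "E_corr": lambda b: b.e_corr,
    "tau_hat": lambda b: np.nan if b.tau_hat is None else b.tau_hat,
    "S": lambda b: b.n_photons,
    "duration": lambda b: b.duration,
    "bva_sd": lambda b: b.bva_sd,
    "bva_mean": lambda b: b.bva_mean,
}


def _values(bursts, axis):
    return np.array([_INDICATOR[axis](b) for b in bursts], dtype=float)


def burst_histogram(bursts, x: str, bins=20, y: str | None = None, range=None):
    """1-D or 2-D indicator histogram; total counts equal len(bursts)
    when no burst carries NaN on the requested axes."""
    xv = _values(bursts, x)
    if y is None:
        return np.histogram(xv, bins=bins, range=range)
    yv = _values(bursts, y)
    return np.histogram2d(xv, yv, bins=bins, range=range)


def select_bursts(bursts, **ranges) -> list:
    """Axis-aligned rectangular sub-ensemble gate.

    ``select_bursts(bursts, E_raw=(0.4, 0.6), S=(30, None))`` keeps
    bursts whose indicators fall inside every closed interval (``None``
    bounds are open-ended).
    """
    out = []
    for b in bursts:
        keep = True
        for axis, (lo, hi) in ranges.items():
            v = _INDICATOR[axis](b)
            if np.isnan(v):
                keep = False
                break
            if lo is not None and v < lo:
                keep = False
                break
            if hi is not None and v > hi:
                keep = False
                break
        if keep:
            out.append(b)
    return out
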