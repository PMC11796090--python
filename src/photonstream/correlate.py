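"""Photon-stream correlation: reference, multi-tau, gated and filtered FCS.

The normalized intensity correlation of two photon streams A and B is

    G(tau) = <I_A(t) I_B(t + tau)> / (<I_A> <I_B>)

estimated directly from photon arrival times: the (weighted) number of
photon pairs whose lag falls in a bin, divided by the count expected for
two independent stationary Poisson streams of the same total weight over
the same span.  With that normalization independent inputs give
``E[G] = 1`` at every lag, which is the convention used throughout.

Two estimators are provided:

* :func:`correlate_pairs` — exact pair counting on an arbitrary lag
  grid; O(n_A · n_B) semantics (evaluated with sorted-search speedups,
  but bitwise equal to the definition).  This is the reference.
* :func:`multi_tau` — the production multiple-tau scheme: a
  quasi-logarithmic lag grid where after each cascade photon times are
  coarsened by a factor two and coincident weights summed.  Its finest
  cascade is exactly :func:`correlate_pairs` on the same edges.

Sign convention: positive lag means B after A.  Lag-zero self-pairs are
excluded from autocorrelations (the shot-noise self-term is not part of
G).  Normalization uses the lag-dependent span ``T - tau`` so long lags
are not biased by the finite record.

Filtered FCS weights photons by micro-time-derived species filters; the
least-squares construction in :func:`compute_fcs_filters` yields weights
that are unbiased in expectation: ``sum_i f_k[i] p_j[i] = delta_kj``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import EventStream, microtime_gate, select_channels
from .errors import ConditioningError, DegenerateInputError, ParameterError

__all__ = [
    "CorrelationCurve",
    "FcsFilterSet",
    "correlate_pairs",
    "multi_tau",
    "gated_correlate",
    "compute_fcs_filters",
]


@dataclass
class CorrelationCurve:
    """Correlation amplitudes on a (quasi-logarithmic) lag grid."""

    lags: np.ndarray          # bin centres, seconds, strictly increasing
    G: np.ndarray             # normalized amplitudes
    pair_counts: np.ndarray   # raw (weighted) pair counts per bin
    T: float                  # observation span, seconds
    lag_edges: np.ndarray | None = None
    rate_sum: float = 0.0     # (W_A + W_B) / T, for the pair-count error
    meta: dict = field(default_factory=dict)

    @property
    def se(self) -> np.ndarray:
        """Standard error of G per bin from the pair counts.

        For a lag bin of width dtau holding K pairs the Poisson error
        G/sqrt(K) is inflated by the pair multiplicity 1 + (a+b) dtau
        (a, b the stream count rates): when dtau exceeds the mean
        inter-photon time, pairs share photons and their counts are no
        longer independent.  Bins without pairs report inf.
        """
        width = (
            np.diff(self.lag_edges)
            if self.lag_edges is not None
            else np.gradient(self.lags)
        )
        mult = 1.0 + self.rate_sum * width
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(
                self.pair_counts > 0,
                self.G * np.sqrt(mult / self.pair_counts),
                np.inf,
            )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag_s": self.lags, "G": self.G, "pair_count": self.pair_counts, "SE": self.se}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _pair_counts(times_a, times_b, weights_a, weights_b, edges, chunk=4096):
    """Weighted pair counts with lag t_b - t_a in [edges[k], edges[k+1])."""
    counts = np.zeros(len(edges) - 1, dtype=float)
    cw = np.concatenate([[0.0], np.cumsum(weights_b)])
    for s in range(0, len(times_a), chunk):
        ta = times_a[s : s + chunk, None]
        wa = weights_a[s : s + chunk, None]
        lo = np.searchsorted(times_b, ta + edges[None, :-1], side="left")
        hi = np.searchsorted(times_b, ta + edges[None, 1:], side="left")
        counts += (wa * (cw[hi] - cw[lo])).sum(axis=0)
    return counts


def _normalize(pair_counts, edges, T, w_total_a, w_total_b):
    width = np.diff(edges)
    mid = 0.5 * (edges[:-1] + edges[1:])
    span = T - mid
    expected = w_total_a * w_total_b * width * span / T**2
    with np.errstate(divide="ignore", invalid="ignore"):
        G = np.where((expected > 0) & (span > 0), pair_counts / expected, 0.0)
    return G, mid


def correlate_pairs(
    times_a: np.ndarray,
    times_b: np.ndarray,
    lag_edges: np.ndarray,
    weights_a: np.ndarray | None = None,
    weights_b: np.ndarray | None = None,
    T: float | None = None,
    exclude_self: bool | None = None,
) -> CorrelationCurve:
    """Exact pair-count correlation on an explicit lag grid (reference).

    ``exclude_self`` removes i == j pairs from the lag-0 bin; it
    defaults to on when ``times_a`` and ``times_b`` are the same array
    (autocorrelation) and off otherwise.
    """
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    lag_edges = np.asarray(lag_edges, dtype=float)
    if np.any(np.diff(times_a) < 0) or np.any(np.diff(times_b) < 0):
        raise ParameterError("photon times must be sorted")
    if len(lag_edges) < 2 or np.any(np.diff(lag_edges) <= 0):
        raise ParameterError("lag_edges must be strictly increasing")
    auto = times_a is times_b or (
        len(times_a) == len(times_b) and np.shares_memory(times_a, times_b)
    )
    if exclude_self is None:
        exclude_self = auto
    wa = np.ones(len(times_a)) if weights_a is None else np.asarray(weights_a, dtype=float)
    wb = np.ones(len(times_b)) if weights_b is None else np.asarray(weights_b, dtype=float)
    counts = _pair_counts(times_a, times_b, wa, wb, lag_edges)
    if exclude_self:
        zero_bin = np.flatnonzero((lag_edges[:-1] <= 0) & (lag_edges[1:] > 0))
        if zero_bin.size and len(times_a) == len(times_b):
            counts[zero_bin[0]] -= float(np.sum(wa * wb))
    if T is None:
        lo = min(times_a[0], times_b[0]) if len(times_a) and len(times_b) else 0.0
        hi = max(times_a[-1], times_b[-1]) if len(times_a) and len(times_b) else 1.0
        T = max(hi - lo, np.finfo(float).tiny)
    G, mid = _normalize(counts, lag_edges, T, wa.sum(), wb.sum())
    return CorrelationCurve(mid, G, counts, T, lag_edges=lag_edges,
                            rate_sum=(wa.sum() + wb.sum()) / T,
                            meta={"estimator": "pairs", "exclude_self": bool(exclude_self)})


def multi_tau(
    times_a: np.ndarray,
    times_b: np.ndarray | None = None,
    weights_a: np.ndarray | None = None,
    weights_b: np.ndarray | None = None,
    delta0: float = 1.0,
    n_bins_per_cascade: int = 16,
    n_cascades: int | None = None,
    T: float | None = None,
) -> CorrelationCurve:
    """Multiple-tau correlation with progressive factor-2 time coarsening.

    Cascade 0 spans lags ``[0, B) * delta0`` at the base resolution; each
    later cascade covers ``[B/2, B)`` coarse ticks at doubled spacing,
    photon times floor-divided by two and coincident weights summed.
    ``n_cascades`` defaults to the count needed to reach ``T / 10``.
    ``times_b=None`` requests autocorrelation (lag-0 self-pairs removed).
    """
    B = n_bins_per_cascade
    if B < 2 or B % 2:
        raise ParameterError("n_bins_per_cascade must be even and >= 2")
    times_a = np.asarray(times_a, dtype=float)
    auto = times_b is None
    times_b = times_a if auto else np.asarray(times_b, dtype=float)
    if len(times_a) == 0 or len(times_b) == 0:
        raise DegenerateInputError("empty photon selection")
    wa = np.ones(len(times_a)) if weights_a is None else np.asarray(weights_a, dtype=float)
    wb = wa if (auto and weights_b is None) else (
        np.ones(len(times_b)) if weights_b is None else np.asarray(weights_b, dtype=float)
    )
    if T is None:
        T = max(max(times_a[-1], times_b[-1]) - min(times_a[0], times_b[0]),
                np.finfo(float).tiny)
    if n_cascades is None:
        n_cascades = 1
        while delta0 * (2 ** n_cascades) * B < T / 10 and n_cascades < 40:
            n_cascades += 1

    ua = np.floor(times_a / delta0).astype(np.int64)
    ub = ua if auto else np.floor(times_b / delta0).astype(np.int64)
    w_total_a, w_total_b = wa.sum(), wb.sum()

    all_counts, all_edges = [], []
    ca, va = _compress(ua, wa)
    cb, vb = (ca, va) if auto else _compress(ub, wb)
    for c in range(n_cascades):
        factor = 2 ** c
        lo_bin = 0 if c == 0 else B // 2
        int_edges = np.arange(lo_bin, B + 1, dtype=float)
        counts = _pair_counts(ca.astype(float), cb.astype(float), va, vb, int_edges)
        if c == 0 and auto:
            counts[0] -= float(np.sum(wa * wa))
        edges_s = int_edges * factor * delta0
        all_counts.append(counts)
        all_edges.append(edges_s)
        # coarsen for the next cascade
        ca, va = _compress(ca >> 1, va)
        cb, vb = (ca, va) if auto else _compress(cb >> 1, vb)

    edges = np.concatenate([e[:-1] for e in all_edges] + [all_edges[-1][-1:]])
    counts = np.concatenate(all_counts)
    G, mid = _normalize(counts, edges, T, w_total_a, w_total_b)
    return CorrelationCurve(
        mid, G, counts, T, lag_edges=edges,
        rate_sum=(w_total_a + w_total_b) / T,
        meta={"estimator": "multi-tau", "delta0": delta0, "B": B,
              "n_cascades": n_cascades, "auto": auto},
    )


def _compress(ticks: np.ndarray, weights: np.ndarray):
    """Sum weights of events sharing a tick; returns (unique ticks, weights)."""
    if len(ticks) == 0:
        return ticks, weights
    uniq, inv = np.unique(ticks, return_inverse=True)
    return uniq, np.bincount(inv, weights=weights)


def gated_correlate(
    stream: EventStream,
    channels_a,
    channels_b,
    gate_a: tuple | None = None,
    gate_b: tuple | None = None,
    weights: np.ndarray | None = None,
    **multi_tau_kwargs,
) -> CorrelationCurve:
    """Micro-time-gated (or per-photon-weighted) multi-tau correlation.

    Composes a channel selection with an optional micro-time gate per
    arm and hands the selected arrival times to :func:`multi_tau`.  With
    ``weights`` (one per event in the stream) this computes filtered
    FCS; identical full-range gates reduce to the plain correlation.
    """
    def arm(channels, gate):
        sel = select_channels(stream, channels)
        if gate is not None:
            sel = sel.intersect(microtime_gate(stream, *gate))
        if len(sel) == 0:
            raise DegenerateInputError("gate excludes all photons")
        t = stream.macro_times[sel.indices].astype(float) * stream.header.macro_time_resolution
        w = None if weights is None else np.asarray(weights, dtype=float)[sel.indices]
        return sel.indices, t, w

    idx_a, ta, wa = arm(channels_a, gate_a)
    idx_b, tb, wb = arm(channels_b, gate_b)
    multi_tau_kwargs.setdefault("delta0", stream.header.macro_time_resolution)
    if np.array_equal(idx_a, idx_b):
        return multi_tau(ta, None, weights_a=wa, weights_b=wb, **multi_tau_kwargs)
    return multi_tau(ta, tb, weights_a=wa, weights_b=wb, **multi_tau_kwargs)


@dataclass
class FcsFilterSet:
    """Per-species photon weights derived from micro-time decay patterns."""

    filters: np.ndarray    # (n_species, n_channels, n_bins)
    patterns: np.ndarray   # (n_species, n_channels, n_bins), rows sum to 1

    def weights_for(self, species: int, channel_index: np.ndarray, microtime_bin: np.ndarray):
        """Per-photon weights for one species from (channel, micro-bin) pairs."""
        return self.filters[species, channel_index, microtime_bin]


def compute_fcs_filters(patterns: np.ndarray, mixture: np.ndarray) -> FcsFilterSet:
    """Least-squares species filters for filtered FCS.

    ``patterns[k]`` is the normalized (channel, micro-time) probability
    pattern of species k; ``mixture`` the measured histogram of the mix.
    The weighted least-squares solution ``f = (M' D M)^-1 M' D`` with
    ``D = diag(1/S)`` makes the filters unbiased: applying filter k to
    photons drawn from pattern j recovers delta_kj in expectation.
    """
    patterns = np.asarray(patterns, dtype=float)
    mixture = np.asarray(mixture, dtype=float)
    if patterns.ndim == 2:
        patterns = patterns[:, None, :]
    if mixture.ndim == 1:
        mixture = mixture[None, :]
    K = patterns.shape[0]
    shape = patterns.shape[1:]
    if mixture.shape != shape:
        raise ParameterError("mixture histogram shape must match the patterns")
    M = patterns.reshape(K, -1).T          # (n_obs, K)
    S = mixture.reshape(-1)
    used = S > 0
    if np.any((M.sum(axis=1) > 0) & ~used):
        raise ParameterError("mixture histogram is zero where a pattern has support")
    Mu = M[used]
    D = 1.0 / S[used]
    N = Mu.T @ (D[:, None] * Mu)
    cond = np.linalg.cond(N)
    if not np.isfinite(cond) or cond > 1e12:
        corr = np.corrcoef(Mu.T)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ConditioningError(
            f"species patterns nearly collinear (species {i} and {j}, "
            f"cond(N) = {cond:.2e})"
        )
    F = np.zeros((K, len(S)))
    F[:, used] = np.linalg.solve(N, Mu.T * D[None, :])
    return FcsFilterSet(F.reshape((K,) + shape), patterns)
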