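"""Burst search, FRET indicators, lifetime estimator and BVA."""

import numpy as np
import pytest

import photonstream as ps
from photonstream.burst import lifetime_from_microtimes
from photonstream.errors import DegenerateInputError, ParameterError


def overlap_recall(intervals, bursts, min_expected=40, brightness=50e3):
    """Fraction of planted intervals (long enough to be findable) that
    overlap at least one detected burst."""
    det = np.array([[b.t_start, b.t_start + b.duration] for b in bursts]).reshape(-1, 2)
    eligible = (intervals[:, 1] - intervals[:, 0]) * brightness >= min_expected
    hits = 0
    for a, b in intervals[eligible]:
        if len(det) and np.any((det[:, 0] <= b) & (det[:, 1] >= a)):
            hits += 1
    return hits / max(1, eligible.sum()), int(eligible.sum())


class TestBurstSearch:
    def test_sparse_background_no_bursts(self):
        s = ps.simulate_background({0: 500.0, 1: 500.0}, duration=5.0, seed=0)
        assert ps.burst_search(s, [0, 1], 1e-3, n_min=15, L_min=20) == []

    def test_empty_selection_empty_list(self):
        s = ps.simulate_background({0: 500.0}, duration=1.0, seed=1)
        assert ps.burst_search(s, [5], 1e-3, 1, 1) == []

    def test_planted_bursts_recovered_at_high_contrast(self):
        """50x brightness contrast: nearly every planted burst is found."""
        s, gt = ps.simulate_bursts(
            E=0.5, burst_rate=10, mean_duration=4e-3, brightness=50e3,
            duration=30.0, background={0: 500, 1: 500}, seed=7)
        bursts = ps.burst_search(s, [0, 1], 1e-3, n_min=10, L_min=20)
        recall, n_eligible = overlap_recall(gt.burst_intervals, bursts)
        assert n_eligible > 100
        assert recall >= 0.95

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_selection_plus_run_grouping_oracle(self, seed):
        """burst_search == oracle composition of the windowed selection
        (restricted to the channels) with run-length grouping."""
        s, _ = ps.simulate_bursts(duration=5.0, background={0: 1e3, 1: 1e3},
                                  seed=seed)
        window, n_min, L_min = 5e-4, 12, 25
        got = ps.burst_search(s, [0, 1], window, n_min, L_min)
        sel = ps.select_channels(s, [0, 1])
        sub = s.take(sel.indices)
        cand = ps.select_time_window(sub, window, n_min).indices
        runs, cur = [], [cand[0]] if len(cand) else []
        for i in cand[1:]:
            if i == cur[-1] + 1:
                cur.append(i)
            else:
                runs.append(cur)
                cur = [i]
        if cur:
            runs.append(cur)
        want = [(int(sel.indices[r[0]]), int(sel.indices[r[-1]]) + 1)
                for r in runs if len(r) >= L_min]
        assert [(b.start, b.stop) for b in got] == want


class TestIndicators:
    def make_burst(self, s_g, s_r, duration=1e-3):
        macro = np.arange(s_g + s_r, dtype=np.uint64)
        ch = np.array([0] * s_g + [1] * s_r, dtype=np.uint16)
        h = ps.HeaderInfo(duration / max(1, s_g + s_r - 1) if s_g + s_r > 1 else 1e-3,
                          1e-11, 256)
        stream = ps.EventStream(macro, np.zeros(len(ch), dtype=np.uint32), ch,
                                np.zeros(len(ch), dtype=np.uint8), h)
        b = ps.Burst(start=0, stop=len(ch), duration=duration)
        return b, stream

    def test_no_red_gives_zero(self):
        b, s = self.make_burst(10, 0)
        ps.burst_indicators(b, s, [0], [1])
        assert b.e_raw == 0.0

    def test_symmetric_counts_give_half(self):
        b, s = self.make_burst(25, 25)
        ps.burst_indicators(b, s, [0], [1])
        assert b.e_raw == 0.5
        assert b.e_corr == 0.5

    def test_zero_photons_degenerate(self):
        b, s = self.make_burst(5, 5)
        with pytest.raises(DegenerateInputError):
            ps.burst_indicators(b, s, [7], [8])  # no photons in these groups

    @pytest.mark.parametrize("seed", range(20))
    def test_randomized_corrections_match_arithmetic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s_g, s_r = int(rng.integers(1, 200)), int(rng.integers(1, 200))
        dur = float(rng.uniform(1e-4, 1e-2))
        b_g, b_r = rng.uniform(0, 2e3, 2)
        alpha, gamma = float(rng.uniform(0, 0.2)), float(rng.uniform(0.5, 2.0))
        b, s = self.make_burst(s_g, s_r, duration=dur)
        ps.burst_indicators(b, s, [0], [1], b_g=b_g, b_r=b_r, alpha=alpha, gamma=gamma)
        # independent step-by-step re-evaluation
        f_g = s_g - b_g * dur
        f_r = s_r - b_r * dur - alpha * f_g
        f_g, f_r = max(f_g, 0.0), max(f_r, 0.0)
        assert b.e_raw == pytest.approx(s_r / (s_g + s_r))
        if f_r + gamma * f_g > 0:
            e = min(max(f_r / (f_r + gamma * f_g), -0.1), 1.1)
            assert b.e_corr == pytest.approx(e)


class TestLifetime:
    def test_recovery_large_sample(self):
        tau, T, n = 2.5e-9, 25e-9, 100_000
        rng = np.random.default_rng(0)
        x = rng.exponential(tau, size=3 * n)
        x = x[x < T][:n]
        got = lifetime_from_microtimes(x, T)
        assert abs(got - tau) < 3 * tau / np.sqrt(n)

    def test_long_window_limit_reduces_to_mean_arrival(self):
        """T >> tau: the truncation correction vanishes and tau ~ mean - t0."""
        x = np.array([1.0e-9, 3.0e-9, 2.0e-9, 1.5e-9])
        t0 = 0.5e-9
        got = lifetime_from_microtimes(x, T=1e-3, t0=t0)
        assert got == pytest.approx(float(x.mean()) - t0, rel=1e-6)

    def test_uniform_microtimes_have_no_solution(self):
        T = 25e-9
        assert lifetime_from_microtimes(np.full(100, T / 2), T) is None
        assert lifetime_from_microtimes(np.full(100, 0.9 * T), T) is None

    def test_burst_wrapper_flags_low_count(self, header):
        n = 5
        s = ps.EventStream(np.arange(n, dtype=np.uint64),
                           np.full(n, 10, dtype=np.uint32),
                           np.zeros(n, dtype=np.uint16),
                           np.zeros(n, dtype=np.uint8), header)
        b = ps.Burst(start=0, stop=n)
        ps.burst_lifetime(b, s, [0], T=header.micro_time_span)
        assert "low_count" in b.flags

    def test_solver_against_forward_mean(self):
        """Round trip: tau -> analytic truncated mean -> solver -> tau."""
        T = 25e-9
        for tau in (0.5e-9, 2e-9, 8e-9):
            mean = tau - T / np.expm1(T / tau)
            got = lifetime_from_microtimes(np.array([mean]), T)
            assert got == pytest.approx(tau, rel=1e-6)


class TestBva:
    def _stream_from_channels(self, channels, header):
        n = len(channels)
        return ps.EventStream(
            np.arange(n, dtype=np.uint64), np.zeros(n, dtype=np.uint32),
            np.asarray(channels, dtype=np.uint16), np.zeros(n, dtype=np.uint8),
            header)

    def test_all_green_zero_sd(self, header):
        s = self._stream_from_channels([0] * 20, header)
        b = ps.Burst(start=0, stop=20)
        ps.bva(b, s, [0], [1], n_window=5)
        assert b.bva_sd == 0.0 and b.bva_shot == 0.0

    def test_alternating_blocks_exceed_shot_noise(self, header):
        """Pure-green then pure-red windows: sd is the hand-computable
        alternating-sequence value, far above the shot-noise curve."""
        seq = ([0] * 5 + [1] * 5) * 4
        s = self._stream_from_channels(seq, header)
        b = ps.Burst(start=0, stop=len(seq))
        ps.bva(b, s, [0], [1], n_window=5)
        # PR per window alternates 0, 1: mean 0.5, sample sd of [0,1]*4
        expect_sd = np.std([0, 1] * 4, ddof=1)
        assert b.bva_sd == pytest.approx(expect_sd)
        assert b.bva_shot == pytest.approx(np.sqrt(0.25 / 5))
        assert b.bva_sd > 2 * b.bva_shot

    def test_insufficient_photons_flagged(self, header):
        s = self._stream_from_channels([0, 1, 0], header)
        b = ps.Burst(start=0, stop=3)
        ps.bva(b, s, [0], [1], n_window=5)
        assert "bva_insufficient" in b.flags

    def test_static_efficiency_fraction_above_shot_noise_is_half(self):
        """Static E: about half the bursts sit above the shot-noise curve
        (binomial test at alpha = 0.01)."""
        s, _ = ps.simulate_bursts(
            E=0.5, burst_rate=8, mean_duration=5e-3, brightness=150e3,
            duration=60.0, background={0: 500, 1: 500}, seed=3)
        bursts = ps.burst_search(s, [0, 1], 1e-3, n_min=20, L_min=100)
        above = total = 0
        for b in bursts:
            ps.burst_indicators(b, s, [0], [1])
            ps.bva(b, s, [0], [1], n_window=5)
            if np.isfinite(b.bva_sd):
                total += 1
                above += b.bva_sd > b.bva_shot
        assert total > 200
        z = (above / total - 0.5) / np.sqrt(0.25 / total)
        assert abs(z) < 2.58

    def test_mean_sd_matches_shot_noise_for_static_e(self):
        s, _ = ps.simulate_bursts(
            E=0.5, burst_rate=8, mean_duration=5e-3, brightness=150e3,
            duration=30.0, background={0: 500, 1: 500}, seed=11)
        bursts = ps.burst_search(s, [0, 1], 1e-3, n_min=20, L_min=100)
        sds, shots = [], []
        for b in bursts:
            ps.bva(b, s, [0], [1], n_window=5)
            if np.isfinite(b.bva_sd):
                sds.append(b.bva_sd)
                shots.append(b.bva_shot)
        sds, shots = np.array(sds), np.array(shots)
        se = sds.std(ddof=1) / np.sqrt(len(sds))
        assert abs(sds.mean() - shots.mean()) < 3 * se


class TestParameterRecovery:
    @pytest.mark.parametrize("E", [0.2, 0.5, 0.8])
    def test_mean_proximity_ratio_matches_truth(self, E):
        s, _ = ps.simulate_bursts(
            E=E, burst_rate=12, mean_duration=2e-3, brightness=80e3,
            duration=60.0, background={0: 300, 1: 300}, seed=int(E * 10))
        bursts = ps.burst_search(s, [0, 1], 1e-3, n_min=15, L_min=30)
        for b in bursts:
            ps.burst_indicators(b, s, [0], [1])
        e = np.array([b.e_raw for b in bursts])
        assert len(e) >= 500
        se = e.std(ddof=1) / np.sqrt(len(e))
        assert abs(e.mean() - E) < 3 * se


@pytest.fixture(scope="module")
def bursts():
    s, _ = ps.simulate_bursts(duration=20.0, background={0: 300, 1: 300}, seed=5)
    bl = ps.burst_search(s, [0, 1], 1e-3, 10, 30)
    for b in bl:
        ps.burst_indicators(b, s, [0], [1])
    return bl


class TestHistogramsAndGates:

    def test_histogram_conserves_bursts(self, bursts):
        hist, _ = ps.burst_histogram(bursts, "E_raw", bins=25, range=(0, 1))
        assert hist.sum() == len(bursts)

    def test_2d_histogram_conserves_bursts(self, bursts):
        hist, _, _ = ps.burst_histogram(bursts, "E_raw", bins=10, y="S")
        assert hist.sum() == len(bursts)

    def test_full_plane_gate_keeps_all(self, bursts):
        assert len(ps.select_bursts(bursts, E_raw=(None, None))) == len(bursts)

    def test_empty_gate_empty_subset(self, bursts):
        assert ps.select_bursts(bursts, E_raw=(2.0, 3.0)) == []

    def test_gate_is_rectangle(self, bursts):
        sub = ps.select_bursts(bursts, E_raw=(0.4, 0.6), S=(50, None))
        for b in sub:
            assert 0.4 <= b.e_raw <= 0.6 and b.n_photons >= 50
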