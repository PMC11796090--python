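"""Image reconstruction, fast FLIM, segmentation, phasor and ICS."""

import numpy as np
import pytest

import photonstream as ps
from photonstream.errors import DegenerateInputError, ParameterError

MARKERS = (4, 1, 2)  # frame, line start, line stop


def small_scan(seed=0, H=8, W=16, n_frames=3, rate=30e3, tau=2.5e-9, **kw):
    rate_map = np.full((H, W), rate)
    tau_map = np.full((H, W), tau)
    return ps.simulate_clsm_scan(rate_map, tau_map, n_frames=n_frames,
                                 marker_config=MARKERS, seed=seed, **kw)


class TestBuildImageStack:
    def test_reproduces_simulator_assignments_exactly(self):
        s, gt = small_scan(seed=1)
        stack = ps.build_image_stack(s, MARKERS, n_pixels=16)
        assert stack.n_frames == 3 and stack.n_lines == 8 and stack.n_pixels == 16
        assert np.array_equal(stack.counts(), gt.pixel_photon_counts)
        assert stack.n_discarded == 0

    def test_photon_conservation_with_discards(self):
        s, _ = small_scan(seed=2, background=20e3)
        stack = ps.build_image_stack(s, MARKERS, n_pixels=16)
        n_photons = int(s.photon_mask.sum())
        assert stack.counts().sum() + stack.n_discarded == n_photons
        assert stack.n_discarded > 0   # background during retrace

    def test_photon_at_line_start_lands_in_pixel_zero(self, header):
        # hand-built stream: start marker, photon at the same tick, stop
        s = ps.EventStream(
            np.array([100, 100, 200, 300], dtype=np.uint64),
            np.zeros(4, dtype=np.uint32),
            np.array([1, 0, 0, 2], dtype=np.uint16),
            np.array([1, 0, 0, 1], dtype=np.uint8),
            header)
        stack = ps.build_image_stack(s, MARKERS, n_pixels=4)
        assert np.array_equal(stack.assignment[0], (0, 0, 0))
        # photon at tick 200 of span [100, 300): pixel 4*(100)/200 = 2
        assert stack.assignment[1][2] == 2

    def test_photon_at_exact_stop_clamped_to_last_pixel(self, header):
        s = ps.EventStream(
            np.array([100, 300, 300], dtype=np.uint64),
            np.zeros(3, dtype=np.uint32),
            np.array([1, 0, 2], dtype=np.uint16),
            np.array([1, 0, 1], dtype=np.uint8),
            header)
        stack = ps.build_image_stack(s, MARKERS, n_pixels=4)
        assert stack.assignment[0][2] == 3

    def test_missing_markers_raise(self, header):
        s = ps.EventStream(np.array([1], dtype=np.uint64), [0], [0], [0], header)
        with pytest.raises(ParameterError):
            ps.build_image_stack(s, MARKERS, n_pixels=8)

    def test_unmatched_start_raises(self, header):
        s = ps.EventStream(
            np.array([10, 20, 30], dtype=np.uint64), np.zeros(3, dtype=np.uint32),
            np.array([1, 2, 1], dtype=np.uint16), np.ones(3, dtype=np.uint8),
            header)
        with pytest.raises(ParameterError):
            ps.build_image_stack(s, MARKERS, n_pixels=8)

    def test_lines_before_first_frame_marker_join_frame_zero(self, header):
        # line pair, then a frame marker, then another line pair
        s = ps.EventStream(
            np.array([0, 100, 150, 200, 300], dtype=np.uint64),
            np.zeros(5, dtype=np.uint32),
            np.array([1, 2, 4, 1, 2], dtype=np.uint16),
            np.ones(5, dtype=np.uint8),
            header)
        stack = ps.build_image_stack(s, MARKERS, n_pixels=2)
        assert stack.n_frames == 2


class TestIntensityAndFlim:
    def test_empty_frame_range_zero_image(self):
        s, _ = small_scan(seed=3)
        stack = ps.build_image_stack(s, MARKERS, n_pixels=16)
        assert ps.intensity_image(stack, frames=[]).sum() == 0

    def test_uniform_rate_poisson_per_pixel(self):
        rate, dwell, F = 50e3, 10e-6, 4
        s, _ = small_scan(seed=4, rate=rate, n_frames=F, H=8, W=8,
                          dwell_time=dwell)
        stack = ps.build_image_stack(s, MARKERS, n_pixels=8)
        img = ps.intensity_image(stack)
        mu = rate * dwell * F
        frac = np.mean(np.abs(img - mu) <= 4 * np.sqrt(mu))
        assert frac >= 0.99

    def test_constant_microtime_flim(self, header):
        s, _ = small_scan(seed=5)
        const = ps.EventStream(s.macro_times, np.full(s.n_events, 40, np.uint32),
                               s.routing_channels, s.event_types, s.header)
        stack = ps.build_image_stack(const, MARKERS, n_pixels=16)
        img = ps.mean_microtime_image(stack, min_photons=1)
        set_px = np.isfinite(img)
        assert np.allclose(img[set_px], 40 * s.header.micro_time_resolution)

    def test_min_photons_unsets_everything_when_too_high(self):
        s, _ = small_scan(seed=6)
        stack = ps.build_image_stack(s, MARKERS, n_pixels=16)
        img = ps.mean_microtime_image(stack, min_photons=10**9)
        assert not np.any(np.isfinite(img))

    def test_lifetime_map_recovery(self):
        """Fast FLIM recovers a two-level lifetime map within 3 SE."""
        H, W = 8, 8
        tau_map = np.where(np.arange(W)[None, :] < W // 2, 1.5e-9, 3.5e-9)
        tau_map = np.broadcast_to(tau_map, (H, W)).copy()
        rate_map = np.full((H, W), 600e3)
        s, _ = ps.simulate_clsm_scan(rate_map, tau_map, dwell_time=20e-6,
                                     n_frames=6, marker_config=MARKERS,
                                     rep_period=100e-9, seed=7)
        stack = ps.build_image_stack(s, MARKERS, n_pixels=W)
        img = ps.mean_microtime_image(stack, min_photons=20)
        counts = ps.intensity_image(stack)
        ok = np.isfinite(img)
        z = (img[ok] - tau_map[ok]) / (tau_map[ok] / np.sqrt(counts[ok]))
        assert np.mean(np.abs(z) <= 3) >= 0.97


class TestSegmentation:
    def test_single_band_single_class(self):
        img = np.random.default_rng(0).uniform(0, 10, (8, 8))
        labels = ps.segment_pixels(img, thresholds=[-1.0])
        assert np.all(labels == 1)

    def test_median_split_balanced(self):
        img = np.arange(64, dtype=float).reshape(8, 8)
        labels = ps.segment_pixels(img, quantiles=[0.5])
        n0, n1 = (labels == 0).sum(), (labels == 1).sum()
        assert abs(n0 - n1) <= 1

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        img = rng.normal(size=(16, 16))
        th = [-0.5, 0.5]
        labels = ps.segment_pixels(img, thresholds=th)
        want = np.where(img < -0.5, 0, np.where(img < 0.5, 1, 2))
        assert np.array_equal(labels, want)

    def test_empty_band_spec_raises(self):
        with pytest.raises(ParameterError):
            ps.segment_pixels(np.ones((4, 4)), thresholds=[])


@pytest.fixture(scope="module")
def scan():
    H, W = 8, 8
    tau_map = np.where(np.arange(W)[None, :] < W // 2, 1.0e-9, 4.0e-9)
    tau_map = np.broadcast_to(tau_map, (H, W)).copy()
    s, gt = ps.simulate_clsm_scan(
        np.full((H, W), 80e3), tau_map, dwell_time=20e-6, n_frames=4,
        marker_config=MARKERS, rep_period=100e-9, seed=8)
    stack = ps.build_image_stack(s, MARKERS, n_pixels=W)
    return stack, tau_map


class TestClassDecay:

    def test_all_pixel_class_equals_whole_image_decay(self, scan):
        stack, _ = scan
        labels = np.zeros((stack.n_lines, stack.n_pixels), dtype=int)
        decay = ps.class_decay(stack, labels, 0)
        assert decay.counts.sum() == stack.counts().sum()

    def test_disjoint_classes_sum_to_total(self, scan):
        stack, tau_map = scan
        labels = (tau_map > 2e-9).astype(int)
        d0 = ps.class_decay(stack, labels, 0)
        d1 = ps.class_decay(stack, labels, 1)
        total = ps.class_decay(stack, np.zeros_like(labels), 0)
        assert np.array_equal(d0.counts + d1.counts, total.counts)

    def test_two_lifetime_classes_recovered(self, scan):
        stack, tau_map = scan
        labels = (tau_map > 2e-9).astype(int)
        res = stack.stream.header.micro_time_resolution
        for cid, tau in ((0, 1.0e-9), (1, 4.0e-9)):
            d = ps.class_decay(stack, labels, cid)
            centers = 0.5 * (d.bin_edges[:-1] + d.bin_edges[1:])
            mean = float((centers * d.counts).sum() / d.counts.sum()) * res
            se = tau / np.sqrt(d.counts.sum())
            assert abs(mean - tau) < 3 * se + res

    def test_unknown_class_raises(self, scan):
        stack, _ = scan
        labels = np.zeros((stack.n_lines, stack.n_pixels), dtype=int)
        with pytest.raises(ParameterError):
            ps.class_decay(stack, labels, 42)


class TestPhasor:
    REP = 50e-9

    def test_delta_decay_at_unit_point(self):
        g, s = ps.phasor_transform(np.zeros(100), self.REP)
        assert (g, s) == (1.0, 0.0)

    def test_zero_photons_raise(self):
        with pytest.raises(DegenerateInputError):
            ps.phasor_transform(np.array([]), self.REP)

    @pytest.mark.parametrize("tau", [1e-9, 3e-9])
    def test_single_exponential_on_universal_circle(self, tau):
        rng = np.random.default_rng(3)
        n = 200_000
        t = np.mod(rng.exponential(tau, n), self.REP)
        g, s = ps.phasor_transform(t, self.REP)
        omega = 2 * np.pi / self.REP
        g0, s0 = ps.phasor_reference_point(omega, tau)
        # SE of a bounded cos/sin mean
        se = 1.0 / np.sqrt(n)
        assert abs(g - g0) < 3 * se
        assert abs(s - s0) < 3 * se

    def test_mixture_lies_on_chord(self):
        rng = np.random.default_rng(4)
        n = 100_000
        t1 = np.mod(rng.exponential(1e-9, n), self.REP)
        t2 = np.mod(rng.exponential(4e-9, n), self.REP)
        z1 = complex(*ps.phasor_transform(t1, self.REP))
        z2 = complex(*ps.phasor_transform(t2, self.REP))
        zm = complex(*ps.phasor_transform(np.concatenate([t1, t2]), self.REP))
        # exact linearity: pooled phasor = photon-weighted mean of parts
        assert abs(zm - (z1 + z2) / 2) < 1e-12

    def test_pooled_linearity_identity_random_partition(self):
        rng = np.random.default_rng(5)
        t = rng.uniform(0, self.REP, 10_001)
        k = rng.integers(0, 3, len(t))
        zs, ws = [], []
        for part in range(3):
            sub = t[k == part]
            zs.append(complex(*ps.phasor_transform(sub, self.REP)))
            ws.append(len(sub))
        pooled = complex(*ps.phasor_transform(t, self.REP))
        mean = sum(w * z for w, z in zip(ws, zs)) / sum(ws)
        assert abs(pooled - mean) < 1e-12

    def test_reference_calibration_removes_irf_shift(self):
        """A shifted (IRF-displaced) reference rotates the sample back
        onto its analytic single-exponential point."""
        rng = np.random.default_rng(6)
        n, tau, tau_ref, shift = 300_000, 3e-9, 1e-9, 2e-9
        sample = np.mod(rng.exponential(tau, n) + shift, self.REP)
        ref = np.mod(rng.exponential(tau_ref, n) + shift, self.REP)
        g, s = ps.phasor_transform(sample, self.REP, reference=(ref, tau_ref))
        omega = 2 * np.pi / self.REP
        g0, s0 = ps.phasor_reference_point(omega, tau)
        assert abs(g - g0) < 5 / np.sqrt(n)
        assert abs(s - s0) < 5 / np.sqrt(n)

    def test_phasor_image_matches_per_pixel_transform(self):
        s, _ = small_scan(seed=9, H=4, W=4, n_frames=2, rate=60e3)
        stack = ps.build_image_stack(s, MARKERS, n_pixels=4)
        rep = s.header.micro_time_span
        ph = ps.phasor_image(stack, min_photons=1)
        res = s.header.micro_time_resolution
        for line in range(4):
            for px in range(4):
                micro = []
                for f in range(stack.n_frames):
                    idx = stack.pixel_photons(f, line, px)
                    micro.extend(s.micro_times[idx])
                if micro:
                    g, sv = ps.phasor_transform(np.array(micro) * res, rep)
                    assert ph.g[line, px] == pytest.approx(g, abs=1e-12)
                    assert ph.s[line, px] == pytest.approx(sv, abs=1e-12)

    def test_constant_microtime_image_single_point(self):
        s, _ = small_scan(seed=10, H=4, W=4, n_frames=1)
        const = ps.EventStream(s.macro_times, np.full(s.n_events, 17, np.uint32),
                               s.routing_channels, s.event_types, s.header)
        stack = ps.build_image_stack(const, MARKERS, n_pixels=4)
        ph = ps.phasor_image(stack, min_photons=1)
        set_px = np.isfinite(ph.g)
        assert np.allclose(ph.g[set_px], ph.g[set_px].flat[0])
        assert np.allclose(ph.s[set_px], ph.s[set_px].flat[0])


def ics_oracle(image):
    """O(N^4) shifted-product oracle with circular wrapping."""
    image = np.asarray(image, dtype=float)
    H, W = image.shape
    mean = image.mean()
    d = image - mean
    out = np.zeros_like(d)
    for dx in range(H):
        for dy in range(W):
            out[dx, dy] = np.mean(d * np.roll(np.roll(d, -dx, 0), -dy, 1))
    return out / mean**2


class TestIcs:
    def test_constant_image_zero(self):
        g = ps.ics_autocorrelation(np.full((8, 8), 3.0))
        assert np.allclose(g, 0.0)

    def test_zero_lag_is_var_over_mean_squared(self):
        rng = np.random.default_rng(0)
        img = rng.poisson(20, (16, 16)).astype(float)
        g = ps.ics_autocorrelation(img)
        assert g[0, 0] == img.var() / img.mean() ** 2

    @pytest.mark.parametrize("seed", range(5))
    def test_fft_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(1, 10, (16, 16))
        got = ps.ics_autocorrelation(img)
        assert np.max(np.abs(got - ics_oracle(img))) < 1e-10

    def test_zero_mean_image_raises(self):
        with pytest.raises(DegenerateInputError):
            ps.ics_autocorrelation(np.zeros((4, 4)))

    def test_too_small_image_raises(self):
        with pytest.raises(ParameterError):
            ps.ics_autocorrelation(np.ones((1, 5)))
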