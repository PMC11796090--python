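# Methods

This note records the models the package implements, the conventions it
fixes where the field has several, and what the synthetic data do and do
not establish.

## Event model

A stream is four parallel arrays — macro times (unsigned ticks), micro
times (TCSPC channel), routing channels, event types (photon/marker) —
plus a header with the two clock resolutions, the TCSPC channel count
and a free-form metadata map. Macro times are **absolute**: counter
overflows are resolved at read time (the T3 decoder consumes overflow
records into an epoch), so every algorithm may assume a non-decreasing
time axis. Markers live in the same arrays rather than a side table
because pixel assignment needs their global ordering. All indexing is
0-based with half-open ranges; merging is stable with first-argument
priority at equal macro times. Merging additionally requires equal
macro-time resolutions (beyond equal TCSPC geometry): tick counters with
different tick lengths cannot share one axis.

**Time-window selection.** A photon is selected when the number of
photons (all channels, itself included) with times in the **closed,
centred** window `[t−w/2, t+w/2]` lies in `[n_min, n_max]`. Centred
counting is symmetric and directly checkable against an O(n²)
neighbour-count oracle; leading/trailing variants would be equally
defensible, so the choice is fixed here once. Restricting the counted
population is done by composing a channel selection first.

## Containers

STTR is the normative open container (magic, u64 header length, UTF-8
JSON header, 16-byte little-endian records: u64 macro, u32 micro, u16
channel, u8 type, 1 reserved byte). Its job is bit-stable round trips
for archiving and testing; metadata is carried verbatim in the JSON
header. PhotonHDF5 support covers the mandatory `/photon_data` fields;
everything else in a file is preserved as opaque metadata keys. Since
plain PhotonHDF5 has no marker slot, markers written by this package go
to an auxiliary `/photon_data/event_types` dataset which the reader
honours when present. The T3 decoder is dialect-table-driven: bit
offsets/widths for sync counter, TCSPC counter, channel and special
flag, an overflow rule (channel value, ticks per record, sync field as
multiplier) and marker channels; a matching encoder exists solely so
tests can round-trip synthetic blocks.

## Simulator

The generators define the study conditions used throughout the tests:

* **Background** — homogeneous Poisson per channel, uniform micro times.
* **Bursts** — molecule transits are *rectangular* intensity epochs:
  starts Poisson (default 2 s⁻¹; recovery tests use 8–12 s⁻¹ to collect
  ≥500 bursts in a minute of simulated time), durations exponential
  (default 4 ms), within-burst emission Poisson at 50 kHz default over a
  0.3–1 kHz background, 20 MHz repetition rate, 256 TCSPC channels.
  Each photon is acceptor with probability E. Micro times follow the
  kinetic picture: donor decay quenched to `τ_D(1−E)`; an acceptor
  photon adds its own `τ_A` exponential after a donor-residence delay;
  Gaussian IRF jitter (default σ = 0.2 ns) is added and wrapped into
  the repetition period. Overlapping burst drawings are discarded so
  ground-truth intervals are disjoint.
* **Scans** — per frame: frame marker, then per line a start marker, W
  equal pixel dwells (default 10 µs) emitting at the pixel's rate with
  the pixel's mono-exponential lifetime, a stop marker, then a retrace
  dead time (default 4 dwells). All scan event times are integer macro
  ticks with pixel boundaries on ticks, so the drawn pixel of every
  photon is exactly recoverable — pixel binning is tested as an exact,
  not statistical, reconstruction.

Not simulated: diffusion kinetics (no burst shape), triplet/blinking,
polarization, detector afterpulsing/dead time. Consequently the tests
establish algorithmic correctness (selection, counting, estimation,
normalization) on streams whose *statistics* match real data locally,
not performance under real transit-shape or photophysics artifacts.
One named `numpy.random.Generator` per call; identical seeds give
identical streams.

## Correlation

`G(τ)` is estimated from (weighted) photon pair counts per lag bin,
normalized by the count expected for independent stationary Poisson
streams of the same total weights over the same span:
`G_k = K_k · T² / (W_A W_B Δτ_k (T − τ̄_k))`. The `T − τ̄` factor removes
the finite-record bias at long lags; with it, `E[G] = 1` for independent
inputs at every lag — the property the tests assert. Sign convention:
positive lag means B after A. Lag-zero self-pairs are subtracted in
autocorrelation (the shot-noise self-term is not part of G).

The multi-tau estimator uses 16 bins per cascade: cascade 0 covers lags
`[0, 16)·Δ₀` at base resolution; each further cascade covers `[8, 16)`
coarse ticks at doubled spacing after floor-dividing photon ticks by two
and summing coincident weights (total weight conserved). Cascade 0 is
bitwise identical to the exact pair correlator on the same edges, which
is the cross-validation the tests run. Default `Δ₀` is one macro tick;
cascades default to covering `[Δ₀, T/10]`.

**Error bars.** The per-bin standard error is derived from the pair
count with a multiplicity correction,
`SE_k = G_k √((1 + (a+b)Δτ_k)/K_k)` where `a, b` are the two streams'
count rates: once a bin is wider than the mean inter-photon spacing,
pairs share photons and the naive `G/√K` underestimates the variance by
orders of magnitude at long lags (window-overlap covariance of Poisson
counts). The corrected error makes the independent-Poisson z-scores
approximately standard normal across the whole lag grid.

**Filtered FCS.** Given per-species micro-time patterns `p_k`
(normalized) and the measured mixture histogram `S`, the weights are the
weighted least-squares solution `f = (Mᵀ D M)⁻¹ Mᵀ D`, `D = diag(1/S)`.
`f M = I` holds algebraically, so the δ-unbiasedness test (to 1e-10) is
a conditioning check; a normal-matrix condition number above 1e12 raises
an error naming the most collinear species pair.

## Burst analysis

Burst search composes the oracle-tested windowed selection (on the
chosen channels) with run grouping: maximal runs of consecutive
candidate photons, discarding runs shorter than `L_min`. Note that with
no background at all, consecutive bursts merge (there are no
intervening non-candidate photons); realistic background separates
them.

Indicators follow the standard correction chain (background, crosstalk
α, detection ratio γ). Negative corrected signals are floored at zero
and flagged; `E_corr` is clamped to `[−0.1, 1.1]` with a flag rather
than discarded — corrections can legitimately overshoot and analysts
filter on flags downstream.

The lifetime estimator inverts the mean of an exponential truncated to
the observation window `T`: `⟨t⟩ − t₀ = τ − T/(e^{T/τ}−1)`, solved by
bracketed Brent iteration to 1e-9 relative tolerance. The right side is
monotone from 0 to T/2, so a sample mean at or beyond `T/2` (within
float roundoff of the boundary) has no solution and is flagged instead
of extrapolated. The estimator is chosen for robustness at tens of
photons; it is *not* an IRF-deconvolving MLE, and with a real IRF a
micro-time gate (excluding the wrap-around region) plus the `t₀` offset
is the intended calibration path.

BVA splits the burst's green+red photons into consecutive
non-overlapping windows of exactly `n_window` (default 5) photons,
dropping the remainder, and reports the per-window proximity-ratio mean
and sample SD next to the binomial expectation `√(PR(1−PR)/n)`. For a
static species the SD distribution straddles the shot-noise curve
(fraction above ≈ 1/2 — slightly below for few windows because the
sample SD is a biased estimator of σ); sustained excess indicates
within-burst dynamics.

PDA builds the joint `P(S_G, S_R)` exactly: per species, the
fluorescence count `F ~ P(F)` splits binomially into red with
`ε = (α + γE/(1−E)) / (1 + α + γE/(1−E))` (ε = 1 at E = 1); independent
Poisson backgrounds convolve onto each axis; species mix by amplitude.
The table is truncated to `S_G+S_R ≤ S_max` with the truncated mass
recorded; auto-selection grows `S_max` until that mass is below 1e-6.
Goodness-of-fit is Pearson χ² with cells of expected count < 5 pooled,
reduced by `cells − 1 − n_free`.

## Imaging

Lines are delimited by start/stop markers; a photon at tick `u` in a
line spanning `[u₀, u₁]` goes to pixel `⌊n_px (u−u₀)/(u₁−u₀)⌋`, clamped
to the last pixel at the exact stop tick — integer arithmetic, so the
simulator round trip is exact. Lines before the first frame marker
belong to frame 0 (acquisitions often start mid-frame); photons outside
all lines are discarded with a counted tally, never silently.
Bidirectional scanning is out of scope.

Fast FLIM is the per-pixel mean micro time minus `t₀`, in seconds;
pixels under `min_photons` are NaN. Channel quantization floors each
delay, giving a constant −½ channel bias that is conventionally
absorbed into `t₀`. Segmentation is deterministic threshold/quantile
banding; class decays pool the micro-time histograms of a class's
photons (disjoint classes sum exactly to the all-pixel decay).

Phasors use photon-wise sums, never histogram bins, so pooling photon
sets is exactly linear (the identity is tested to 1e-12). Calibration
with a measured reference of known lifetime multiplies by the complex
factor mapping the measured reference phasor onto its analytic
single-exponential point — equivalently a rotation plus scaling that
removes the IRF phase and modulation loss.

ICS uses the periodic (circular) FFT convention, stated in the result:
`G = ifft2(|fft2(δI)|²)/N / mean²`. The zero-lag element is recomputed
directly as `var/mean²` (the same quantity) so the identity holds to
machine zero rather than FFT roundoff; the full map is validated
against an O(N⁴) shifted-product oracle at 1e-10.

## Pipelines and determinism

The two end-to-end pipelines (`pipeline-smfret`, `pipeline-fis`) are
parameter-dictionary functions in `photonstream.pipelines` with thin CLI
wrappers. Every run writes its fully resolved configuration as JSON
beside the outputs; all computation is deterministic given the input
stream, so outputs are byte-reproducible (CSV via fixed `%.10g`
formatting; TIFF compared by decoded pixel values).

## Problem sizes

Test and acceptance workloads are sized for seconds-scale runs: burst
recovery uses ~60 s simulated measurements (≈500–600 bursts per E
value), correlator validation ≤10⁴ events per stream and 10⁵-photon
Poisson streams, PDA one million Monte-Carlo draws, imaging 8×16×3 to
16×16×8 scans, the selection oracle 50 streams up to 5000 events. These
are the regimes in which the statistical tolerances (3 SE recovery,
4 SE Monte-Carlo agreement) are meaningful without being dominated by
simulation cost.

## Known limitations

No FCS model fitting (diffusion/triplet terms), no dynamic PDA, no
IRF-deconvolving lifetime fits, no anisotropy channels, no bidirectional
or pixel-clock scan variants, no memory-mapped streaming of
larger-than-memory files. Vendor format support is deliberately limited
to the dialect-table mechanism plus one worked PicoQuant-style T3
example; full vendor header parsing is out of scope.
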