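# Methods

This note documents the signal model, the algorithms, the synthetic-data
generator, and the numerical choices behind `radarhrv`, in the order the
pipeline runs.

## FMCW signal model and preprocessing

A point scatterer at range R contributes to the mixer output of one chirp

    S_IF(t) = A · exp[ j( 2π f_b t + 4πR/λ ) ],   f_b = 2 S R / c,

with chirp slope S (Hz/s), carrier wavelength λ, and speed of light c. The
fast-time FFT separates scatterers by beat frequency; the selected bin is
`round(2 S R₀ / c · N / f_s)` for the operator-supplied chest range R₀
(N fast-time samples at rate f_s). At the defaults (77 GHz, 70 MHz/µs,
128 samples, 4 MHz) a chest at 0.6 m lands at 280 kHz, bin 9.

Defaults mirror a 3 Tx / 4 Rx single-chip sensor: 50 µs chirps, 100 Hz
frame rate, λ/2 receive spacing. The ADC window (128 / 4 MHz = 32 µs) is
shorter than the chirp; the configuration validator enforces
`samples_per_chirp / fast_fs ≤ chirp_duration` rather than equality.

Two simulator conventions matter for exactness:

* **Fast-time phase reference.** Fast-time samples are placed symmetrically
  about the ADC window center. The FFT of a symmetric window has a real
  kernel, so the selected bin's phase equals 4πR/λ exactly and the
  demodulated displacement needs no window group-delay correction. With a
  left-aligned axis the Dirichlet-kernel phase adds a configuration-
  dependent ≈1.4 % gain error on displacement — measurable against the
  round-trip test (which requires RMS ≤ λ/100 ≈ 39 µm at infinite SNR; the
  implementation achieves machine precision).
* **Stop-and-go.** Displacement is sampled once per frame (chest velocity ×
  50 µs ≪ λ) and the Tx time-division multiplexing is collapsed into one
  synchronized snapshot per frame for all virtual antennas.

**Beamforming.** The azimuth steering vector on the M = 8 half-wavelength
elements is `α(θ)ₘ = exp(−j2πm·(d/λ)·sinθ)`. MVDR weights
`ω = R⁻¹α / (αᴴR⁻¹α)` minimize output power under the unit-gain
(distortionless) constraint `ωᴴα = 1`, enforced in the returned object to
1e−9. The covariance is a single sample estimate over the whole record
(≥ M frames; 1500 frames ≫ 8 for a 15 s record) of *mean-removed*
per-antenna snapshots — static clutter otherwise dominates R — with
diagonal loading `loading · trace(R)/M` (default loading 1e−3). The
weights are applied to the raw (not mean-removed) snapshots so the target's
absolute phase is preserved. A numerically singular covariance with zero
loading raises an error advising loading > 0. Beamforming operates on the
per-bin snapshots (rather than before the range FFT); the two orders are
equivalent under linearity and this one is cheaper.

**Demodulation.** Per frame, `y = ωᴴx`; the phase sequence is unwrapped
with standard ±π jump correction (chest motion per 10 ms frame ≪ λ/4, so
unwrapping is safe), converted by `R = φλ/4π`, mean-centered, and
cubic-spline resampled from the 100 Hz frame rate to the 250 Hz working
rate (one sample = 4 ms). Zero-magnitude beamformed frames have undefined
phase and are interpolated from neighbors with a warning. Downsampling is
refused — the working rate is only ever above the frame rate.

## Heartbeat enhancement

The second difference `a(n) = (R(n+1) + R(n−1) − 2R(n)) / Ts²` annihilates
locally-affine motion, attenuating the slow respiration by its squared
frequency ratio while passing the sharp beat pulses. Edge samples replicate
the nearest interior value so the length is preserved without spurious edge
spikes. The short-time average power `P(n)` is a centered moving mean of
|a|² over 2L+1 samples, default full window 0.4 s (about half a beat
cycle); near the edges the window truncates and renormalizes by the actual
count.

**Initial cut-offs S⁰** are crests of P: local maxima accepted greedily by
descending prominence under a minimum separation (default 0.5 s), then
gaps longer than the maximum beat length (default 1.2 s) are filled with
the best remaining maximum that keeps the separation rule. One
implementation subtlety: for a compact beat event the P bump is
flat-topped (window length minus event length ≈ 280 ms of plateau), so the
raw argmax position wanders ±100 ms with whatever tilts the plateau.
Accepted crests are therefore located at the center of their
half-prominence width, which is stable for both flat-topped and rounded
bumps. Whether beat boundaries should sit at power crests or troughs is an
open modeling choice; crests are used, and the joint optimizer relocates
boundaries anyway.

**Bandpass baseline.** A zero-phase order-4 Butterworth bandpass
(0.8–1.5 Hz) on R(n), followed by positive-peak picking under the same
beat-length bounds. Peaks below 1 % of the input standard deviation are
treated as stopband residue, and two low-cutoff periods at each end are
excluded (zero-phase filtering leaves slow edge transients there). This is
deliberately the classical method: it confuses respiratory harmonics inside
the heart band with heartbeats, which is the failure mode the comparison
harness measures.

## Joint template/segmentation optimization

Successive heartbeats are assumed to share one acceleration morphology up
to temporal stretch/compression. With cut-offs S = {s₁ < s₂ < …} and a
template μ of length m, the objective is

    Var(S, μ) = Σᵢ ‖ a[sᵢ₋₁+1 : sᵢ] − ω(μ, sᵢ − sᵢ₋₁) ‖²,

where ω(·, p) is cubic-spline resampling to p points (exact identity at
p = len(input); ≥ 4 support points required). The two blocks are updated
alternately:

* **Template:** μ = (1/n) Σᵢ (sᵢ − sᵢ₋₁) · ω(a[sᵢ₋₁+1:sᵢ], m), the
  length-weighted mean of warped segments (weights sum to one since
  Σ gaps = n, the covered length). This is the exact minimizer only when
  warping is length-preserving, so monotonicity of the objective is
  guaranteed — and asserted — only at the segmentation step.
* **Segmentation:** dynamic programming over the grid of ±B-sample
  neighborhoods around the current cut-offs (B = 20 ms → 5 samples at
  250 Hz). Neighborhoods must not overlap (2B < min gap). The DP is exact
  on that grid — verified against exhaustive enumeration over the full
  candidate product on every tested instance — and since the zero offset is
  always in the grid, the objective never increases at this step. Ties are
  broken toward the lexicographically smallest cut-off tuple, and the cost
  is reported as a canonical left-to-right sum so DP and enumerator values
  are bitwise comparable.

**Convergence.** A cut-off is stable when it moved at most α₁ = 5 ms
between iterations (≤ 1 sample at 250 Hz); the loop stops when the stable
fraction reaches α₂ = 0.80 (inclusive), or after 50 iterations with a
warning and the last iterate. Template length m defaults to the median
initial beat length, keeping most warps near identity. The acceleration is
z-normalized first (a uniform rescaling of all costs; switchable).

**Translation degeneracy.** The objective is invariant, to first order,
under a uniform shift of all cut-offs: the template re-estimated in the
shifted frame matches the shifted segments as well as the true-frame
template matches the true segments (the residual asymmetry, from unequal
gap lengths entering the warps, is second-order). Consequently the
alternating iteration converges to the segmentation whose *consensus
offset* matches the initialization: all interbeat intervals are recovered,
but absolute cut-off positions only up to a global shift of a few samples.
This is harmless for HRV (IBIs are shift-invariant) and is why the exact
position-recovery experiment is run as a single segmentation update against
the construction's own template, where the minimum is unique at the truth.
With a balanced (zero-consensus) perturbation the full loop also recovers
truth exactly, typically in two iterations.

First and last partial segments (before s₁, after the last cut-off) are
excluded from the objective and from the IBI output.

## Synthetic data generator

The generator emulates a supine, normally breathing adult at 0.6 m:

* **IBIs:** mean 850 ms, SDNN 40 ms, AR(1) coefficient 0.3, clamped to
  [400, 1500] ms. The AR coefficient sets the SDNN/RMSSD ratio
  (RMSSD ≈ SDNN·√(2(1−ρ))); the stationary SD equals the requested SDNN.
* **Respiration:** 0.25 Hz quasi-sinusoid, 5 mm fundamental amplitude,
  with a 0.3-weight second harmonic by default — deliberately exercising
  the harmonic-confusion regime. The harmonic-confound fixture moves the
  rate to 0.5 Hz with a 0.6-weight second harmonic at 1.0 Hz, inside the
  0.8–1.5 Hz heart band, with mean IBI 833 ms (1.2 Hz).
* **Heartbeat:** a 120 ms raised-cosine-windowed biphasic pulse of 0.3 mm
  peak amplitude at each beat onset, evaluated at continuous onset times
  (cumulative IBI sums plus a 0.25 s lead-in) so ground-truth intervals
  are exact and the first beat is clear of the record edge. Respiration
  dominates heartbeat variance by well over 100×, as in real chest motion.
* **IF cubes:** per-frame rendering of each source (chest, plus optional
  interferers with their own displacement series — e.g. a second breathing
  person at 25° azimuth) with complex white noise at a requested per-sample
  SNR. Every stochastic step is a pure function of its seed.

What the generator does **not** emulate: body posture changes, coughing or
scratching artifacts, multipath beyond point interferers, beat-morphology
drift over minutes, and ECG-style waveform detail. Passing the recovery
tests therefore demonstrates correctness of the processing chain under the
stated motion model, not clinical performance on real subjects.

## Evaluation

IBI series are aligned to a reference by the integer beat offset (bounded
by 5 s over the shortest interval) minimizing the mean absolute IBI
difference over the overlap (minimum overlap 3 beats; ties prefer the
smaller |offset|; a mean residual above 100 ms flags a poor match). Signed
per-beat errors, their RMSE, the CDF of |err| at {4, 8, 16} ms, and the
Pearson correlation (reported as undefined for < 3 pairs or zero variance)
follow. Summaries: MEAN = ΣIBI/N; SDNN with population divisor N (the HRV
literature varies; the choice is documented and tested against a two-pass
computation); RMSSD with divisor N−1 over the N−1 successive differences.

The comparison harness runs the full pipeline, the
differential-enhancement-only extractor (initial cut-offs without joint
optimization), and the bandpass baseline on the same displacement record
and tabulates absolute MEAN/SDNN/RMSSD errors and aligned per-beat RMSE; a
method that fails on an input is reported as failed, not fatal. On the
harmonic-confound batch the expected ordering full ≤ DE ≤ BPF holds for
SDNN and RMSSD medians.

## Problem sizes and numerical choices

The quantitative experiments use: 100 random DP instances (4–5 cut-offs,
B = 2–3 samples, exhaustive product ≤ ~17k combinations); 20 tiled-template
records (8 cut-offs, gaps 130–240 samples); 20 × 60 s full-chain records at
20 dB SNR and noise-free; 20 two-source beamforming simulations (300
frames); 20 × 60 s harmonic-confound records. These sizes give stable
medians while keeping a full run in the minutes range on one CPU.

Other numerics: range-bin rounding is half-away-from-zero; segments need
≥ 4 samples (cubic warping support); warped templates are cached per
length inside a DP pass; the stability comparison adds a 1e−9 ms epsilon
so exact sample-grid moves compare inclusively; CSV/JSON writes are atomic
(temp file + rename).

## Known limitations

* A single fixed template cannot track beat-morphology drift; records of
  several minutes or longer degrade.
* No automatic range/azimuth localization of the subject; R₀ and θ are
  inputs.
* Azimuth-plane beamforming only; the elevation aperture is unused.
* The initial segmentation assumes beats between 0.5 and 1.2 s; sustained
  bradycardia/tachycardia outside that band needs adjusted bounds.
* Absolute beat-onset timing is defined only up to a global shift (see the
  translation degeneracy above); all interval-domain quantities are
  unaffected.
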