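# Methods notes

This note records the model, the numerical choices, and the limits of what
the synthetic-data validation shows. Everything quantitative stated here is
computed by the test suite or the analysis scripts; nothing is quoted from
elsewhere.

## Wavelet transform and coherence

The continuous wavelet transform uses the complex Morlet mother wavelet with
ω₀ = 6, for which the equivalent Fourier period is
T = (4π / (ω₀ + √(2+ω₀²))) · s ≈ 1.033·s. All frequency axes in the package
are derived through this factor; only axis labelling, not coherence values,
depends on it.

**Exact FFT evaluation.** The transform is defined as the discrete
correlation sum Wₙ(s) = √(Δt/s) Σ xₙ′ ψ₀*((n′−n)Δt/s). Rather than the usual
frequency-domain approximation (multiplying by the *continuous* Fourier
transform of the wavelet), the implementation samples ψ₀ in the time domain
on a zero-padded circle of length ≥ 2n (next power of two) and performs the
circular correlation by FFT. This makes the fast path *identical* to the
literal double sum at machine precision (verified to <1e−12 relative error at
n = 128), so there is no scale-dependent approximation error to reason about.
The kernel FFTs depend only on (grid, n, Δt) and are cached on the grid
object; a full 99-scale transform of 1200 frames costs ~25 ms and a full
coherence estimate ~60 ms on one CPU.

**Smoothing.** Coherence without smoothing is identically 1 (Cauchy–Schwarz
equality of a single complex product), so the estimator smooths the
s⁻¹-weighted auto- and cross-spectra with a Gaussian in time of sd s/√2
(matched to the Morlet decorrelation time) and a boxcar across scales of 0.6
decorrelation scales (0.6/dj voices, 7 voices at the default dj = 1/12). Both
kernels are normalized to unit mass and renormalized where they overhang the
record edges, so constant fields pass through unchanged. Because numerator
and denominators share identical positive weights, R² ≤ 1 holds exactly up to
floating-point rounding (clipped at [0, 1]; an excursion beyond 1 + 1e−6
raises instead of being hidden). A regression test asserts the degenerate
R² ≡ 1 field when smoothing is disabled.

**Scale grid.** Dyadic: s_j = s₀·2^(j·dj) with s₀ = 2Δt and dj = 1/12 by
default, up to periods of half the record. For Δt = 0.72 s and n = 1200 this
spans periods ~1.49–427 s, covering the 0.02–0.4 Hz analysis bands with ≥12
voices per octave.

**Cone of influence.** A point is trusted at periods shorter than
1.033·(distance to the nearest record edge)/√2, the Morlet e-folding
criterion. Scales whose period exceeds the cone everywhere (periods above
~315 s at 1200 frames) have no trustworthy points and are reported missing,
not zero, by every aggregate.

**Demeaning.** Inputs are demeaned inside `wtc` (not inside `cwt`, which
stays the faithful transform for oracle comparison). With the ratio form of
R², coherence is then exactly invariant to affine rescaling of either input;
a negative gain flips the cross-spectrum phase by π, which the tests pin
down explicitly.

**Phase convention.** Coherence phase is arg(W_physio · conj(W_BOLD)):
+π/2 means the physiological signal leads the BOLD cycle by a quarter
period, −π/2 means BOLD leads. The convention is asserted by a
constructed-lag test rather than assumed, because toolboxes differ in sign.
The four phase categories are half-open quarter-circle arcs
[center − π/4, center + π/4) around 0, π/2, π, −π/2, which partition the
circle exactly; per-category percentages therefore sum to the unsplit
percentage identically.

## Physiological preprocessing

HBI is the inverse of the mean beat-to-beat duration inside a 6 s window
centered on each frame. A duration belongs to a window iff its *midpoint*
falls inside — an unambiguous, symmetric rule. The inverse (rate-like) form
is the default; the plain mean duration is available via `inverse=False`,
and coherence band structure is essentially identical for either monotone
form at physiological fluctuation sizes. Frames whose window contains no
duration are filled with the nearest valid value and flagged (`qc_flags`),
never interpolated: filling cannot invent oscillatory structure, and flags
make the repair auditable. With ~1 s beats and 0.72 s frames, adjacent
windows share roughly 5 of 6 durations, so the HBI series has lag-1
autocorrelation near 5/6 even for white interval jitter — an intrinsic
smoothing of the windowed definition worth remembering when interpreting
high-frequency HBI coherence.

RVT pairs each breath maximum with the following minimum and divides the
amplitude difference by the spacing to the next maximum; values sit at the
maxima and are linearly interpolated to frame centers with boundary values
held. The bellows trace is low-pass filtered (zero-phase 4th-order
Butterworth at 1 Hz) before extrema detection so sensor ripple cannot create
spurious breaths; zero-phase filtering leaves extrema times unshifted.
Strict max/min alternation is enforced by keeping the more extreme of two
same-kind neighbors.

Mean-normalization defaults to subtracting the temporal mean; a
divide-by-mean (percent-change) mode exists because either reading of
"mean-normalized" is defensible. Coherence is invariant to the choice (a
tested property), so nothing downstream depends on it.

## Significance of coherence magnitude

Each signal of a pair is fit separately by Yule–Walker AR(p) (order 1
default, order 9 supported for physiological signals) and `n_boot = 300`
*independent* surrogate pairs are simulated from the two fitted models.
Null R² values are pooled per scale across out-of-cone time points and
across pairs, and the 95th percentile per scale is the threshold. Pooling
across time maximizes the null sample; a per-(scale,time) null would be far
noisier for no benefit since out-of-cone coherence under the null is
time-stationary. Thresholds are computed per signal–network pair, since the
null must inherit that pair's autocorrelation. Simulation starts from the
stationary distribution (AR(1)) or after a 500-sample burn-in.

Calibration (the headline check, also recomputed by
`scripts/acceptance.py`): with φ = 0.5 on both sides, n = 1200, thresholds
from 300 pairs leave 95.0% (mean over scales) of out-of-cone points of 200
fresh independent pairs sub-threshold. Per-scale coverage concentrates in
95 ± 1 percentage points for the bulk of scales; the few coarsest scales
(periods within a factor ~2 of the cone plateau) carry only a handful of
effectively independent wavelet elements per record, so their coverage
estimate has a sampling sd above half a percentage point and the test suite
bounds them by a 3σ envelope (92–98) rather than the ±1 point band.

Phase-shuffled surrogates replace the phases of all interior Fourier bins
with i.i.d. uniform draws, keeping DC and Nyquist untouched, so the
amplitude spectrum is preserved bin-for-bin exactly. Note a structural
caveat: phase randomization destroys coherence with a partner only for
*broadband* shared structure; a shared pure sinusoid survives (it is still a
sinusoid after a phase shift) and remains coherent. The test suite therefore
exercises the surrogate against broadband shared components, which is also
the regime the null is meant for (power-matched control signals).

## Temporal variability of coherence

z(t) = R²(t)·e^{iφ(t)} per scale, over out-of-cone times only; the statistic
is the complex variance ⟨(z−μ_z)(z−μ_z)*⟩ — real, non-negative, zero iff
magnitude and phase are both constant, and invariant to global phase
rotation. Scales with fewer than 8 valid points are reported missing. The
null fits a VAR(1) by ordinary least squares per equation to the demeaned
pair (the estimator and innovation law are free choices here; OLS with
correlated Gaussian innovations from the residual covariance is the standard
one) and simulates `n_boot = 1000` pairs (200 in the scaled-down calibration
suite), flagging scales whose observed variance exceeds the null's 95th
percentile. Unlike the independent-AR null above, this null *preserves* the
pair's stationary cross-dependence — a tested property — so a flag means
"more time-variation than any fixed linear coupling of this strength", not
"any coupling at all". Rank-deficient innovation covariances (e.g. duplicate
inputs) are flagged and simulated via an eigenvalue square root rather than
Cholesky. One caveat shown by the analysis scripts: a deterministic shared
sinusoid is outside the VAR(1) class, so strongly narrowband-coupled pairs
can be flagged at rates above α even when the coupling never switches off;
calibration statements apply to data actually generated by a VAR(1).

## Synthetic data: what it does and does not emulate

The generator reproduces the *acquisition geometry* (1200 frames at
TR 0.72 s, 400 Hz sensor traces, seven network series) and gives exact
ground truth by injecting coupling additively at the frame rate: a shared
sinusoid at a configurable frequency, amplitude (in units of the AR
background's stationary sd), phase lag (positive = physio trails BOLD), and
on/off epochs. Defaults: AR(1) φ = 0.5 for BOLD and 0.3 for physiological
fluctuation profiles with unit innovation sd — autocorrelation levels typical
of network-averaged BOLD at this TR — coupling at 0.1 Hz (inside the low HBI
band) with amplitude ratio 1.0. Pulse waveforms are raised-cosine trains
(only peak times carry information; waveform noise defaults to zero because
event-time recoverability, not morphology, is the generator's contract);
breathing is a fixed 0.25 Hz oscillation whose amplitude tracks the target
RVT profile, keeping RVT fluctuations slow (the profile itself fluctuates at
the AR background's time scale). Per-subject seeds are derived from the
study seed by a fixed prime stride, so studies are byte-reproducible.

Deliberately *not* emulated: hemodynamic response convolution (the estimator
is agnostic to the generative physiology, and additive coupling gives exact
truth), cardiac/respiratory waveform realism, arrhythmias or motion
artifacts, voxelwise structure, and 1/f BOLD backgrounds beyond AR(1).
Passing tests therefore demonstrate that the estimator stack recovers known
band-limited coupling, correct phase direction, and calibrated false-positive
rates — not that real HBI/BOLD coherence has any particular value.

## Problem sizes

The test suite and analysis scripts scale the Monte-Carlo stages to run on a
single CPU in minutes: calibration suites use 400–600-frame records with
dj = 1/8 and 80–300 bootstrap pairs; the full-resolution configuration
(1200 frames, dj = 1/12, 300/1000 bootstrap pairs) is used where the check
is about the full-scale behavior (threshold calibration, phase recovery).
The cohort recovery analysis uses 10 subjects. These sizes are the package's
own validation choices; all of them are plain parameters.
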