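# Methods

## Signal model and demixing

The laminar LFP is treated as a linear, instantaneous mixture of a small
number of spatially stationary sources: `LFP(t) = Σₙ Vₙ sₙ(t)`, where each
source has a fixed depth profile `Vₙ` (its voltage loading) and a time
course `sₙ(t)`.  The assumptions behind this model are the physics of
quasistatic field superposition and the anatomical fixedness of synaptic
input domains; the statistical assumption ICA adds is that the source
strengths are mutually independent and non-Gaussian.

Demixing runs in two steps.  PCA first centres each channel and keeps the
smallest number of components whose cumulative explained variance reaches
`var_frac` (default 0.99).  FastICA (logcosh contrast, whitened, seeded)
then unmixes the retained subspace; the mixing matrix mapped back through
the PCA basis gives the channel-space loadings.  FastICA's fixed-point
iteration routinely stalls on the near-Gaussian sensor-noise components of
the retained subspace, so the implementation retries up to four
deterministic restarts and, if the tolerance is still not met, keeps the
best attempt with a warning (`strict=True` raises instead).  Components
are sign-fixed (largest-magnitude loading entry positive — profile shape
matters, polarity does not), ordered by relative contribution
`Wₙ = ‖Vₙ‖² var(sₙ) / Σₘ ‖Vₘ‖² var(sₘ)`, and the scale ambiguity is
removed per component by reporting `ICₙ(t) = Vₙ(k*) sₙ(t)` at the dominant
electrode `k* = argmax |Vₙ(k)|` (ties to the smaller index).

"Major" components — the analogue of picking the four physiological
components by eye — are selected by excess kurtosis of the time courses:
real sources are bursty and heavy-tailed while retained noise components
stay near-Gaussian, which separates far more reliably than the variance
share (a noise component can out-weigh a weak source).

## Loading geometry

Profiles are compared with the normalized Sobolev-type dissimilarity

    d(Vₙ, Vₘ) = 1 − |⟨Vₙ, Vₘ⟩| / (‖Vₙ‖ ‖Vₘ‖),
    ⟨Vₙ, Vₘ⟩ = ∫_Ω Vₙ Vₘ + κ ∇Vₙ ∇Vₘ + κ² ∇²Vₙ ∇²Vₘ dx,

with κ = 150 µm² weighting the derivative terms at the coarse 150 µm
electrode spacing.  First derivatives use second-order central/one-sided
differences (`np.gradient`, `edge_order=2`); second derivatives use the
central second difference with the second-order one-sided stencil
`(2V₀ − 5V₁ + 4V₂ − V₃)/h²` at the ends, keeping both exact for
quadratics — hence exactly zero curvature terms on affine profiles.  The
integral is the trapezoid rule over the depth span.  Because the discrete
form is a Gram bilinear form with non-negative weights, Cauchy–Schwarz
bounds d in [0, 1] up to floating point (a 1e-12 guard clips the fringe).

Clustering across replicates/animals offers two linkages: Ward with a
Euclidean metric on the Sobolev feature embedding
(√w·V ⊕ √(κw)·∇V ⊕ κ√w·∇²V, whose squared Euclidean norm equals the
inner-product norm), the default, and average linkage directly on the d
matrix.  Loadings are max-normalized (extremum → +1) before clustering
since their scale is an ICA artefact.

The CSD loading is the negative discrete Laplacian
`Iₖ = −σ(Vₖ₋₁ − 2Vₖ + Vₖ₊₁)/h²` at interior electrodes, σ fixed at 1
(arbitrary units).  Volume conduction is flagged by the dimensionless
curvature ratio `‖I‖₂ / (‖V‖₂/h²) < 0.05`; the threshold is calibrated for
clean or averaged profiles (at amplitude SNR 100 the false-negative rate
is ~0) — single-session ICA estimates carry enough curvature noise that
the ratio should be compared across components rather than thresholded.

## Spectra

The Morlet spectrogram convolves (FFT-based, reflect-padded) with
complex atoms of 7 cycles, normalized so a unit-amplitude sinusoid yields
unit ridge power; a cone-of-influence mask marks samples within √2·σ_t of
the edges and is excluded from averages.  The frequency grid defaults to
2–150 Hz in 1 Hz steps.  Longer stretches use Welch's PSD with a
4096-point FFT (Hann, 50% overlap); the integral of the PSD reproduces the
trace variance within a few percent (Parseval check in the tests).
Event-triggered averages compute wavelet power once on the continuous
trace and average only windows fully inside the recording.  Slow-gamma
band power is read at the in-band frequency of maximum power; fast gamma
at a fixed 80 Hz probe.

## Cross-frequency coupling

The theta reference is always the raw-LFP channel with the highest mean
theta-band power — never a component.  Filtering is a zero-phase
windowed-sinc FIR (≈3 cycles of the low band edge, forward–backward);
phase and amplitude come from the Hilbert analytic signal.  The gamma
amplitude envelope is averaged over 18 theta-phase bins, normalized to sum
1, and the modulation index is the normalized KL divergence from uniform,
`MI = (log 18 − H)/log 18`.

Significance uses 200 trial-shuffling surrogates: each surrogate re-pairs
every trial's phase series with a *different* trial's envelope (random
permutation, self-pairings displaced) and recomputes the MI over the full
re-paired session, so the null carries the same sample size — and hence
the same finite-sample entropy bias — as the observed MI.  Both a
normal-fit p and the empirical rank p are reported.  The significance flag
uses the rank p at α = 0.01: at desk-scale trial counts the null MI is
strongly right-skewed (measured skew ≈ 1.8), which makes the normal-fit
flag fire at 3–5% instead of 1%, while the rank flag is calibrated by
construction (minimum attainable p = 1/201).  At the trial counts of a
full experimental session the two flags converge.

Watson–Williams (circular one-way ANOVA, Fisher κ̂ approximation with the
1 + 3/(8κ̂) correction) compares preferred phases between groups; results
carry a validity flag when the pooled mean resultant length is below 0.45.

## Spike–field locking

Spike phases are linear interpolations of the unwrapped Hilbert phase of
the band-filtered component trace at spike times (avoiding
sample-quantization bias).  Locking strength is the mean resultant length
(PLV); uniformity is rejected by the Rayleigh test (Z = NR̄², standard
finite-N tail approximation, cross-checked against pingouin), locked
meaning p < 0.05.  Behavioural-state tables restrict spikes to the hold
([−1000, −500] ms) or pull ([−200, +300] ms) windows around each onset and
require ≥ 50 in-window spikes per unit (configurable).

## Synthetic data

The generator's defaults are the package's study conditions: 8 channels at
depths 400–1450 µm (150 µm spacing, archetype landmarks on-grid), 1 kHz
sampling (all analysis bands < 150 Hz; the acquisition-rate decimation is
left out of scope), 18 trials ~3 s apart, per-channel power SNR 10.

Loadings are closed-form Gaussian-bump archetypes: a non-reversing
superficial profile peaking at 700 µm; a deep profile peaking at 1450 µm
reversing at 1000 µm; a superficial profile (max ≈ 450 µm) with the same
reversal; and an exactly depth-linear volume-conducted profile.  The bump
widths were chosen so that the four archetypes, at the default power
ratios, leave the fourth eigenvalue of the mixture covariance above 1% of
the total — with broader, more collinear profiles the 99%-variance PCA
step truncates the fourth source direction and no ICA can recover it.
Analytic second derivatives are exposed as the oracle for CSD tests.

Time courses sum, per band, a band-limited Gaussian noise carrier
(Butterworth-filtered white noise, unit variance) scaled by the band power
(mV²), a behavioural-state amplitude envelope (hold/pull power gains, pull
window [−200, +300] ms around onset with optional per-band delay and 50 ms
raised-cosine ramps), a unit-RMS lognormal burst envelope (σ = 0.8 on a
250 ms timescale — cortical source amplitudes are lognormal-like, and this
heavy-tailedness is what a maximum-non-Gaussianity ICA exploits; with
Gaussian-envelope carriers the sources are near-Gaussian and demixing
fails), and the theta-phase amplitude modulation
`m(t) = 1 − κ_c + κ_c (1 + cos(θ(t) − φ₀))/2` with coupling depth
κ_c ∈ [0, 1].  One frequency-wandering theta oscillator (4–10 Hz) sets the
modulation phase of every source; its waveform is injected as theta-band
*content* only for sources flagged `theta_coherent` (the volume-conducted
archetype by default, mimicking a distant coherent theta generator) — this
keeps the sources statistically independent while leaving a clean raw-LFP
theta reference for the coupling analysis.  Each source also carries a
slow raised-cosine evoked deflection around pull onset (amplitude, centre
and width per source): this is the trial-locked component visible in
event-triggered averages of real LFPs, and the only part of a source that
survives the 10 Hz low-pass feeding the reservoir — without it the inputs
carry no pull-timing information and the lever cannot be learned.

Spikes are inhomogeneous Poisson with rate
`λ(t) = r·exp(κ cos(φ(t) − φ_pref))/I₀(κ)`, with κ solved from the von
Mises mean-resultant-length relation `A(κ) = I₁/I₀ = PLV_target` (brentq);
targets ≥ 0.999 degenerate to one spike per cycle at the preferred phase.
Generation filters the reference with the same FIR as the analysis side so
generated and measured phases refer to the same band signal.  The lever is
flat (hold) with a raised-cosine pull excursion (rise 200 ms, plateau
100 ms, fall 300 ms) beginning at each onset; onsets violating the 1 s
minimum hold raise.

What the generator does *not* emulate: biophysical forward models,
electrode drift, non-stationary source geometry, 1/f background,
correlated sensor noise (a config option, off by default), spike
waveforms, or reward-related signal differences.  Passing tests therefore
establish that the pipeline recovers the parameters of data satisfying the
model's assumptions — not that real recordings satisfy them.

## Reservoir model

Units follow `τ dxᵢ/dt = −xᵢ + g_G Σ J^{GG} rⱼ + J^{Gz} z + Σ J^{GI} I_µ`
with rectified-tanh rates `r = [tanh x]₊ ∈ [0, 1)`, N_G = 300, τ = 50 ms,
g_G = 1.5, connection probability p = 0.1, explicit Euler at dt = 1 ms
(halving dt changes trajectories by < 1% NRMSE).  Feedback weights are
U(−1, 1); input weights are U(−1, 1) scaled by an input gain (default 2)
on the assigned channel (one random component per neuron, an equal
partition, or a single component for all).

Recurrent weights are Gaussian with standard deviation `weight_sd`
(default 0.6) on the Bernoulli mask.  This parameter deserves its note:
with *rectified* tanh units (roughly half silent at any moment) the
chaotic transition at g_G = 1.5 sits near weight sd ≈ 0.55 — the classical
1/√(pN) scaling leaves the network at a globally attracting fixed point,
while raw unit-variance weights produce chaos too strong for the
unit-range feedback to entrain, and FORCE then diverges.  sd = 0.6 is the
calibrated middle: sustained irregular pre-training activity *and* stable
FORCE learning, which is the behaviour the model is specified by.

FORCE training runs recursive least squares (P initialized to I/α, α = 1,
update every step) on the readout while trials — [−1000, +500] ms segments
around the 18 pull onsets, teaching signal the lever trace mapped to
[−1, 1] (hold → −1) — are concatenated in shuffled order per epoch
(8 epochs default) with 200 ms washouts.  During washouts the readout is
trained toward the hold level: a feedback that merely free-runs between
trials lets the chaos re-emerge and training never converges, whereas the
constant hold-level feedback anchors the inter-trial state.  The same
mapping makes the hold phase a non-zero target, so the feedback loop stays
entrained throughout (a hold-at-zero target provides no feedback drive at
all).  Evaluation rolls the trained network through the trial sequence
with learning off (washout, feedback on, state carried over) and reports
the RMS error normalized by the target's centred RMS (NRMSE).

## Subtype classification

Trial-averaged rates are min–max normalized per neuron (flat neurons are
flagged and classified "others").  Phasic epochs are runs beyond
μ ± 3σ of the baseline (1000–250 ms before onset) lasting more than 60 ms.
Labels apply in the fixed precedence Pre-movement → Post-movement →
Movement-related → Hold-related/Movement-off → Others: Pre-movement is a
positive epoch starting before −500 ms whose activity falls below half its
peak after onset; Post-movement starts at/after onset and is over by
+350 ms; Movement-related is a positive epoch overlapping the movement
window (operationalized as the pull window [−200, +300] ms);
Hold-related/Movement-off (not distinguished) is a phasic *decrease*
overlapping movement.  Note an intrinsic limit of the μ ± 3σ screen: a
clean sustained step that starts before −500 ms contaminates its own
baseline (the elevated fraction exceeds ~10% of the baseline window) and
can never cross the threshold, so Pre-movement labels arise only for
responses with small or gradual baseline contamination.

The activation time is the amplitude-weighted circular mean of response
timing: responses are averaged onto T = 750 two-millisecond bins covering
(−1000, +500] ms (−1000 wraps onto the +500 bin — the segment is circular
with period 1500 ms), and
`t̂ = wrap((T/π)·arg Σ_t' r̄(t') e^{i2πt'/T} − 1000)` into (−1000, +500] ms.
Point masses return their own bin time exactly and circular shifts of the
response shift t̂ correspondingly.

## Problem sizes

Defaults throughout are the study conditions above.  The bundled
verification runs use: ten synthetic animals (≈55 s each) for the
clustering check; 500 uncoupled sessions of 24 trials at 500 Hz for the
surrogate false-positive rate; 600 s single-source sessions for PLV
recovery; and the full 18-trial, 300-unit reservoir experiment for all
five input conditions.
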