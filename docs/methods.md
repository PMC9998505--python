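# Methods

This note documents the models, parameter choices and numerical decisions
behind `hdotools`, and what the synthetic validation does and does not
establish about real data.

## Signal model

A region-level fMRI time course is modelled as

    y(t) = B + drift(t) + hdo(t) + resp(t) + bold(t) + ε(t)

with baseline `B` (default 100 arbitrary units), Legendre-polynomial drift
up to `drift_order` with independent Gaussian coefficients (`drift_sd`,
default 1 unit ≈ 1% of baseline), white scanner noise `ε` (`noise_sd`,
default 1% of baseline), and optional narrowband and task components.

**HDO component.** Vasomotion appears in spectra as a Gaussian peak of
center `f_o ≈ 0.20 Hz` and width `σ ≈ 0.025 Hz`. The generator realizes it
as a sinusoid with slow Ornstein–Uhlenbeck frequency and amplitude drift:
the instantaneous frequency is `f_o + δ(t)` with `δ` an OU process
(correlation time 30 s, long against the 5-s oscillation period, so the
line shape is set by the frequency excursions), and the amplitude is
modulated by `1 + OU` (std 0.2, correlation time 60 s, floored at 0). The
OU standard deviation is `bandwidth / √2`: the amplitude spectrum is the
square root of the power spectrum, which widens a Gaussian line by √2, so
this calibration makes the *fitted* EGF σ equal `bandwidth`. Verified by
simulation: over 20 seeds the median fitted σ/bandwidth ratio is 0.93.
`bandwidth = 0` gives a pure sinusoid. The oscillation amplitude in real
data is not established; the defaults (2–6% of baseline against 1% noise)
are generator parameters, not claims about physiology.

**Respiration confound.** A narrowband component at 0.9 Hz (bandwidth
0.02 Hz). At a 1-s TR it aliases to ~0.1 Hz — the lower edge of the
feature interval — which is precisely why the detector must be trained
with it present.

**Stimulus locking.** With `phase_locking`, the oscillation phase is reset
at each stimulus onset and its amplitude is zeroed for one period,
emulating the brief interruption of vasomotion by stimulus-evoked
vasodilation.

**BOLD component.** Boxcar convolved with a double-gamma rat HRF: positive
lobe peaking at 2.8 s (gamma scale 0.6 s), undershoot peaking at 7 s with
relative amplitude 0.35. These are configuration (`HRFParams`), shared
between the generator and the GLM design matrix; rodent HRFs vary with
anesthesia and strain, and no single parameterization is canonical.

**Determinism and linearity.** Every component draws from its own child
stream of the recipe seed, so outputs are bit-reproducible and the full
signal equals the sum of its separately generated components under a
shared seed.

## Spectral characterization

Spectra are one-sided amplitude spectra of the mean-removed signal, scaled
2/N so a unit sinusoid at a bin frequency has amplitude 1. Amplitude (not
power) is used throughout: the attenuation ratio of the suppression stage
and the detector features then live on the same scale.

**Peak screening** (`screen_peak`) smooths the 0.08–0.8 Hz interval with a
0.0125-Hz boxcar (half a typical peak width), detrends it linearly, and
asks for a local maximum with prominence above 12× the median absolute
deviation of the result. The threshold was calibrated by Monte-Carlo on
white-noise spectra: at 12×MAD the false-positive rate is ≤ 2/100 across
sampling intervals 0.1–1 s, while ≥ 2%-amplitude oscillations are retained.
(Prominence thresholds of a few MAD flag essentially every white-noise
spectrum once the bin count is in the hundreds, so the conventional "3×"
heuristic is not usable here.)

**EGF fitting** is bounded nonlinear least squares over 0.01–1 Hz
(`c ≥ 0`, `σ ∈ [df, 0.2 Hz]`; `d` and `f_o` deliberately unconstrained so
unphysiological fits are visible). Initialization is staged: a robust
(soft-L1) exponential-background fit locates the peak on the
background-subtracted residual — a raw spectrum argmax picks the interval
edge whenever the 1/f background dominates — then the background is
refitted with the peak region masked, and the Gaussian is initialized from
the residual height and half-width. Five jittered restarts from a fixed
seed guard against local minima. On noiseless EGF-generated spectra all
six parameters are recovered to better than 1e-4 relative; with 5%
multiplicative noise the median peak-frequency error is ≪ σ/2. Fits with
`d ≤ 0` or `f_o ≤ 0` are flagged unphysiological and excluded from the
consensus average of `f_o` and `σ`, which fixes the band intervals
(stopband ±σ, passband edges ±3σ, feature interval ±4σ).

## Detection

Features: 17 spectral values (detrended interval, block-averaged onto a
σ/2 grid anchored at `f_o − 4σ`; grid points that receive no FFT bin on
coarse spectra are filled by linear interpolation) and 5 autocorrelation
values (biased, N-normalized autocorrelation of the 1-s resampled course
at lags 1–15 s, linearly detrended over lag, averaged in the groups
{1,6,11}…{5,10,15}). The grouping reading — five groups of three lags 5 s
apart — preserves one oscillation period of phase information; for a 5-s
periodic signal the three members of each group sit at the same phase and
the group means trace one period while noise averages out. The spectral
branch uses the full-resolution course; only the autocorrelation branch is
resampled to 1 s, so lags are exactly integer seconds.

Classifier: a single-hidden-layer perceptron (8 tanh units, logistic
output) on standardized features, trained with L-BFGS from a fixed seed —
the smallest architecture that separates the 22-dimensional features
reliably and reproducibly. Scoring uses an explicit numpy forward pass so
a JSON-serialized model reproduces its scores bit-exactly. The decision
threshold is fixed at 0.5. The shipped training set is synthetic
(113 oscillatory / 113 clean courses with randomized frequency, width,
amplitude, drift and respiration); on a held-out synthetic benchmark the
detector reaches specificity ≥ 0.95. That figure validates the
implementation against the generator's ground truth — real scanner data
with manual labels would be needed to state a specificity for any
particular acquisition protocol.

## Suppression

The bandstop FIR is designed by weighted least squares (`scipy.signal.firls`)
with the stopband gain set from the adaptive attenuation estimate and the
tap count grown from 31 in steps of 20 until the evaluated response keeps
passband ripple within 1% and reaches the requested stopband gain (the
design target is 15% deeper in dB than requested so the realized response
meets it with margin). Attenuations below 0.5 dB return an identity
filter.

The attenuation estimate is `20·log10(peak / baseline)` on the 17-block
downsampled interval, floored at 0 dB, with the peak taken as the maximum
over the stopband blocks (`|f − f_o| ≤ σ`, where the peak lies by
construction) and the baseline as the median over the blocks outside the
transition region (`|f − f_o| > 3σ`). Measuring the baseline where neither
the peak nor a previous filtering pass can reach keeps the estimate near
0 dB on peak-free and already-suppressed courses. On white noise the
estimate has mean ~1.7 dB and stays below ~4 dB; estimates below a 6-dB
floor (the upper edge of that peak-free sampling distribution) skip
filtering entirely. This makes suppression idempotent in practice and
leaves non-oscillating courses untouched.

"Double filtering" is two forward passes of the same linear-phase filter
with reflection padding (one filter length) and group-delay compensation,
doubling the stopband attenuation in dB while keeping the output
sample-aligned; a forward–backward (`filtfilt`) mode is available via
`mode="zero_phase"`.

## GLM impact

The design matrix holds three task regressors — boxcar ⊛ HRF, its temporal
derivative (0.1-s shift quotient) and its dispersion derivative (central
difference on the gamma scale) — computed on a 16× oversampled grid,
bin-averaged to the scan grid, mean-centered, and sequentially
orthogonalized against the preceding task columns (the usual convention,
which also keeps the basis well-conditioned); nuisance columns are a
Legendre drift basis (default order 1; the original analyses' drift model
inside SPM is unspecified, so the order is configuration). The omnibus
F-test compares the full model against the drift-only model,
`dof = (3, n − p)`.

Family-wise error control is Bonferroni over in-mask voxels — deliberately
simpler and more conservative than random-field theory, and exactly
specifiable; under a white-noise null the realized FWE rate is ~4–5% at
α = 0.05. Clusters are face-connected components of suprathreshold voxels.
Impact ratios (suppressed/original cluster size and maximum F) are
compared between oscillatory and non-oscillatory cohorts with two-sided
Mann–Whitney U tests, Bonferroni-corrected for the two endpoints.
Datasets qualify only with more than 12 and at most 100 activated voxels
in the original map.

## Network-based statistics

Preprocessing: in-plane Gaussian smoothing (0.6 mm FWHM at 0.35 mm pixels),
hard Fourier lowpass at 0.3 Hz, voxel-wise regression of the global
in-brain mean, region extraction. Pearson matrices keep only positive
coefficients (negatives zeroed); group averaging is entrywise
Fisher-z → mean → tanh with |r| clipped to 1 − 1e-7 before `artanh`.

The NBS contrast selects the 140 strongest connections of the Fisher-z
average pooled over *both* conditions (pooling avoids biasing the edge set
toward either condition), runs a two-sided paired t-test per edge on the
Fisher-z differences, retains the largest connected component (counted in
edges) of suprathreshold (p < 0.05) edges, and calibrates its size against
1000 sign-flip permutations of the per-pair differences:
`p_corr = (1 + #{perm max ≥ observed}) / (n_perm + 1)`. The MDCC is the
mean of `r_suppressed − r_unsuppressed` over the significant edges and all
pairs, reported signed with its absolute value alongside.

A caveat inherent to paired permutation tests at small n: with 9 pairs
there are only 512 distinct sign patterns, and near-aligned patterns
partially resurrect a true effect in the permutation null. For a compact
6-edge altered component at a per-edge paired effect size of d = 2 the
corrected p therefore concentrates around 0.01–0.1 rather than collapsing
toward the 1/(K+1) floor; detecting such an effect at p < 0.05 is
intrinsically marginal at this sample size, whereas spatially broader
effects (as in real suppressed-vs-unsuppressed contrasts, where dozens of
edges change) are detected comfortably. The synthetic connectivity
benchmark (`connectivity_benchmark`) plants exactly this compact
worst case.

## Problem sizes used in validation

The test suite and acceptance script validate on 600-s courses at 0.1–1 s
sampling, 226-course training sets, 100-course evaluation sets, 5×5×1 to
10×10×1 voxel grids, 28-region networks with 9 pairs, 500 null activation
maps and 200 null NBS runs with 1000 permutations each — sizes chosen to
match the scan durations, region counts and cohort sizes typical of the
rodent experiments the package targets while keeping the whole validation
runnable on a laptop in minutes.

## Known limitations

* The generator produces stationary Gaussian noise without MR physics
  (no motion, spikes, multi-slice timing, susceptibility dropout); passing
  synthetic benchmarks bounds algorithmic correctness, not robustness to
  artifacts absent from the model.
* The shipped detector is trained on synthetic data; applying it to real
  scans should start from features extracted with a band fitted to that
  cohort and, ideally, retraining on manually labelled courses.
* Bonferroni FWE is conservative relative to random-field or
  permutation-based voxel thresholds; absolute cluster sizes are therefore
  smaller than an SPM-style analysis would report, while suppressed/original
  ratios are comparatively insensitive to the threshold choice.
* Atlas registration, realignment and masking are out of scope; region
  extraction assumes a label volume already in register with the data.
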