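# hdotools

Detection, characterization and suppression of vasomotion-induced
**hemodynamic oscillations (HDO)** in rodent fMRI time courses.

Under vasoconstrictive sedation (e.g. medetomidine), rhythmic oscillation of
blood-vessel diameter — vasomotion — imprints a narrowband ~0.2 Hz
oscillation on BOLD fMRI signals. These oscillations are physiological
noise: they inflate or distort GLM activation statistics and bias
functional-connectivity estimates. `hdotools` provides the full analysis
chain for anyone working with small-animal fMRI:

* **characterize** the oscillation by fitting an exponential-Gaussian
  function (EGF) to the amplitude spectrum,

  `EGF(f) = a + b·exp(−c·f) + d·exp(−(f − f_o)² / 2σ²)`

  where `f_o` is the oscillation frequency (~0.20 Hz) and `σ` the spectral
  peak width (~0.025 Hz);
* **detect** HDO per time course with a small neural-network classifier on
  22 features: the linearly detrended amplitude spectrum over
  `[f_o − 4σ, f_o + 4σ]` downsampled to resolution `σ/2` (17 values), plus
  the autocorrelation at 1–15 s lags, detrended and phase-averaged in five
  groups of lags 5 s apart (5 values);
* **suppress** HDO with an adaptive linear-phase FIR bandstop filter
  (stopband `[f_o − σ, f_o + σ]`, passband resuming outside
  `[f_o − 3σ, f_o + 3σ]`), whose depth is set per course from its own
  spectral peak-to-baseline ratio and which is applied twice
  ("double filtering");
* **quantify the impact** of suppression on downstream analyses: omnibus
  F-test activation mapping with a 3rd-order rat-HRF basis set
  (cluster sizes, maximum F, Mann–Whitney group comparison) and
  network-based statistics (NBS) on 28-region Pearson connectivity
  matrices (paired t-tests on the 140 strongest connections, largest
  suprathreshold component, sign-flip permutation correction, mean
  difference of correlation coefficients);
* **simulate** all of the above: a synthetic generator produces time
  courses with baseline drift, scanner noise, narrowband respiration,
  BOLD responses through a configurable rat HRF, and an HDO component with
  a calibrated Gaussian spectral line shape — the ground truth every other
  module is validated against.

## Worked example

```python
from hdotools import (SignalRecipe, OscillationSpec, simulate_time_course,
                      compute_spectrum, screen_peak, fit_egf, consensus_band,
                      benchmark_courses, extract_features, train_detector,
                      detect, suppress, estimate_attenuation)

# a 10-min course at 0.5-s TR with a 3%-amplitude HDO at 0.20 Hz
recipe = SignalRecipe(duration=600, dt=0.5, drift_order=1,
                      hdo=OscillationSpec(freq=0.20, bandwidth=0.025,
                                          amplitude=3.0),
                      seed=42)
tc = simulate_time_course(recipe)

spec = compute_spectrum(tc)
print(screen_peak(spec))             # True  -> a peak in 0.08-0.8 Hz
model = fit_egf(spec)                # f_o = 0.205 Hz, sigma = 0.0161 Hz
band = consensus_band([model])       # stopband (0.189, 0.221) Hz
print(estimate_attenuation(tc, band))  # 20.6 dB

courses, labels = benchmark_courses(113, 113, seed=2026)
det = train_detector([extract_features(c, band) for c in courses],
                     labels, seed=7)  # CV accuracy 0.960
print(detect(tc, det))               # {'oscillatory': True,  'score': 1.000}
print(detect(suppress(tc, band), det))
                                     # {'oscillatory': False, 'score': 0.000}
```

The fitted `f_o` of 0.205 Hz recovers the generated 0.20 Hz oscillation;
the adaptive filter depth of ~21 dB reflects the ~10× peak-to-baseline
ratio of this course; after suppression the same detector scores the
course as clean.

The same workflow is available from the shell:

```bash
hdo simulate --out ds/ --seed 3 --n-regions 14 --n-oscillatory 5
hdo fit-frequency --in ds/R01.csv --in ds/R02.csv --out band.json
hdo train --synthetic 226 --seed 0 --out model.json
hdo detect --in ds/R01.csv --model model.json
hdo suppress --in ds/R01.csv --band band.json --out clean.csv
hdo run --out results/ --seed 0     # full characterize-then-suppress pipeline
```

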