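# Methods

## Physical model

A tooth measured in a two-electrode electrochemical cell behaves, over
0.1 Hz–10 kHz, like a first-order system: resistive at high frequency,
capacitive at low frequency.  `dentaleis` models it as a series resistance
`R1` (electrolyte plus tooth–electrode interface) feeding a parallel pair of
a charge-transfer resistance `R2` and a constant-phase element (CPE):

    Z(f) = R1 + R2·Z_CPE / (R2 + Z_CPE),   Z_CPE = 1 / ((j·2πf)^N · Q)

The CPE generalizes an ideal double-layer capacitor (`N = 1`) to the
distributed, porous interfaces seen on enamel; fitted `N` values on teeth are
near 0.8.  Demineralization dissolves hydroxyapatite, opens pores that fill
with ion-rich fluid, and thereby shifts all element values and — most
usefully — the impedance phase in the low tens of Hz.  The class-center
element values shipped as `ND_PARAMS` / `DM_PARAMS` are the published fitted
values for sound and demineralized enamel:

|        | sound (ND) | demineralized (DM) |
|--------|-----------:|-------------------:|
| R1 (Ω) | 3.9×10³    | 7.5×10⁴            |
| R2 (Ω) | 2.6×10⁷    | 3.4×10⁷            |
| Q (s^N/Ω) | 3.3×10⁻⁷ | 2.1×10⁻⁷          |
| N      | 0.81       | 0.86               |

At 15 Hz these centers give phases of ≈70° (ND) and ≈44° (DM) in the
positive-degrees convention.  Note one internal tension in the source data:
the tabulated R1 is *larger* after demineralization, while the narrative
description of the spectra reports a high-frequency magnitude *decrease*.
The package uses the tabulated values exactly as printed; the 15 Hz phase
separation that the classifiers rely on holds either way.

**Sign convention.**  Impedance is a true complex number internally
(capacitive ⇒ negative imaginary part).  Every user-facing phase — the
classifier input, CSV files, meter output — is the positive magnitude in
degrees, which is how dental impedance phases are quoted.

**Acquisition grid.**  The standard grid is 10^(k/5) Hz for k = −5…20:
0.1 Hz to 10 kHz at five points per decade, endpoints inclusive, 26 points.
15 Hz is not a grid point (neighbours 10.0 and 15.85 Hz), so
`phase_at_frequency` interpolates linearly in log₁₀(f); the circuit's phase
is smooth on a log axis and the interpolation error at 15 Hz is below 0.5°.

## CNLS fitting

`fit_spectrum` minimizes Σ_f w_f·|Z_meas − Z_model|² with the real and
imaginary residuals stacked.  Choices that matter:

- **Modulus weighting** `w = 1/|Z|²` by default.  Tooth spectra span ~4
  decades of magnitude; unweighted least squares would fit only the
  low-frequency end.  Unit weighting remains available (and is what the
  unit-rescaling covariance test uses).
- **Log-space parameters** for R1, R2, Q: enforces positivity and conditions
  the optimizer across the 10³–10⁷ Ω range; N is bounded in (0.05, 1].
- **Initialization**: R1 from the high-frequency magnitude, R1+R2 from the
  low-frequency magnitude (R2 floored when the spectrum is flat), N = 0.8,
  Q placed so the CPE shoulder sits at the most-capacitive measured
  frequency.  Five additional multistart points with ±50% log-uniform jitter
  (seeded, default 0) guard against local minima.
- **Convergence**: scipy `least_squares` (trust-region reflective) with
  xtol = ftol = gtol = 1e-14.  Non-convergence is reported in the result,
  not raised.

On noiseless synthetic spectra the round trip recovers all four parameters to
machine precision; the test suite asserts < 0.5% on 50 random draws within a
factor of 10 of the class centers, and < 0.1% on the class centers
themselves.  Note that for parameter draws whose time constant pushes the
low-frequency plateau far below 0.1 Hz, R2 is identified only through the
curvature of the available decades — exact on noiseless data, but
increasingly noise-sensitive on real spectra (the noisy-recovery test
asserts a 10% median error on R2 at 2% magnitude / 1° phase noise).

## Synthetic data generator

The generator defines the study conditions for every statistical claim the
tests make.  Per class, circuit parameters are drawn log-normally around the
class center with geometric SD 1.6 for R1, R2, Q and Gaussian SD 0.04 for N
(clipped to (0, 1]).  These spreads were chosen so that the classes overlap
slightly in parameter space — the classifiers should be good but imperfect,
matching accuracies in the high-0.8s rather than 1.0 — while the 15 Hz phase
still separates the classes most of the time.  Each tooth yields three
replicate spectra with 2% relative magnitude noise and 1° additive phase
noise per point, emulating visibly tight measurement triplicates.

What the generator does **not** emulate: demineralization kinetics, pH and
exposure-time effects, tooth-geometry and contact-pressure variation,
electrode drift, autoranging artifacts, or any correlation between element
values within a tooth.  Passing tests therefore demonstrate that the
pipeline is correct and well-behaved under the assumed statistical
structure; they do not certify clinical performance on measured teeth.

The default dataset size is 12 teeth per class (a balanced 24-sample set,
the size of the published test set); the MLP tests use 40 per class so a
70/30 split leaves 24 test teeth.

## Single-neuron classifier

`demineralization_index(phase) = 100 / (1 + exp(G·(W·phase − IB)))`, an
inverted (decreasing) sigmoid: high phase ⇒ sound ⇒ index near 0%.  The
functional form was chosen so that with W = 1 the bias IB is exactly the 50%
midpoint on the phase axis, which is what makes its statistical derivation
meaningful: `calibrate` sets IB = mean(DM phases) + 1.5·SD(DM phases)
(sample SD over per-tooth replicate-averaged phases), so the boundary sits
just above virtually the whole demineralized population.  Defaults IB = 65,
W = 1, G = 2, threshold 50%, f₀ = 15 Hz.  G is selected from a small grid by
training error with ties going to the smaller (smoother) gain.  An index
exactly at the threshold classifies as DM — in screening, a borderline tooth
should be flagged.

## MLP classifier

Inputs are the fitted (R1, R2, Q) per tooth — N is excluded by default
because its variation is small and weakly class-related, and including it
does not improve cross-validated accuracy (asserted ≤ +0.02 on seeded runs).
Features are min–max normalized using **training-set extremes only**; test
values may fall outside [0, 1] and are never clipped.  The network is
scikit-learn's `MLPClassifier` with hidden layers (3, 2), tanh activations, a
single logistic output (probability of DM, enabling the ROC), L-BFGS solver,
L2 penalty 1e-4, max_iter 2000, fixed seed.  A quoted "adaptive learning
rate α = 1e-4" cannot apply to L-BFGS (which has no learning rate); it is
treated as a reporting artifact and only the L2 penalty of that magnitude is
used.  Splits are stratified and grouped at the tooth level (replicates never
straddle train/test), 70/30 by default, with stratified 5-fold
cross-validation reporting per-split accuracy, recall and AUC.

## Phase-meter emulation

The portable meter measures impedance at one frequency (1–100 Hz): stimulus
v(t) = 10 mV·sin(2πf₀t), exact circuit current, trans-impedance gain
(default 1.4×10⁷ V/A) and stimulus buffer gain (default 100 V/V) chosen so
the 77–500 kΩ tooth/validation range stays on the 4.096 V unipolar 16-bit
ADC without clipping, additive Gaussian noise (default 2 mV at each ADC
input), midscale offset, quantization.  Both channels are fitted with a
**four-parameter sine fit** (amplitude, phase, frequency, offset; frequency
free because the stimulus generator's clock is not trusted), initialized
from the fixed-frequency linear least-squares solution; a fit model rejects
residual PWM harmonics by construction.  Z = V̂/Î per repeat; ten repeats are
averaged (phase SD reported).  The analog PWM + low-pass stimulus chain is
represented by an ideal sine plus optional odd harmonics at a configurable
level, not by a filter model — the algorithmic content is the sine fit, not
the electronics.  Defaults: fs = 10 kHz, 1 s records (15 cycles at 15 Hz).

Under these defaults the emulated meter's phase error stays below 0.6° on
pure resistors and below 2° on R‖C pairs across 100–500 kΩ (18.2 nF fixed),
the bounds reported for the hardware prototype; quantization alone
contributes < 0.05°, and repeat-averaging follows the expected 1/√n law.

## Metrics

DM is the positive class everywhere, so recall is sensitivity to
demineralization.  `scores` returns NaN with an `undefined` flag for
zero-denominator ratios.  `roc_auc` sweeps unique score thresholds (ties
grouped into single steps) and integrates by the trapezoidal rule; this is
algebraically identical to the Mann–Whitney pair-counting statistic with
ties half-weighted, and the tests assert equality to 1e-12 against an
independent pair-counting oracle on 200 random score/label sets.  On a
balanced 24-sample set, enumeration over all confusion matrices with 12
positives and 12 negatives shows (tp=11, fn=1, tn=10, fp=2) is the unique
matrix consistent with the published single-neuron score set rounded to two
decimals; the metrics tests freeze that enumeration.

## Problem sizes and numerical choices

Test and acceptance runs use 26-point spectra, 24–80-tooth synthetic
datasets, 50-draw fit-recovery sweeps, 100-trial sine-fit Monte Carlo and
25-seed averaging studies — sizes at which every property asserted is stable
across seeds while the whole suite runs in well under a minute.  All
randomness flows through `numpy.random.default_rng` with explicit seeds;
datasets record generating parameters (provenance) sufficient to recompute
every spectrum.

## Known limitations

- R1 is not decomposed into solution and interface contributions; they are
  not separately identifiable from a single spectrum.
- One circuit topology only; no automatic model selection.
- The published classification scores were measured on ~100 real tooth
  spectra that are not deposited; this package reproduces the methods and
  their synthetic-data analogs, not those exact numbers.
- The generator's parameter draws are independent across elements; real
  teeth likely show correlated element shifts.
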