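# Methods

This note documents the models, algorithms and numerical choices behind
`endofluct`, and what the synthetic validation does and does not establish.

## 1. Choice models

Offers pit a 50/50 gamble (prize *g* ∈ {6, 9, 12}, otherwise 0) against a
safe amount *s*. Utilities are power functions, `U_g = 0.5 g^α`,
`U_c = s^α`, and the gamble is chosen with probability
`P = expit(μ (U_g − U_c + κ))`. Parameters and fitting bounds:

| parameter | meaning | bounds | typical |
|---|---|---|---|
| α | utility curvature (risk aversion; 1 = neutral) | (0.01, 3] | 0.9 |
| μ | inverse temperature (choice determinism) | (10⁻³, 50] | 3 |
| κ | additive gambling bias, in utility units | [−5, 5] | ±0.2 |

The registry ships the base model (`pt`, κ ≡ 0), the gambling-bias model
(`pt_kappa`), and two *non-canonical placeholder* alternatives that keep the
model-comparison machinery exercised: a multiplicative bias on the softmax
slope (`pt_kappa_mult`, μ_eff = μ·e^κ) and a dual-curvature model with
separate exponents below/above £9 (`pt_dual_alpha`). The placeholders make
no claim of fidelity to any particular published alternative.

**Estimation.** The Bernoulli negative log-likelihood is computed through
the softplus identity (overflow-safe); missed trials (NaN choice) are
excluded. Fitting is bounded multi-start L-BFGS-B (default 20 starts: the
box midpoint plus a seeded Latin-hypercube sample), with analytic gradients
for `pt`/`pt_kappa` and `ftol = 1e-10`. Simulation studies inside the test
suite use fewer starts (4–10); with only 2–3 bounded parameters and
Latin-hypercube coverage this reliably reaches the same optimum. Fit
quality is summarised by McFadden-style pseudo-R² against a coin-flip null,
`1 − LL/(n ln ½)`, and `BIC = k ln n − 2 LL`.

Per-condition fits estimate all three parameters independently in the low-
and high-activity trial subsets; paired differences across subjects feed
group t tests. With 45 trials per condition the (α, μ, κ) likelihood
surface is shallow — individual fits can wander within the bounds — but the
group-level κ contrast is recovered reliably. An optional pseudo-R²
screen (`min_pseudo_r2` in `fit_cohort_by_condition`) excludes
poorly identified subjects, mirroring fit-quality exclusions common in this
literature.

**Identifiability of κ.** A constant κ offset is partially absorbable by
α and μ within a single data set, so single-subject BIC comparisons favour
the κ model only weakly. Model selection is therefore done at the group
level (BIC summed over subjects), where the consistent per-subject
likelihood gain dominates the per-subject penalty; with 43 subjects × 90
trials and κ = 0.4 the κ model is selected essentially always, and base-model
data select the base model.

## 2. Task design

Calibration sessions form the full factorial of 3 prizes × 12 divisors
(0.82 … 3.5) applied to the gamble's expected value (`certain_amount`,
rounded half-up to £0.01), repeated 5 (day 1, 180 trials) or 3 (day 2,
108 trials) times in a seeded shuffle.

For the triggered session, the fitted *base* model is inverted: for a
target gamble probability *p*, `U_c = U_g + κ − ln(p/(1−p))/μ`, mapped to
money by `U_c^(1/α)`, rounded to pennies and clipped to (£0.01, gain −
£0.01) with a clipping flag. Five probability bins (0.3–0.7 for group 1,
0.1–0.9 for group 2) × 6 repeats per gain give 90 trials; each (gain, safe)
cell is split 3/3 between low and high condition slots so both conditions
face identical offer multisets.

## 3. Real-time trigger

The trigger keeps the last 71 samples: the 69-volume window and the 2 most
recent volumes being tested (the window *excludes* the recent samples).
The recent mean *m* is mapped to a percentile `Φ((m − μ_w)/σ_w)` with the
sample SD (n−1); a numerically degenerate window (σ_w below 1e-12 relative
tolerance) maps to 0.5. Percentiles ≤ 0.15 / ≥ 0.85 (closed bounds, for
floating-point robustness) trigger low/high trials after a 20 s minimum
ITI; at ≥ 55 s without a trigger, a trial is forced and labelled by whether
*m* sits below or above μ_w. The ITI clock starts when the warm-up window
first fills, is anchored to option presentations, and the trigger is
evaluated every volume. Offline replay (`run_session`) is exactly the
iterated online rule.

Note a structural property of this windowing rule: because *m* averages 2
volumes but is ranked against the distribution of *single* volumes, the
low-tail rate for white-noise input is `Φ(√2 Φ⁻¹(0.15)) ≈ 0.07`, not 0.15;
with realistically autocorrelated BOLD input the rate moves back toward
0.15. The implementation keeps the rule unchanged.

Real-time denoising is modelled as expanding-window least squares
(`IncrementalNuisanceRegressor`): accumulated normal equations, solved
exactly each step (minimum-norm via pseudo-inverse when collinear, with a
`rank_deficient` flag once more samples than parameters have been seen).
After a full pass the coefficients equal the batch solution.

## 4. Synthetic data generator

The generator defines the study conditions used by all validation:

* **Endogenous BOLD** — AR(1) innovations (SD 1, φ = 0.8, 200-sample
  burn-in) around a raw mean of 100, plus slow drift: 3 seeded cosines with
  periods 100–600 s (below 0.01 Hz) and amplitudes ~drift_amplitude/3.
  The raw mean exists so that percent signal change is well defined; 1 raw
  unit ≈ 1 % signal change.
* **Sessions** — 1800 volumes at TR 1.75 s (~52 min), long enough for the
  trigger to schedule ~90 trials; with these settings ~4 % of trials are
  forced (real recordings, with different temporal structure, tend to force
  trials more often).
* **Evoked responses** — a canonical double-gamma HRF (modes exactly at 6 s
  and 16 s, undershoot amplitude 1/6 of the unit peak) scaled per trial by
  `base + slope·(percentile − 0.5) + ε`, with base 1.0, slope −1.0
  (negative: smaller responses on high-activity trials) and independent
  trial-to-trial amplitude noise ε ~ N(0, 0.5) — trial-wise phasic
  variability comparable to half the mean response, typical of
  event-related BOLD.
* **Choices** — the per-trial gambling bias follows the *realized* evoked
  amplitude, linearly rescaled so that its condition means equal κ_low and
  κ_high (defaults +0.2/−0.2, i.e. a 0.4 contrast). This routes the
  condition effect through the phasic response, so the mediation pathway
  (prestimulus level → evoked response → choice) is genuinely present in
  the generative model rather than mimicked by two parallel condition
  effects; conditional on the prestimulus level the response still carries
  choice information. Per-condition model fits recover the κ contrast in
  expectation.
* **RTs** — log-normal with σ_log = 0.3 and condition-specific arithmetic
  means (1.72 s low, 1.67 s high).
* **Subjects** — parameters jittered per subject (Gaussian, SD 10 % of the
  value, truncated to validity); all per-subject and per-stage seeds derive
  deterministically from the master seed via `SeedSequence`.

What the generator does **not** emulate: volumetric images, motion and
physiological artifacts, condition-specific RT–difficulty coupling,
non-stationary noise variance, and the serial dependence between the
trigger's selection and the evoked noise (epochs inherit genuine
mean-reversion after extreme baselines, which the analyses must tolerate —
see below). Passing tests therefore demonstrate the *machinery* is correct
and well calibrated under realistic desk-scale conditions, not that the
biological effect sizes are right.

## 5. Evoked-response statistics

Epochs are 8 volumes (0–12.25 s) from option onset. Percent signal change
is computed per trial against the mean of the first 2 volumes at/after
onset (trials with non-positive baseline are flagged invalid); the epoch
summary is the mean PSC over the closed 5.25–10.5 s window (samples 3–6 at
TR 1.75 s). Because low-activity trials are *selected* for extreme
baselines, mean reversion of the endogenous process adds to the genuine
evoked difference; this is a property of the design itself, not an
artifact of the implementation.

**Cluster permutation test.** Paired t statistics per timepoint; clusters
are maximal sign-consistent runs with |t| ≥ 2; the null is the maximum
cluster statistic under seeded per-subject sign flips of the difference
time courses, with `p = (1 + #null ≥ obs)/(1 + B)` (default B = 5000 in the
config; pipeline runs use 1000). The default cluster statistic is extent
(run length), with summed |t| ("mass") behind a flag. The observed and
null statistics are computed identically (both split clusters at sign
changes). The extent statistic is integer-valued and therefore
*conservative* at short epoch lengths — the critical extent's null
probability falls strictly below α, so its family-wise error rate sits
around 0.02–0.03 at nominal 0.05; the continuous mass statistic calibrates
at the nominal rate. On the pipeline's own 8-point epochs, where
per-subject difference courses are strongly correlated across timepoints,
the max-extent null is nearly bimodal and extent p-values cannot fall much
below ~0.03; the pipeline therefore judges the directional evoked contrast
by the paired t on the 5.25–10.5 s epoch average and reports the cluster
test alongside.

**Mediation.** Two-stage summary statistics: per subject, path a from the
linear fit m ~ x, paths b and c′ from a logistic fit y ~ m + x, path c
from y ~ x (a linear y-stage variant, for which c = c′ + a·b holds exactly
per subject, is available); at the group level, one-sample t tests on the
per-subject coefficients, with the indirect effect as the mean of
per-subject a·b and a percentile CI from resampling subjects with
replacement (seeded). Subjects with degenerate variance or failed/separated
logistic fits are dropped with a warning; fewer than 3 usable subjects is
an error. This is a deliberately transparent two-stage estimator, not a
joint hierarchical model: no shrinkage, and the CI treats subjects as the
sole resampling unit. In the pipeline, x is the prestimulus percentile, m
the epoch-average PSC and y the choice; "supported mediation" means the
indirect CI excludes 0 with sign consistent with the total effect (both
negative in percentile units: higher baseline → smaller response → fewer
gambles).

**Behavioral summaries.** Per-subject gamble rates and RT means by
condition with paired t tests; per-subject equal-size quantile bins of the
objective value difference `0.5·gain − safe` (default 5 bins, computed
across both conditions so each bin probes the same offers in both states);
Spearman (midrank ties) and Pearson susceptibility correlations; and a
per-subject OLS of RT on prestimulus percentile, choice, and |ΔSV| from the
subject's fitted parameters, with group t tests on the coefficients
(rank-deficient subject designs are dropped, or raised for single-subject
input).

## 6. Pipeline defaults and problem sizes

`run_all` simulates 43 subjects (the study-scale cohort), fits
per-condition and pooled models (10 starts), and runs the statistics with
1000 permutations and 1000 bootstrap draws — about 10 s on one CPU.
Simulation studies in the test suite use 100–500 repetitions with 500–1000
permutations. Every stage seed derives from the master seed; re-running a
config reproduces the manifest exactly (wall-times are reported separately).

The synthetic κ contrast of 0.4 produces a low-vs-high gamble-rate
difference of ~15 percentage points — larger than effects typically seen
in vivo —
because with μ ≈ 3 a 0.4 utility-unit bias shifts the choice function
substantially; the end-to-end checks are directional, not effect-size
matching. Similarly, pooled pseudo-R² (~0.22–0.26) reflects offers placed
at gamble probabilities 0.1–0.9, whose intrinsic choice entropy bounds the
attainable value.

## 7. Known limitations

* Per-subject, per-condition (α, μ, κ) estimates from 45 trials are noisy;
  only group-level contrasts should be interpreted.
* The extent-based cluster test is conservative on short time axes (see
  §5); prefer the mass statistic when calibration matters.
* The mediation estimator is two-stage with a subject bootstrap; it does
  not partial-pool level-1 uncertainty.
* The trigger's low/high yield depends on the temporal autocorrelation of
  the input; the 15th/85th thresholds do not imply 15 % tail rates for
  arbitrary inputs.
* Monetary rounding is fixed at £0.01 and applied after model inversion,
  so realised gamble probabilities deviate from their targets by up to
  ~0.02 near steep regions of the choice function.
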