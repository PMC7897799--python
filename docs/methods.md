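# Methods

## The two-pool model and its constants

The DLW calculation treats ¹⁸O and ²H as washing out of two slightly
different body-water pools. All equation variants implemented here are
instances of

    rCO2 (L/d) = c · N · (1.007·ko − f·kd) · 22.26

with N the body-water pool in mol, ko and kd the elimination rate
constants in d⁻¹, and:

- `c = 1/2.078 − 0.0246·1.05 = 0.45540` (printed 0.4554). The 1/2.078
  term converts the water pool into the CO₂-flux denominator; the
  0.0246·1.05 term removes the fractionated evaporative water loss.
- `1.007` scales the ¹⁸O dilution space to total body water.
- `f = 1.007·DSR` folds in the population dilution-space ratio
  N_d/N_o. The printed factors are 1.043 (DSR 1.036, adults), 1.038
  (1.031, infants 2–10 kg) and 1.026 (1.019, preterm babies < 2 kg).
- `22.26 L/mol` is the real-gas molar volume of CO₂. The ideal-gas
  22.4 used historically inflates rCO₂ by exactly 22.4/22.26 − 1 =
  0.629%; it remains available behind an explicit override (logged,
  never default) for back-comparisons.

Fully collapsing the adult constants gives the per-isotope form
`N·(0.45859·ko − 0.47498·kd)·22.26`. The mass-dependent variant uses
the `0.45859·N·(ko − DSR·kd)·22.26` form with DSR evaluated from body
mass (below). A structured error (`non_positive_rco2`) is raised when
the flux difference is non-positive, since that implies a failed
isotope analysis rather than a computable result.

**Accuracy of the printed constants.** The coefficients are rounded at
the fifth decimal and the flux *difference* amplifies that rounding.
On the physiological domain ko/kd ≥ 1.15 the long, simplified and
collapsed forms agree to 1×10⁻⁴ relative (the package's equivalence
tests use this grid); pushing kd/ko toward 0.95 grows the disagreement
to ~6×10⁻⁴. Likewise, substituting exact 1.007·DSR for the printed
deuterium factors changes rCO₂ by at most 0.2% on that domain — the
worst case is the infant factor (1.038 truncates 1.038217) right at
ko/kd = 1.15; the adult and preterm factors stay under 0.15%.

## Pool-size conventions

- Adults: N = (N_o/1.007 + N_d/1.043)/2 by default. Averaging the two
  spaces halves the impact of analytical error in either. When N_d is
  absent the oxygen-only pool N = N_o/1.007 is used, with a logged
  note.
- Baby equations (fixed-DSR and mass-dependent): N = N_o/1.007. The
  source material is ambiguous for the mass-dependent equation (one
  passage implies N = N_o, which differs by 0.7%); the N_o/1.007
  reading is consistent with the other baby equations and is the
  default, with `literal_No_pool=True` exposing the alternative.
- Dilution spaces are accepted in mol (canonical) or kg of water,
  converted at 18.02 g/mol.

## The mass-dependent dilution-space ratio

DSR(BM) = 1.036 − 0.05·exp(−0.5249·BM), BM in kg: monotone increasing
from 0.986 at zero mass toward the adult asymptote 1.036, passing
1.0185 at 2 kg (the preterm population value ≈ 1.019). Automatic
equation selection uses the adult equation at ≥ 10 kg and this curve
below; the boundary goes to the adult side, where the curve is within
0.03% of 1.036, so the switch is numerically seamless.

The constrained fitter (`fit_dsr_model`) estimates amplitude and rate
(and optionally the asymptote) by nonlinear least squares
(`scipy.optimize.curve_fit`). Starting values are deterministic and
scale-free — amplitude₀ = asymptote₀ − min(DSR), rate₀ =
1/median(mass) — with a 1×10⁻¹⁰ sum-of-squares tolerance and at most
10,000 evaluations, so identical inputs give identical fits. The fit
requires ≥ 10 points spanning ≥ 2 kg (the curve's amplitude and rate
are otherwise poorly identified). Confidence intervals use the t
distribution with n − p degrees of freedom on the curve-fit standard
errors; at the dispersion observed in real baby cohorts (residual SD
0.012) the 95% intervals cover the true constants at their nominal
rate (~95% over 200 simulated replicates of n = 300). The published
constants themselves cannot be re-derived here because the underlying
DSR-vs-mass scatter is not available; the fitter is validated on
synthetic data only.

## Energy conversion

Weir: TEE (MJ/d) = rCO₂·(1.106 + 3.94/RQ)·4.184/10³; kcal/d uses the
single constant 4.184 J/cal, so the two units are exactly consistent.
A measured RQ and a diet-derived food quotient enter identically and
are distinguished only by a provenance tag. No default RQ exists:
energy is computed only when one is supplied. RQ outside [0.6, 1.3]
warns but computes; RQ ≤ 0 is an error.

## Validation statistics

- Percent deviation: 100·(test − reference)/reference.
- Column summaries: sample mean, SD with the n−1 denominator (the
  printed table footers reproduce t = mean/(SD/√n) only under n−1),
  and a two-sided one-sample t-test against zero (t distribution,
  n−1 df). Missing cells are excluded and n reports the values used;
  a constant column yields SD = 0 with t/p reported as missing.
- Bland–Altman: limits of agreement are mean ± 2·SD, matching the
  published figures' convention rather than 1.96·SD; the multiplier is
  configurable. The >10% disagreement count is computed on percent
  differences.
- Regression: OLS of prediction on reference (chamber calorimetry is
  always the x axis) plus the reduced-major-axis slope SD(y)/SD(x)
  signed by r, which satisfies |rma| = ols/r identically.

## Packaged validation tables

The two chamber-calorimetry validation tables (61 adults across six
studies; 34 babies across four studies, masses printed in grams) are
transcribed once into version-controlled CSVs and verified against a
recorded SHA-256 checksum on every load. Subject IDs are opaque
strings (including the duplicate-looking "C2"/"C2b"). The adult
table's two N_d-requiring legacy columns exist for exactly 35
subjects; the baby table's individual-dilution-space column exists for
20. One printed inconsistency is handled explicitly: the baby table's
mass-dependent-equation summary (0.64%) is the ≥ 2 kg subgroup mean of
the printed column — the full-34 mean of the printed cells is 2.89%
(SD 12.17, which matches the printed SD) — so the package reports both
quantities. Every percent cell is consistent with its printed L/d
cells once each column's own printing precision is allowed for; the
preterm-equation column prints L/d at one decimal, which propagates up
to ±0.4 percentage points into recomputed deviations.

### The kinetics back-out oracle

The preterm and infant equations differ only in the deuterium factor
(1.026 vs 1.038), so their two printed columns form a linear system in
the products N·kd and N·ko:

    N·kd = (rCO2_preterm − rCO2_infant) / (0.4554·0.012·22.26)

This lets the mass-dependent column be reconstructed from printed data
alone, without the unpublished per-subject kinetics; the
reconstruction matches the printed column within 0.72% for all 34
babies (printing granularity is the only error source).

## Synthetic cohort generator

The generator draws cohorts consistent with the two-pool model: body
mass uniform on the spec's range, body water 50–65% of mass (converted
to mol at 18.02 g/mol), N_o = 1.007·N, N_d = DSR·N_o with DSR 1.036 at
≥ 10 kg or the mass curve below, kd uniform on 0.07–0.10 d⁻¹ (typical
adult water turnover), and ko solved by inverting the equation that
automatic selection will apply, so every noise-free record reproduces
its target rCO₂ exactly (the round trip is exact to < 1×10⁻¹⁰
relative). The default target model is the allometry 12.5·BM^0.84 L/d,
anchored so it passes through the validation-cohort means (~18.9 L/d
at 1.63 kg; ~497 L/d at 80.5 kg).

Measurement noise is multiplicative Gaussian with a common relative SD
(default 0.01, the typical analytic precision of isotope-ratio
measurement) applied independently to ko, kd, N_o and N_d. A subject's
noise draw is rejected and redrawn (bounded attempts) if it violates
the kinetics invariants (ko > kd, N_d/N_o within the physiological
0.95–1.15 window), so emitted cohorts are always valid; at noise SD
≤ 0.05 rejections are rare and do not visibly bias the error
distribution. At 1% noise the recovered rCO₂ shows ~7% SD — the
amplification intrinsic to differencing two similar fluxes — which is
the same order as the subject-level scatter in the real validation
tables.

What the generator does **not** emulate: correlated errors between the
four parameters (shared mass-spectrometry batches), within-subject
isotope dynamics (plateau vs intercept protocols), body-composition
covariance with mass, or RQ variation. Passing round-trip and
noise-propagation tests therefore verifies the calculation chain and
its error sensitivity, not field performance of the DLW method.

## Problem sizes and other numerical choices

Simulation studies use 200 fit replicates of n = 300 (interval
coverage), cohorts of 500 (noise propagation) and 60–100 (round trip);
all are seeded and reproducible, and the full suite plus the
acceptance script run in well under a minute. Ties and degenerate
inputs: the 10-kg selection boundary goes to the adult equation;
constant deviation columns report SD = 0 with missing t/p; zero-
variance regressors, mass spans under 2 kg, non-positive pools, rates,
RQs and reference values are rejected with structured errors rather
than propagated as NaN.

## Known limitations

- The equations inherit the population DSRs and fractionation
  corrections of their sources; subjects with atypical water turnover
  (illness, extreme diets) or age > 70 (where DSR may decline) fall
  outside the validated domain.
- The DSR curve is calibrated below 10 kg and flat above; it is not a
  model of DSR variation in adults.
- Legacy equation outputs in the validation tables are transcribed
  data: the package deliberately does not re-implement those methods.
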