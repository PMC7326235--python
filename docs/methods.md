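# Methods

## The score

The package models reproductive ageing as a continuous, fuzzy state. A
woman's score is the probabilistic-sum union

    RAS = mu_A + mu_B − mu_A·mu_B,

of two membership values: mu_A, her degree of membership in the *not
regularly menstruating* set, evaluated at the number of periods she
reported for the last twelve months; and mu_B, her membership in the
*menses stopped* set, evaluated at her (modified) age. The union is
commutative, has 0 as neutral and 1 as absorbing element, and dominates
both components, so the score can only move toward 1 as either input
does. Because both memberships lie in [0, 1], so does the score.

Both membership curves are derived from cross-tabulations of the three
regularity answers ("regular", "irregular for a few months", "stopped")
against period count and against whole year of age in a development
population of 3107 women aged 38–66 (packaged as fixtures in
`rascore/data/`). Writing x, y, z for the three answer counts in a row:

* P(period) = x/(x+y+z), the proportion menstruating regularly at each
  period count, is approximated by a biquadratic exponential
  `fitted_P = exp(quartic(period − shift))`, and mu_A = 1 − fitted_P.
  The curve is U-shaped in the complement: both fewer than ~11 and more
  than ~13 periods a year signal the transition, since cycles lengthen
  *and* shorten as it begins.
* P(age) = z/(x+y+z), the proportion with stopped menses at each age,
  is approximated by a quadratic logistic
  `mu_B = expit(b2·age² + b1·age + b0)`, a sigmoid rising through the
  transition midpoint near age 51.

## Age modifiers

Current smoking is associated with roughly two years' earlier menopause
and unilateral oophorectomy with about one year, so mu_B is evaluated at
a modified age: +2 years for current smokers, +1 for one ovary, +3 for
both conditions. The offsets live on the scoring model (`RASModel`) and
can be disabled (`modifiers_enabled=False`) when smoking or oophorectomy
are to be analysed separately. Bilateral oophorectomy is an eligibility
exclusion rather than an automatic score of 1.00: the modifiers only
cover the loss of one ovary, and the development population is a
natural-transition cohort, so scoring surgical menopause would leave the
model's support. Other exclusions mirror the development study: current
exogenous sex-hormone use (intermittent progestin therapy is folded into
this flag — the filter semantics are identical), pregnancy,
breastfeeding, and irregularity unrelated to menopause.

## Fitting

Refits minimise the **unweighted** sum of squared residuals in
probability space over the observed grid points —
`sum (exp(quartic) − P)²` for the period curve and
`sum (expit(quadratic) − P)²` for the age curve. Unweighted least
squares reproduces the published approximation-error bounds; whether the
original development fit weighted rows by their counts is not
documented, so the bounds are treated as upper limits. Implementation:

* **Initialisation** is deterministic — ordinary least squares of
  log P (period curve) or logit P (age curve) on the polynomial basis,
  using only grid points with P strictly inside (0, 1) — followed by
  Levenberg–Marquardt refinement (`scipy.optimize.least_squares`,
  tolerances 1e-15, max_nfev 50 000). No random restarts.
* **Shift**: the published period curve uses u = period − 0.7, but a
  shifted quartic is just a reparameterised quartic, so refits fix
  shift = 0 and absorb it into the coefficients. The published parameter
  set keeps its 0.7 offset and is evaluated exactly as printed.
* **Rows with zero totals** (a period count or age nobody reported) are
  dropped from the proportion series with a warning; the fit sees only
  observed grid points.

On the packaged development tables the refits achieve MSE 0.0022 over
the 16 period points and 0.0011 over the 29 age points, both below the
published coefficients' own residual errors against the same series
(0.0094 and 0.0017), as a correctly converged least-squares fit must be.

## Numerical edge cases

* With the published coefficients the exponential slightly exceeds 1
  around 12–13 periods/year, making raw mu_A negative. Memberships are
  clamped into [0, 1] **after** evaluation; the clamp is part of the
  scoring contract and is stated in the CLI help.
* Period counts above 15 are clamped to 15 before evaluating mu_A: the
  development data end there and the quartic is unconstrained beyond the
  observed range. Ages outside 35–70 are computed (the logistic is
  globally well behaved) but logged as extrapolation.
* Ages are whole years; fractional ages are truncated toward zero with a
  warning, matching the by-year development table.
* Scores carry full float precision; the two-decimal 0.00–1.00 form is
  presentation-only (`display_score`).

## Hormone validation

Women with a complete serum panel are classified by joint cut-offs:
nonmenopausal iff FSH ≤ 20 IU/L **and** 17β-estradiol ≥ 147 pmol/L;
postmenopausal iff FSH ≥ 80 IU/L **and** estradiol ≤ 73 pmol/L; everyone
else perimenopausal. Records missing either hormone are skipped with a
logged count, never imputed. Two ROC contrasts are computed with the RAS
as the score: peri+postmenopausal vs nonmenopausal, and postmenopausal
vs nonmenopausal+perimenopausal. The AUC is computed in its Mann–Whitney
form (ties count one half), which the test suite checks against
brute-force pair counting; curve points come from the standard threshold
sweep (`sklearn.metrics.roc_curve`). The 95% confidence interval uses
the DeLong midrank variance estimator — the original validation did not
name its CI method, so the method name is recorded in the result
metadata. Quartile summaries bin the two-decimal-rounded score closed on
the right at 0.25/0.50/0.75, matching the conventional bin labels
0.00–0.25 … 0.76–1.00.

## Synthetic cohort generator

No development or validation microdata are distributable, so
`rascore.simulate` generates cohorts with the statistical structure the
method assumes. Each woman receives a latent stage
u = expit((age − 51)/3 + ε), ε ~ N(0, 1), with age uniform on 38–66
whole years. The stage drives everything else:

* menses have stopped with probability u; stopped women report zero
  periods with probability 0.93, otherwise 1–6;
* among menstruating women the period count drifts down from 12 as the
  stage advances (Gaussian noise, SD 1.2), with an occasional 13–15
  mid-transition (probability 0.1·4u(1−u)) for shortening cycles; the
  probability of answering "regular" then rises with the period count
  (logistic centred at 10.6 periods, 0.03 → 0.96, tapering to 0.5 by 15)
  so the generated P(period) series shows the same gradient as the
  development table rather than a hard step;
* log FSH rises and log estradiol falls linearly in u between the
  nonmenopausal and postmenopausal anchor medians (11 → 124 IU/L,
  264 → 12 pmol/L) with lognormal noise (σ = 0.5), matching the strongly
  right-skewed spreads seen in real panels.

The regularity-given-periods gradient matters: if "regular" answers
vanish entirely below 11 periods, the fitted period curve saturates and
nearly half the cohort ties at RAS = 1.0, destroying rank information
among postmenopausal-range women. With the gradient in place, the
end-to-end pipeline (generate → refit both curves → score → ROC) yields
AUCs of about 0.92 and 0.87 at n = 5000, comfortably above the 0.8 the
generator contract requires.

Exclusion flags default to small nonzero prevalences (hormone use 8%,
pregnancy and breastfeeding 0.5% each, restricted to early-stage women;
irregularity unrelated to menopause 1%; unilateral oophorectomy 2%,
bilateral 1%; current smoking 25%) so the eligibility filter is always
exercised. The generator is fully determined by (config, seed).

**What passing tests do and do not show.** The generator encodes exactly
the monotone stage→questionnaire and stage→hormone couplings the score
assumes, with unimodal noise. Real cohorts add what it omits —
centre effects, reporting error in recalled period counts, gynaecological
disorders, hormone assay batch effects, and women whose hormone profile
contradicts their menstrual history — so synthetic AUCs characterise the
pipeline's correctness, not the score's field performance.

## Problem sizes

The default test and validation runs use the 16- and 29-point
development series for fitting and synthetic cohorts of n = 3000–5000
for the end-to-end checks — comparable to the development population —
with ROC oracle cross-checks at n ≤ 50 where exhaustive pair counting is
exact.

## Known limitations

* The score ignores chronic disease, gynaecological disorders and prior
  hormone use; these are eligibility exclusions, not model inputs.
* The membership curves were developed on a Northern/Western European
  questionnaire population; age-at-menopause differences across
  ethnicities would shift mu_B.
* The period curve is only supported on 0–15 periods/year; everything
  above is clamped.
* The DeLong interval is asymptotic; for very small validation sets a
  bootstrap would be preferable.
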