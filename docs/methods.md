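# Methods

## Unit of analysis and data model

The unit of analysis is a randomized pairwise comparison. A multi-arm
trial contributes one record per intervention-vs-control comparison,
sharing a `trial_id`; comparisons are treated as independent (no
shared-control covariance adjustment), and trial counts in reports are
distinct `trial_id`s so the multiplicity stays visible. Eligibility
requires at least 500 randomized patients per comparison; the filter is
idempotent and its attrition is logged.

Event counts are intention-to-treat: numerators are events per randomized
arm, denominators the randomized arm sizes. A missing endpoint is encoded
as an empty CSV cell and is never conflated with zero events — each
endpoint pairing therefore has its own pair count, as in real extractions
where not every trial reports every endpoint.

## Effect measures

Treatment effects are natural-log odds ratios from the 2×2 table
(`ln(ad/bc)`, Woolf SE `sqrt(1/a + 1/b + 1/c + 1/d)`). When any cell is
zero, 0.5 is added to all four cells (Haldane–Anscombe) before both the
estimate and the SE; this is the default because it is the dominant
meta-analysis convention, with exclusion of zero-cell tables available as
`zero_cell="exclude"`. A table with zero events in *both* arms carries no
information about the odds ratio under either convention and is returned
as a non-informative sentinel that every downstream stage excludes.

Reported effects (for the hazard-ratio sensitivity track) enter as
`ln(value)` with SE back-calculated from the 95% CI,
`(ln hi − ln lo) / (2 · z₀.₉₇₅)`; a degenerate CI (`lo = hi`) is rejected
because the implied SE of zero would give the comparison infinite weight
in any inverse-variance use. The sensitivity track pairs the count-based
bleeding log-OR with the article's reported mortality log-HR, restricted
to comparisons that reported one; the primary analysis always recomputes
ORs from counts, even when an OR was also reported.

## Trial-level surrogacy

The regression of final-endpoint effects on surrogate effects is weighted
least squares with weights equal to randomized patients per comparison
(the convention for trial-level surrogacy displays where circle area is
proportional to trial size); inverse-variance weighting
(`weighting="inverse_variance"`, weights `1/SE²` of the final-endpoint
effect) is available as a sensitivity option. With weighted means
x̄ = Σwx/Σw, ȳ = Σwy/Σw:

- slope = Σw(x−x̄)(y−ȳ) / Σw(x−x̄)², intercept = ȳ − slope·x̄;
- R² = 1 − Σw(y−ŷ)² / Σw(y−ȳ)², identical to the squared weighted Pearson
  correlation;
- slope CI from a t quantile with n−2 degrees of freedom on the weighted
  residual mean square (needs ≥ 3 pairs). No published account pins the
  slope-CI method for this kind of analysis to a unique convention; the
  t-based WLS interval is the standard choice and is labelled as such.

All of slope, intercept, R², and the slope CI are invariant to rescaling
the weights by a positive constant. Degenerate designs (all x equal) and
zero outcome variance (all y equal) raise typed errors rather than
returning NaNs.

The R² confidence interval is the delta-method interval
`R² ± z · sqrt(4R²(1−R²)²/(n−3))` clipped to [0, 1]. This form was chosen
because it exactly reproduces, at two-decimal precision, the published
interval bounds recomputable from published (R², pair-count) inputs; it
requires at least 4 pairs (the smallest subgroup for which a CI is
reported) and degrades gracefully — below 4 pairs the point estimate is
reported with a missing CI and an "inconclusive" CI-scheme label. One
published subgroup bound (R² 0.76 with 8 pairs, printed lower bound 0.61)
is *not* reproduced by this formula (it yields ≈ 0.39); that row is
recorded as unexplained rather than special-cased.

Classification: CI scheme — lower bound > 0.72 strong, upper bound < 0.50
weak, otherwise inconclusive; point scheme — R² ≥ 0.7 strong, 0.5 ≤ R² <
0.7 moderate, < 0.5 weak. Rendered tables round to two decimals (with
−0.00 normalized to 0.00); JSON output keeps full precision.

## Heterogeneity

Per-endpoint pooling uses inverse-variance weights `1/SE²`: Cochran's
Q = Σwᵢ(θᵢ − θ_fixed)², DerSimonian–Laird
τ² = max(0, (Q − df)/(Σw − Σw²/Σw)), I² = max(0, (Q − df)/Q)·100, and
random-effects weights `1/(SE² + τ²)`. Random-effects (`random_dl`) is
the default; with τ² = 0 it coincides exactly with the fixed-effects
estimate. Funnel data are (log effect, SE) points sorted by precision
with the fixed-effects centerline; no asymmetry test is attached.

## Evaluation grid and subgroups

The overall grid crosses six bleeding-definition families — study-defined
major/minor, BARC 2-3-5 (including 2-3-4-5 labels), TIMI major/minor,
study-defined major, BARC 3-5 (including 3-4-5), TIMI major — with two
final endpoints (all-cause and cardiovascular death): 12 primary rows.
Study-defined rows pool every trial reporting the endpoint regardless of
definition label. Subgroups are conjunctions of record-level filters:

- enrollment era split at 2010/2011, with year 2010 in the early stratum;
- follow-up split at 12 months, with exactly 12.0 months in the
  "≤ 12 months" stratum;
- region (East Asia vs non-East Asia), ACS-only, and BARC-only/TIMI-only
  definition criteria.

Cells with fewer than 2 informative pairs are reported as not-estimable
with a reason code, never silently dropped; one structured log line per
cell records its counts. Reruns on identical input and configuration are
byte-identical: nothing in the pipeline is random and rendered artifacts
carry no timestamps (the metadata block holds the software version, a
SHA-256 of the canonical input CSV, and the configuration echo instead).

## Synthetic data generator

Each simulated comparison draws true effects (θ_bleed, θ_death) from a
bivariate normal with means (μ_S, μ_F), SDs (σ_S, σ_F) and correlation
`rho_trial` on the log-odds scale, so the true trial-level R² is
`rho_trial²`. Control-arm risks are jittered per trial on the logit scale;
treatment-arm risk is `expit(logit(p_control) + θ)`; counts are binomial
per arm. θ_bleed drives both bleeding endpoints and θ_death both death
endpoints; the four endpoints are otherwise conditionally independent —
within-trial patient-level correlation (e.g. fatal bleeds counting toward
both) is deliberately not modeled, because only trial-level surrogacy is
under study.

Default configuration (the emulated study conditions): 58 comparisons
with 10 multi-arm pairs (48 distinct trials), total sizes log-uniform on
[500, 10,000] (≈ 190,000 patients in expectation, the scale of the real
extraction, with the heavy right tail real RCT sizes show), control risks
4% major/minor bleeding (major = 0.45× that) and 2% all-cause death
(CV = 0.6×), μ_S = −0.10, μ_F = −0.02, σ_S = 0.35 ≫ σ_F = 0.15 (bleeding
effects are far more heterogeneous across trials than mortality effects),
`rho_trial = 0.3` (true R² = 0.09, the weak-surrogacy regime), endpoint
missingness of 20%/8%/15% for major-minor bleeding / major bleeding / CV
death (reproducing endpoint-specific pair counts), 60% of articles
reporting a mortality HR, and attribute mixes of 25% East Asia, 50% ACS,
48% pre-2010 enrollment, 42% follow-up beyond 12 months. All randomness
flows from one seeded generator; identical config + seed gives identical
CSV bytes.

`SyntheticConfig.recovery_conditions` defines the estimator-validation
regime: 200 trials of ≥ 5,000 patients, 10% control risks, σ = 0.5 on
both axes. These values keep binomial sampling error second-order relative
to between-trial spread, so the estimated R² should approach `rho_trial²`;
at small trial sizes the estimate attenuates toward zero (classical
measurement error in both axes), which is expected behavior and is
covered by a test, not corrected. CI coverage of the delta-method interval
is *reported* by the recovery experiment, not asserted at 95% — the
interval is a first-order approximation and empirically covers at roughly
90% in the strong-correlation regime.

What passing tests on synthetic data do **not** show: the generator has no
publication bias, no outcome misclassification, no shared-control
covariance for multi-arm trials, independent endpoints given the true
effects, and binomial (not time-to-event) outcomes — the HR track is
synthesized directly from the true mortality effect. Conclusions about
real extractions inherit none of these simplifications' guarantees.

## Numerical choices

- Natural logarithms throughout; z₀.₉₇₅ from `scipy.stats.norm.ppf`.
- R² is clipped to [0, 1] against floating-point undershoot; CI bounds to
  [0, 1] by construction.
- Problem sizes in the test suite (200-replicate recovery at 200 trials,
  1,000-instance regression cross-checks) were chosen to give Monte-Carlo
  standard errors well inside the asserted tolerances.
- Seeds derived for replicate streams use `numpy.random.SeedSequence` and
  stay below 2³¹.

## Known limitations

- Per-comparison pooling treats multi-arm comparisons as independent in
  heterogeneity statistics; per-trial collapsing is not implemented.
- No individual-patient-level surrogacy (R²_indiv), surrogate threshold
  effect, or Bayesian bivariate meta-analytic model.
- The delta-method R² interval can be anti-conservative near the
  boundaries (sd → 0 as R² → 0 or 1); the recovery experiment quantifies
  rather than hides this.
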