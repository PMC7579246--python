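# Methods

## The classification model

Each subject contributes raw scores on an 8-measure neuropsychological
battery spanning five cognitive domains: episodic memory (CVLT-II
trials 1–5 total, CVLT-II long-delay free recall), executive function
(Trail Making Part B, D-KEFS Color–Word inhibition), attention
(WAIS-III Digit Span, Trail Making Part A), language (Boston Naming)
and visuospatial function (WAIS-III Block Design). Scores are
standardized against an age-banded normative table; the sign convention
is uniform — more negative is worse — so timed measures (seconds) are
standardized as `z = (mean − raw)/sd` and all others as
`z = (raw − mean)/sd`. A score is *impaired* when `z ≤ −1.0`,
boundary inclusive. The threshold is configurable but the 1 SD cut is
the point of the actuarial method: it trades a lenient per-measure cut
for a requirement of convergence across measures.

Classification operates on per-domain summaries. A domain is *touched*
if at least one of its measures is impaired. The rules, in precedence
order (precedence affects only the recorded trace, never the label):

1. **MCI** — both measures impaired in episodic memory, executive
   function, or attention (the two-measure domains);
2. **MCI** — at least 4 of 5 domains touched;
3. **CN** — no domain touched;
4. **intermediate** — otherwise (1–3 domains touched, no full
   two-measure hit).

The one-measure domains can only contribute "touched": a single
impaired Boston Naming score is intermediate, not MCI. The rule set is
monotone — adding an impairment can never improve the label — and the
implementation is tested exhaustively against an independent
brute-force evaluator over all 2⁸ impairment patterns.

Missing data: a two-measure rule requires both measures present and
impaired; a fully missing domain counts as untouched; and a subject
with fewer than 6 of 8 scored measures is labelled UNCLASSIFIABLE
rather than CN, because "no impaired score" must not be conflated with
"no score". The source criteria do not state a missing-data rule; this
policy is this package's own.

APOE covariate coding: genotypes 3/4 and 4/4 are ε4-positive, 2/3 and
2/4 ε2-positive; 2/4 is *not* ε4-positive (the protective allele takes
precedence for flagging).

## Normative table

Published norms for these instruments are licensed and are not
redistributed here. The package ships a **synthetic** default norm
table (`gwmci/data/default_norms.csv`): decade-wide bands covering ages
35–84 with plausible means/SDs per measure (e.g. Trail Making B rising
from 58 ± 20 s in the 35–44 band to 110 ± 45 s at 75–84). Any
age-banded norm set can be substituted through the same CSV contract
(`measure_id,age_min,age_max,mean,sd`; inclusive integer bands matched
on completed years). Classification results depend on the norms only
through the z-transform, and the synthetic cohort inverts the same
table, so all planted structure is norm-consistent by construction.

## Statistical layer

* **Chi-square** — Pearson, no continuity correction, expected counts
  from the margins. Degenerate margins raise instead of returning 0/0.
* **ANOVA** — classical between/within decomposition; also computable
  from per-group (mean, SD, n) summaries, which is algebraically
  identical and lets printed summary tables be re-tested.
* **ANCOVA group test** — OLS with two group indicators against a
  reference (CN by default) plus covariates; the group effect is the
  partial F comparing full and covariate-only models. With no
  covariates this reduces exactly to the one-way ANOVA (tested).
  Planned contrasts are linear contrasts on the fitted coefficients
  with t/p from the coefficient covariance, reported without
  multiplicity correction as is conventional for pre-specified
  contrasts.
* **Regressions** — hierarchical (blockwise) OLS reports R², ΔR² and
  per-term standardized β (z-scoring outcome and every predictor,
  binary predictors included; t and p are scale-invariant and shared
  with the raw fit). Binary outcomes (MCI status) are fitted as linear
  probability models, matching the analysis style this package
  emulates; a logistic fit would be the modern choice but would not
  reproduce that style. Stepwise selection is forward with backward
  removal at p_enter = 0.05 / p_remove = 0.10 (the common default;
  configurable). Listwise deletion within each model, dropped counts
  logged.
* **Correlated-endpoints threshold** — `m_eff = n^(1 − r̄)` with the
  Sidak threshold `1 − (1 − α)^(1/m_eff)`. `r̄` is the mean of the
  strictly-upper-triangle pairwise Pearson correlations, signed (not
  absolute); a negative `r̄` is clamped to 0 with a warning, recovering
  the ordinary Sidak correction. Both this form and `α/m_eff`
  reproduce the printed thresholds (0.03 for n = 5, r̄ = 0.58; 0.006
  for n = 15, r̄ = 0.21) after rounding; the Sidak form is exact in
  both limits r̄ = 0 and r̄ = 1, which is why it is the default.
  In the pipeline `r̄` is computed in-sample from the analyzed cohort
  for each family (five cortical thicknesses; fifteen exposure codes).

## The synthetic cohort

The generator's defaults are the study conditions it emulates:
202 subjects; planted status 25 MCI / 98 intermediate / 79 CN with the
intermediate group touching 1/2/3 domains for 68/25/5 subjects; ages
truncated-normal per group (51.8 ± 6.7, 53.7 ± 7.3, 55.4 ± 8.4 years,
bounded to 35–79 so every subject is covered by the norm table);
binary clinical and military flags at the per-group rates of the
emulated demographics table (e.g. current PTSD 40%/12%/8%); race,
service, branch, TBI and APOE categories from the printed per-group
counts; and the fifteen deployment-exposure items drawn per group from
the printed frequency-category percentages through a latent-Gaussian
copula with exchangeable latent correlation 0.21.

Test z-profiles are drawn from an exchangeable-block Gaussian template
(within-domain ρ = 0.6, cross-domain ρ = 0.3, chosen to be positive
definite and to make multi-domain impairment non-trivially frequent)
and then forced to the planted pattern by reflecting offending
coordinates about the −1 threshold — a deterministic shift that keeps
the constrained margins half-normal about the threshold. Label
recovery is therefore guaranteed and is asserted at generation time;
round-trip tests confirm it for arbitrary valid configurations. Raw
scores are produced by inverting the norm-table transform at the
subject's age, so re-standardization recovers the planted z exactly
(tested to 1e−9).

Imaging scalars are planted per group: hippocampal volume
(8.05 ± 0.98, 8.59 ± 0.80, 8.68 ± 0.79 cc for MCI/intermediate/CN)
loads on standardized ICV (coefficient 0.35 cc/SD; ICV 1500 ± 140 cc)
and on age (−0.02 cc/yr), with residual SD chosen so the marginal
group SD matches its target; the five cortical thicknesses carry their
group means/SDs, a small age slope (−0.003 mm/yr) and exchangeable
residual correlation 0.58, so the pipeline's in-sample `r̄` for the
cortical family lands near the value its threshold emulates.

What the generator does **not** emulate: item-level test responses,
measurement error in the norms themselves, missing data (fixture
cohorts are complete), the observed ordinal attenuation of exposure
correlations (coding the copula draws into four ordered categories
shrinks the realized `r̄` below the latent 0.21, to roughly 0.13), or
any causal structure — status-conditional sampling is a convenience,
not a claim. Passing tests therefore demonstrate that the method
recovers structure of this planted form at these effect sizes, not
that it would behave identically on the real cohort.

## Problem sizes and determinism

The packaged fixture is `generate_cohort` at a pinned seed (20200930);
it is byte-stable across runs for a given numpy version. Power-style
checks (covariate-adjusted detection of the planted hippocampal
deficit; sign of the step-2 PTSD coefficient) use 200 replicate
cohorts at the default n = 202, which keeps the full suite under a
minute on one CPU. All randomness flows through
`numpy.random.default_rng` seeds.

## Known limitations

* The default norm table is synthetic; absolute impairment rates on
  real data depend entirely on the norms supplied.
* The linear probability model can predict outside [0, 1]; it is kept
  deliberately for fidelity to the emulated analysis.
* Stepwise selection inherits the usual caveats (post-selection
  inference is not corrected).
* One demographic table row of the emulated study (mild–moderate CMI)
  is internally inconsistent in print and its test statistic is not
  reproducible from its cells; it is excluded from the packaged
  contingency tables.
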