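# Methods

## The classification

During robotically assisted total knee arthroplasty (ra-TKA), the robot's
registration step reports the medial and lateral soft-tissue laxity of the
knee — the maximal femorotibial compartment opening, in millimetres, under
applied varus/valgus stress — in two positions: full extension and 90°
flexion. For each position let *m* and *l* denote the medial and lateral
laxity. The pipeline computes

* the **signed difference** *d = m − l* (positive = more medial laxity) and
* the **sum** *s = m + l*,

and bands the **absolute** difference |d| into three ordinal categories at
two limits *t₁* and *t₂* (defaults 2.5 mm and 5.0 mm):

| category | band |
|---|---|
| 1 (extension) / A (flexion) | |d| < t₁ |
| 2 / B | t₁ ≤ |d| ≤ t₂ |
| 3 / C | |d| > t₂ |

Band edges belong to the middle category, matching the printed "< 2.5",
"2.5–5" and "> 5" bands. The extension digit and flexion letter concatenate
into one of nine phenotype labels, 1A … 3C. Classification depends only on
|d|, so it is invariant to swapping the compartments; the sign convention
(medial − lateral) only matters for distribution summaries and is
configurable in the sense that callers can negate it before ingestion.

A **balanced-area policy** marks end-of-surgery labels as balanced
(default {1A}), almost balanced (default {1B, 2A}) or unbalanced. The
default union reproduces the published 93.1% figure; a stricter variant
with only {1A, 1B} is provided (`BalancedAreaPolicy.abstract_variant()`)
because the source abstract groups the balanced area that way while its
results section includes 2A. Neither is privileged in code; the policy is a
parameter.

## Threshold derivation (phase 1)

The category limits are not free parameters: if the mediolateral difference
is normally distributed, the bands mean ± 1 SD and mean ± 2 SD partition a
cohort into three natural severity groups, and a single rounded SD value
can serve as the band width. The derivation rule implemented is:

1. compute the sample SD (n−1 denominator) of the signed difference in each
   position whose difference passed normality;
2. floor each SD to a 0.5 mm grid (an SD "slightly over 2.5 mm" becomes
   2.5 — flooring is one consistent formalization of that judgment; the
   alternative readings, truncation or nearest-0.5 rounding, coincide with
   it for the observed 2.72 and 2.98);
3. take the minimum across positions as *t₁* and set *t₂ = 2 t₁*,
   mirroring the ±2 SD construction.

Applied to the published difference SDs (2.72 mm extension, 2.98 mm
flexion) this yields the canonical 2.5/5.0 mm scheme. Sums are summarized
and normality-tested for completeness but never drive thresholds, because
only the differences were normally distributed and only differences define
the bands.

Normality is assessed jointly: the Lilliefors variant of the
Kolmogorov–Smirnov test (mean and SD estimated from the sample;
`statsmodels`' implementation) with its p-value capped at 0.2 — classic
Lilliefors tables do not resolve beyond 0.2, which is why clinical software
prints "p = 0.2" — together with the Shapiro–Wilk test (`scipy`). A sample
is called normal only if **both** p-values exceed α = 0.05. Because two
correlated tests are combined, the empirical type-I error of the joint
verdict is slightly above nominal: measured at 0.068 over 1,000 normal
samples of n = 120 (the acceptance suite recomputes this), inside the
[0.03, 0.08] band considered acceptable for the joint rule.

Outliers in distribution summaries use the Tukey boxplot rule (values
beyond the quartiles ± 1.5 × IQR, linear-interpolation quartiles). The
source reports outlier counts without stating its criterion; the fence
multiplier is a parameter, and reproducing those exact counts is not a
goal.

## Phase 2 (validation)

The validation pipeline classifies every knee at the start and end of
surgery under a **frozen** scheme — validation must not re-derive
thresholds from its own data — and produces both phenotype distributions,
the 9×9 initial→final transition table, and the balanced-area percentage of
the final distribution. Percentages are rounded half-up to one decimal to
match clinical table conventions; distribution counts always sum to n, and
the transition table's marginals reconcile exactly with the two
distributions (tested as an invariant). Zero cells render as "-" in CSV
table output, as in the published tables.

`compare_phase_distributions` computes the textbook Pearson correlation of
two 9-vectors of label percentages with its two-sided p (n = 9 pairs).
Replaying the published tables gives r ≈ 0.96 between the two phases'
initial distributions — both are dominated by 1A/1B — which cannot be
reconciled with the r = 0.039 (p = 0.7) the source prints for this
comparison. The package reports the computed value and does not target the
printed one; the discrepancy is noted here as a known defect of the source
tables or of the figure printed alongside them.

## Synthetic cohort generator

The generator emulates the distributional structure the analysis assumes,
so every stage is testable without clinical data. Defaults are the
derivation-phase study conditions:

| quantity | law | mean ± SD |
|---|---|---|
| extension difference | normal (truncated, see below) | 0.54 ± 2.72 mm |
| extension sum | normal, truncated at 0 | 5.33 ± 2.38 mm |
| flexion difference | normal (truncated) | 0.203 ± 2.98 mm |
| flexion sum | shifted gamma (shift 1 mm) | 6.57 ± 3.26 mm |
| age | normal, clipped to [18, 105] | 69.6 ± 8.69 y |
| sex / side / deformity | Bernoulli | 89/120 F, 51.7% L, 103/120 varus |

Sums and differences are drawn (the parameterization of the source data)
and compartments reconstructed as m = (s+d)/2, l = (s−d)/2, which implies a
side correlation rather than assuming one. The flexion sum uses a
moment-matched shifted gamma (shape (μ−c)²/σ², scale σ²/(μ−c), shift
c = 1 mm) — a free family choice realizing the reported right skew so the
flexion sum fails normality at cohort size while the differences pass.
Extension and flexion are independent by default; their true dependence is
unreported.

**Non-negativity and moment calibration.** Compartment laxities must be
non-negative, i.e. d is confined to [−s, s]. Under the default marginals,
independent draws put ~14% of extension knees outside that region;
rejecting and redrawing them would truncate the joint law and bias the
extension-sum mean upward by ≈ 0.5 mm — an order of magnitude beyond the
±0.05 mm moment-recovery tolerance the generator is held to. The generator
therefore samples *exactly* from truncated laws via inverse-CDF transforms
(no rejection loop at all): the sum from a normal truncated at zero, then
d | s from a normal truncated to [−s, s]. The proposal mean/SD of each
truncated law is calibrated once per parameter set by root-finding
(closed-form truncated-normal moments; expectation over s by 400-node
Gauss–Legendre quadrature) so that the **post-truncation** marginals have
exactly the configured mean and SD. Verified at n = 5×10⁵: all four
moments within 0.01 mm of targets. Calibrations are cached; generation of
10⁵ knees takes ~1.5 s on one CPU.

Generated laxities are rounded half-up to 0.1 mm (the robot's display
resolution is unstated; 0.1 mm preserves CSV round-tripping and perturbs
moments negligibly).

**End-of-surgery states** are phenomenological, not biomechanical: each
knee's final label is drawn from a configurable mixture (defaults: the
published final-assessment frequencies, 70/23/5/2/1/1 over 102),
independently of its initial state; laxities realizing the label are drawn
uniformly inside the label's difference band — with 0.15 mm margins at the
band edges so 0.1 mm display rounding cannot move a knee across a
boundary — with the lesser compartment uniform in 0.5–3 mm (the surgical
target of 1–2 mm residual laxity, plus spread). Because final labels are
independent of initial ones, the synthetic transition table has the correct
marginals but not the source's (unpublished) dependence structure; tests
about transition *reconciliation* are meaningful on synthetic data, tests
about transition *content* are only meaningful on replayed published
counts.

**What passing tests show.** Synthetic cohorts reproduce the four printed
marginal moments, the skew/normality pattern, the final-state frequencies
and the demographics — not the unknown joint distribution across the four
laxity channels, nor any real measurement error structure. Agreement on
synthetic data therefore validates the pipeline's arithmetic and logic, not
clinical generalizability.

## Numerical choices and degenerate inputs

* Sample SD uses the n−1 denominator throughout (clinical-statistics
  convention).
* Band edges: |d| equal to a limit goes to the middle category;
  grid-flooring in the derivation guards against float wobble at exact grid
  points with a 1e-9 tolerance.
* Percentages round half-up (`decimal.Decimal`), so 68.627 → 68.6 and
  15.83 → 15.8, matching the published tables digit for digit.
* Degenerate inputs raise: constant samples (normality), n < 2 (summaries),
  n < 8 (normality), empty cohorts, missing final profiles (errors name
  the offending record ids), mixtures not summing to 1, infeasible
  generator parameters (mean sum < |mean difference|).
* Determinism: cohorts are pure functions of (params, seed); pipelines are
  pure functions of their cohort; repeated runs are byte-identical.

## Problem sizes used in the checks

Moment recovery runs at n = 100,000 (Monte-Carlo SE of each mean ≤ 0.01 mm
against a ±0.05 mm tolerance); unit tests use n = 20,000 with
proportionally looser bounds; normality calibration uses 1,000 replicates
of n = 120; scheme-recovery uses 100 replicates at the study's n = 120.

## Known limitations

* At the study's own cohort size the derived scheme is not a near-certain
  event: the sampling SE of a sample SD at n = 120 is σ/√(2(n−1)) ≈ 0.18 mm,
  so a population SD of 2.72 mm falls below the 2.5 mm grid edge in ~10% of
  cohorts and the derivation then returns 2.0/4.0 mm. The observed recovery
  rate of 2.5/5.0 across seeded replicates is ~0.85. This is a property of
  the derivation rule at that n, not an implementation artifact.
* The SPSS `.sav` ingestion contract (column map → native schema) is fully
  implemented and tested via CSV, but reading an actual `.sav` file
  requires the optional `pyreadstat` dependency, and the deposited study
  file is not distributed here; the replay test runs only when a user
  supplies it under `data/`.
* The generator's final states ignore initial states; modelling the
  balancing process itself (releases, recuts) is out of scope.
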