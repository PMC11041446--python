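# Methods

## Problem setting

A 3D-imaging device estimates child stature (recumbent length below 24
months, standing height after) and mid–upper arm circumference (MUAC).  To
validate it against manual anthropometry in children aged 6–59 months, each
child is measured by both methods and the paired differences d_i = scan −
manual are analysed.  The package implements that analysis plus a generator
of synthetic paired data with the statistical structure such field studies
exhibit, so every stage is exercised end to end without external data.

## Agreement model

The differences are treated as exchangeable draws whose first two moments
carry the validation verdict:

* Bias = mean(d), with a 95% CI using the t distribution on n−1 df.  At the
  sample sizes involved (n ≳ 150) t and z multipliers agree to the second
  decimal; t is used as standard practice.
* Limits of agreement = bias ± 1.96·s, with s the sample SD (n−1
  denominator).  The multiplier is the conventional fixed 1.96, not
  t-based, matching standard Bland–Altman usage.
* TEM = √(Σd²/2N).  Because Σd² = N·bias² + (N−1)·s², a (bias, LoA, n)
  summary determines TEM exactly:
  TEM = √((bias² + s²(n−1)/n)/2) with s = (LoA_upper − LoA_lower)/(2·1.96).
  `technical_error` (from raw differences) and `tem_from_summary` are tied
  together by a property test at 1e−9 relative tolerance.
* Pitman's test of equal paired variances is computed as the Pearson
  correlation of d_i with the pair mean, with the two-sided p from
  t = r·√((n−2)/(1−r²)) on n−2 df.  This is the classical
  difference-versus-sum formulation (the sum is twice the mean; correlation
  is scale-invariant).  Zero variance in either vector yields an explicit
  undefined result (NaN, NaN) rather than an arbitrary number.

Stratified summaries (by team, sex, or the 6–23/24–59 month age groups that
correspond to measurement position) suppress — rather than drop — strata
below `min_n` (default 5): the stratum appears with its n and NaN
statistics, so small teams remain accountable in output tables.

## LMS z-scores and classification

z = ((x/M)^L − 1)/(L·S) for L ≠ 0 and ln(x/M)/S at L = 0.  Ages are
converted to reference days at 365.25/12 = 30.4375 days/month.  Lookup
interpolates L, M, S linearly in the key by default (nearest-key
selectable); outside tabulated coverage the z-score is missing, never
extrapolated.  The weight-based indicators (WHZ, WAZ) apply the standard
tail restriction: beyond |z| = 3 the score is linearised against the
distance between the reference's ±2 and ±3 SD values, keeping gross
outliers on an interpretable scale; HAZ is always the plain score.  Whether
the restriction is applied is a flag (`restrict_tails`, default on) because
validation reports rarely state it.  No length/height position correction
is applied by default: measurement position is inferred from age alone.

Stature outside the window in which z-scores are considered generatable
(length 45–110 cm under 24 months, height 65–120 cm otherwise; boundaries
inclusive-valid) is *flagged*, not rejected — the z-scores are still
computed and exclusion is a downstream decision, keeping computation and
filtering separable.

Severity classes use the standard cutoffs: z < −3 severe, −3 ≤ z < −2
moderate, otherwise normal; MUAC < 11.5 cm severe, 11.5 ≤ MUAC < 12.5
moderate.  Scan-side WHZ uses the manually recorded weight, since the
device measures no weight.

### The synthetic reference

Reproducing official growth-standard values is out of scope.  The shipped
table uses smooth power-law medians of realistic scale (stature ~66.5 cm at
6 months to ~109 cm at 59 months; weight-for-stature ~5.9 kg at 66.5 cm to
~22 kg at 120 cm), constant S per indicator (0.035 stature, 0.08
weight-for-stature, 0.12 weight-for-age) and fixed Box-Cox powers (1,
−0.35, 0.1 respectively).  Weight-for-age medians are the *composition* of
the weight-for-stature and stature-for-age curves, so a child at the median
of both HAZ and WHZ also scores WAZ ≈ 0 — an internal-consistency choice
that keeps the three indicators mutually coherent.  Coverage extends
slightly past the 6–59 month and 45–120 cm analysis windows (ages ~5.4–60.6
months, statures 40–130 cm) so that truth generation near the boundaries
never hits a coverage edge.

## Synthetic cohort generator

The generator emulates the study conditions of a six-team field validation
of ~539 children; its defaults are fixed once and documented here.

* **Truth.** Age uniform on 6–59 months; sex Bernoulli(0.5); teams
  round-robin.  HAZ ~ Normal(−0.9, 1.25) and WHZ ~ Normal(−1.0, 1.1) are
  inverted through the reference to true stature and weight; MUAC truth is
  Normal(14.0, 1.2) cm (MUAC is classified on raw cm and needs no
  reference).  WAZ is implied by the other two rather than sampled.
* **Manual process.** Truth + Normal noise (SD 0.4 cm stature, 0.2 cm
  MUAC, 0.05 kg weight), then with probability 0.2 (stature) / 0.3 (MUAC)
  the value is rounded to the 0.5-cm grid.  Those rates reproduce the
  digit-preference-score scale seen in field data via DPS ≈ 66.7·p for a
  rounding-mixture on a half-cm grid.
* **Scan process.** Per retained child and session:
  value = truth + bias + slope·(truth − cohort mean) + Normal(0, SD_team).
  Bias defaults: −0.5 cm stature, +0.72 cm MUAC.  The slope term (0.3
  stature, 0.5 MUAC) produces the size-correlated error a positive Pitman
  correlation detects.  Per-team noise SDs (3.6–10.0 cm stature, 1.5–2.8 cm
  MUAC) span the clean-measurement spread implied by the
  flagged-and-discordant-excluded agreement scale; the contamination
  mechanism below, not the base noise, generates the whole-sample tail.
  With probability 0.05 a session is replaced by a contaminant: the
  `adult-contaminant` model draws stature Normal(165, 10) cm and MUAC
  Normal(26, 3) cm (a caregiver in the frame read as the child); the
  `near-zero` model emits junk below 10 cm (device failure).  Children are
  dropped entirely with probability 0.104 (refusal) and, independently,
  with a per-team missingness probability (0.09–0.96) reproducing strongly
  team-dependent scan loss.  Session counts are 1 or 2 (P = 0.88/0.12).
* **Identifier corruption.** A fraction (default 0.25) of children have
  their scan-side IDs pairwise swapped.  Records keep their own recorded
  attributes, so the linkage stage sees genuine sex/age/weight conflicts
  and — because the scan now describes a different child — genuinely
  mismatched measurements.
* **Determinism.** Every child draws from a `SeedSequence((seed, stage,
  child_index))` substream: identical config + seed gives byte-identical
  output, and enlarging the cohort leaves existing children untouched.

What the generator does *not* emulate: cluster sampling design, enumerator
learning over time, correlated session errors within a child, non-Normal
manual error, or any 3D-imaging physics.  Passing tests therefore
demonstrate the *analysis machinery* is correct and recovers known
parameters — not that real devices behave like the error model.

## Linkage and exclusions

Multi-session scans are median-aggregated per child *before* matching
(midpoint convention for even counts), then inner-joined to manual records
on child ID; duplicate IDs within a source are an error naming the ID, and
both unmatched sets are returned, never silently dropped.  Discordance
flags use strict inequalities: age differences strictly greater than 6
months, weight strictly greater than 5 kg (threshold configurable; 10 kg is
also in circulation for this check and selectable), any sex mismatch.  The
"excluding flagged and discordant" sensitivity analysis removes pairs with
out-of-range or fixed-outlier scan values or any attribute discordance.

Which outlier set (fixed or flexible) feeds post-exclusion SDs in quality
reports is configurable; the default is flexible, with the flexible median
computed separately per source and indicator (each column of the quality
table is its own sample).

## Numerical choices and degenerate inputs

* Sample SDs use the n−1 denominator throughout; the summary-TEM identity
  carries the (n−1)/n correction explicitly.
* Terminal digits are defined on the 0.1-cm grid (measurements are recorded
  to one decimal in cm): digit = round(value/0.1) mod 10, with values
  snapped to the grid before extraction.
* Nonpositive or missing recorded measurements yield missing z-scores at
  the cohort level (junk readings are data, not programming errors); the
  scalar `lms_zscore` remains strict and raises on nonpositive input.
* Zero-variance inputs: Pitman and Pearson report an explicit undefined
  status; `mean_bias` of a single difference collapses the CI to the point;
  LoA and summary-TEM require n ≥ 2.
* All boundary rules are as stated: classification boundaries half-open,
  exclusion windows strict, stature range boundaries inclusive-valid.

## Problem sizes used in tests and acceptance

Property suites use the sizes at which their tolerances are meaningful and
cheap: LoA coverage at 10^5 draws (binomial tolerance ±0.005), Pitman
type-I error over 2,000 replicates of n = 100 (tolerance ±0.015 around
0.05), generator parameter recovery at ~1,000 pairs per team (3·SE bands),
and replicate-simulation recovery of summary statistics over 2,000
replicates of n = 234 differences.  The acceptance script completes in a
few seconds; the full test suite in well under a minute.

## Known limitations

* The synthetic LMS table is a stand-in: z-scores are internally coherent
  but not comparable to scores computed against official references.
* The generator's error model is additive-Normal plus point contamination;
  real device error is likely multimodal and scene-dependent.
* Repeat-measurement reliability (intra-/inter-observer TEM) is out of
  scope: the data model carries one manual and one aggregated scan value
  per child.
* Probabilistic record linkage is out of scope; matching is exact on ID.
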