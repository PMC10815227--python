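# Methods

`isomirome` screens circulating small-RNA sequencing data for isomiRs —
sequence variants of mature miRNAs — whose abundance tracks a continuous
clinical risk score better than the aggregated counts of their parent
miRNA.  This note records the models, the tunable parameters, the synthetic
cohort the package tests itself against, and the numerical and design
choices that were genuinely open.

## IsomiR classification

Each unique sequence is placed ungapped on the extended canonical axis
(5' precursor flank + mature sequence + 3' precursor flank).  Candidate
placements have a 5' offset in [−2, +4] and an implied 3' offset in
[−4, +4] (both configurable); the winner minimizes first the number of
internal substitutions, then the total offset magnitude, with ties broken
toward the canonical register (smaller |5' offset|, then |3' offset|, then
fewer seed-window substitutions).  Variant classes follow the standard
taxonomy: `iso_5p` / `iso_3p` (length change at one end only),
`polymorphic` (substitutions at identical length), `mixed` (both), and
`canonical`.  Bases beyond the mature span are extension bases, never
substitutions; they are compared with the precursor flank to call the
variant `templated` or (for a mismatching 3' addition) `non_templated`,
and `unknown` when the flank is unavailable.

The seed is positions 2–7 counted on the isomiR's own 5' end, because that
is the register in which the molecule engages targets.  Consequently any
5' shift is seed-changing, as is a substitution inside positions 2–7.
Internal insertions/deletions and A-to-I editing inference are out of
scope; the parent assignment of the input table is trusted.

## Quality gates

* **Hemolysis**: ΔCt = Ct(miR-23a-3p) − Ct(miR-451a) < 7 cycles passes,
  strictly; miR-451a is the erythrocyte marker, so a small difference
  means little red-cell contamination.
* **Library outliers**: features present (raw count ≥ 1) in ≥3 and ≥5
  libraries form two reference subsets; each library's detection count
  within the ≥5 subset is compared against the lower Tukey fence
  (Q1 − 1.5·IQR, quartiles by linear interpolation), OR-combined with a
  floor of 0.6 on the library's median Spearman correlation (on RPM over
  all features) with the other libraries.  The subsets are computed once
  over all libraries.  At 13 libraries any such rule has a small
  false-positive rate on healthy libraries (an extreme detection count a
  few counts under a tight fence); strict mode removes every flagged
  library and logs the detection count and median correlation that
  justified each removal.

## Abundance and the screen

Counts are normalized to reads per million using the matrix's own column
totals, before any feature filtering.  miRNA-level counts are the sum of
member isomiR raw counts (totals conserved exactly, so aggregated RPM
equals the sum of member RPMs).  A feature enters the screen when its mean
RPM > 5 and its maximum RPM > 50, both strict, at either level.  Dynamic
range is max/min RPM, undefined (reported NA) when the minimum is 0 —
a pseudocount would manufacture a number for a feature that simply
dropped out.

The screen computes Spearman ρ (midranks on ties; undefined for constant
vectors) between each feature's RPM and the score.  Features with
|ρ| ≥ 0.55 are candidates.  Their p-value is the fraction of score
shufflings whose |ρ| reaches the observed |ρ| — absolute value, because
negatively correlated markers are screened too — over n_perm = 10,000
shufflings by default.  One seeded permutation stream is shared by every
feature (and both levels), so the whole screen is jointly reproducible and
preserves the cross-feature dependence of the null.  The estimator is
count/n_perm, so exactly 0 is possible; an `add_one_smoothing` flag gives
(count+1)/(n_perm+1) for users who need positive p-values.

**Multiplicity.**  Benjamini–Hochberg runs per level, but over the full
family of screened features, with non-candidates entering as p = 1.
Correcting the candidates alone would be circular: a null feature only
becomes a candidate when its sample |ρ| is already in the null tail, so
candidate p-values are sub-uniform (≤ ~0.07 at n = 12) and a
candidates-only family lets essentially all of them through once a few
true signals occupy the top ranks.  The practical consequence at n = 12
with ~50–130 screened features is that only associations with |ρ| ≳ 0.9
can reach p-adj < 0.05 — weak-to-moderate correlations at this cohort
size are reported but not called significant, which we consider the
honest behaviour.

**Discrimination.**  The cohort is dichotomized at the 75th risk
percentile (score ≥ 75 is high).  AUC is the Mann–Whitney statistic with
ties counted 1/2, oriented "higher abundance predicts high risk" with no
automatic flip, so AUC < 0.5 is possible and the discrimination rule
(lower 95% DeLong CI bound > 0.5) naturally selects positively oriented
markers only.  With perfectly separated classes the DeLong variance is 0
and the CI collapses to a point; with fewer than 2 observations in a
class the CI is reported as [0, 1].

**Superiority.**  A candidate isomiR is superior to its parent when all
four hold strictly: higher |ρ|, lower p-adj (a parent that never entered
permutation testing counts as p-adj = 1), larger dynamic range, higher
AUC.  An undefined dynamic range or AUC on either side never wins a
comparison.  `isomir_only` marks isomiRs significant while the parent is
not — the headline scenario, strongest when the isomiR is seed-changing.

## Cholesterol efflux

Total efflux per well is 100·CPM_medium/(CPM_medium + CPM_lysate);
specific efflux subtracts the plate's no-plasma blank and may be slightly
negative (reported as-is).  Before averaging, the triplicate rule removes
every replicate whose total efflux deviates from the triplicate mean by
≥ 1.15 sample standard deviations (n−1 denominator), in a single pass.
With three values the maximum possible deviation is 2/√3 ≈ 1.155 SD, so
the rule only fires when the other two replicates agree closely, and it
can never remove more than one value (two deviations ≥ 1.15 SD would
exceed the fixed total squared deviation 2·SD²).  The rule is applied to
the derived efflux percentages rather than raw CPM — under that reading a
single bad well is detectable regardless of plating density; both the
CPM-level and iterative alternatives would be small local changes.
Efflux associations use Pearson's r: these are percentage-scale assay
values, not counts.

## The synthetic cohort

The generator emulates the shape of a small plasma sequencing study:
13 libraries with integer risk scores on the 0–99 percentile scale
(≈ 6:7 split around the 75th percentile, both sides always represented),
hemolysis Cts that pass ΔCt < 7 unless failures are requested, a 60-miRNA
catalog (mature 20–24 nt, 10 nt precursor flanks), and 2–6 isomiRs per
miRNA drawn from the edit vocabulary (5'/3' trims and templated
extensions of 1–2 nt, non-templated 3' A/U chosen to differ from the
flank, internal substitutions, a mixed variant); the first variant of
every parent is the 1 nt 5'-trim so each parent owns a seed-changing
isomiR.

Counts are multinomial per library over an intensity profile, at depths
spaced geometrically over 0.5–1.5 million reads (shuffled order).
Geometric spacing matters: detection counts are near-linear in log depth,
so the healthy libraries' ≥5-subset detection counts spread smoothly and
the QC Tukey fence behaves as it would at the real scale of hundreds of
thousands of features, where per-feature Bernoulli jitter is negligible.
Six "core" parents with high, across-patient-stable abundance
(overdispersion 0.02) pin ~90% of the library, as the dominant plasma
miRNAs do; without them the planted signals' swings would leak into every
null feature's RPM rank through the normalization denominator.  Remaining
null features get gamma multiplicative noise (dispersion 0.2, i.e.
negative-binomial-like counts, CV ≈ 0.45) around lognormal baselines
spanning the abundance filter, so a realistic fraction of features fails
it.

Planted features follow a Gaussian copula: the latent
z = a·u + √(1−a²)·ε with u the unit-variance normal scores of the
score ranks and a = 2·sin(π·ρ/6), so that the population Spearman
correlation of the (strictly monotone) multiplier exp(σz − σ²/2), σ = 0.9,
equals the requested `effect_rho`.  The default effect_rho = 0.9 is the
regime in which an association at n = 12 survives the full-family
correction.  miRNA-level signals ride on the canonical isomiR; the first
planted parent's canonical carries only ~45% of the parent's reads so the
isomiR out-performs its diluted aggregate (the superiority scenario), the
second ~85% (a robustly significant miRNA).  Each isomiR-only scenario
plants +ρ on the seed-changing variant and the mirrored −ρ (same latent z)
on a sibling, making the parent aggregate symmetric in z and hence
rank-uncorrelated with the score.  The optional outlier library zeroes
70% of the features every other library detects.  The efflux plate plants
specific efflux ≈ 11 − 0.08·score (+N(0, 1.5)) over a blank of 3–5%, and
displaces one replicate by 8–14 points in 5 samples to exercise the
triplicate rule.

What a green test does **not** establish: fidelity to any real cohort's
count distributions (the emulated study's deposited data are not used),
cross-mapping between paralogous miRNAs, adapter/quality artifacts, or
hemolysis effects on specific features.  Generator parameters are chosen
once for plausibility; the deposited series' per-sample distributions are
unknown to this package.

## Numerical notes

* Permutation comparisons use |ρ_perm| ≥ |ρ_obs| − 1e-12 to keep exact
  rank ties stable in floating point; the null matrix is evaluated in
  blocks of 2048 permutations to bound memory.
* Spearman is the Pearson correlation of midranks computed by one shared
  standardization path, so screen, QC inter-correlation and single-pair
  calls agree to machine precision.
* Quartiles for the Tukey fence use NumPy's default linear interpolation.
* Seeded streams: every generator stage derives an independent
  `default_rng([seed, stage])`; identical config and seed give
  byte-identical outputs.

## Known limitations

* At 13 libraries the outlier fence occasionally (≈1 in 60 seeded runs)
  flags one healthy library alongside a true outlier; removals are logged
  with their evidence so such cases are auditable.
* DeLong CIs are asymptotic and anti-conservative at n ≈ 12 with heavy
  ties; the discrimination flag should be read as exploratory, as in the
  emulated study.
* The permutation p-value floor is 1/n_perm (0 reported below it), which
  is what the count/n_perm estimator of the emulated protocol does.
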