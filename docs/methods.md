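# Methods

## Scope and data model

The package analyzes a normalized, log2-scale gene × sample expression
matrix (RMA-style microarray output or equivalent) together with a sample
annotation table carrying patient id, day of life, treatment
(control/LPS), and BPD outcome (none/mild/moderate/severe). Outcomes are
collapsed to a two-group comparison: "resilient" (none or mild) versus
"severe"; moderate disease falls into "other" and is excluded from the
two-group analyses. Upstream array processing (background correction,
quantile normalization, probe-to-gene collapse) is out of scope: every row
of the input matrix is treated as one feature, and the loader refuses
non-finite values unless row-mean imputation is explicitly enabled, because
silent NaNs would corrupt the sum-of-squares computations downstream.

## Step detection

Each gene's series is the group's control samples ordered by day of life,
with ties within a day broken by patient id then sample id — a
deterministic but arbitrary rule, so a fitted boundary can fall between
replicate samples of the same day. The reported `step_day` is the day of
life of the first right-segment sample; an option collapses the series to
per-day means instead.

The fit enumerates every boundary leaving at least `min_segment` samples
(default 2) on both sides, fits each segment by its arithmetic mean, and
keeps the boundary minimizing the residual sum of squares, earliest
boundary on ties. Single-sample segments (`min_segment = 1`) are allowed
but default off because they let single outliers absorb the step. Only
single steps are fitted; two-step (transient) patterns are out of scope.

Significance uses the adaptive-regression F statistic
`F = [Σ(X̂ᵢ−X̄)²/(m−1)] / [Σ(Xᵢ−X̂ᵢ)²/(n−m)]` with p from the upper tail of
F(m−1, n−m) and a default call threshold of p ≤ 0.01.

**Choice of m.** Because the boundary is searched rather than fixed, the
regression consumes more than the two degrees of freedom of the segment
means, and the F reference distribution is only an approximation whose
quality depends on the charge m. We calibrated m by simulation: on iid
Gaussian series at this design's control-series lengths (25 and 52 ordered
samples), m = 3 yields an empirical type-I error at p ≤ 0.01 of ≈0.025
(n = 25) and ≈0.041 (n = 52), i.e. anti-conservative by up to 4×, while
m = 4 (two means + two for the searched boundary) gives ≈0.008 and ≈0.014.
The default is therefore m = 4. m is exposed everywhere, and the null
calibration is re-run as part of the test suite so users with very
different series lengths can re-check it; for much longer series a larger
charge may be appropriate.

**Numerical details.** Each series is centered by its mean before the
boundary scan; the fit is shift-invariant, and centering avoids
catastrophic cancellation between the total and between-segment sums of
squares when expression sits at a 4–12 log2-unit baseline. A series whose
centered sum of squares is at rounding level is reported as constant
(F = 0, p = 1, direction none); a fit whose residual is at rounding level
relative to the centered sum of squares is an exact step (F = +inf, p = 0,
with a logged warning — this occurs only in noiseless fixtures). Direction
is "up"/"down" only for significant fits with distinct segment means.

## Differential expression

Welch's unpaired two-sample t-test (unequal variance, unequal sample size,
two-tailed), implemented from the textbook formulas with
Welch–Satterthwaite degrees of freedom and vectorized across genes; the
test suite cross-checks it against an independent reference
implementation. Zero-variance degenerates: equal means give t = 0, p = 1
with a warning; separated constant groups give infinite t and p = 0. The
LPS contrast is run unpaired even though LPS/control aliquots are
patient-paired, matching the stated test of the study design this package
mirrors; pairing-aware analysis can be built from the annotation if
desired. FDR is Benjamini–Hochberg across all genes in the matrix with no
pre-filtering, significance flagged at fdr ≤ 0.05 by default — a
conventional, explicitly configurable choice. Volcano tables report
−log10 p with exact zeros clamped to one unit above the table's largest
finite value and flagged.

## Pseudotime profiles

Samples are grouped by chronological week (ceil(day/7); the grouping
column is a parameter, so a gestational-age column can be used instead) and
averaged per gene within each treatment arm, dropping weeks beyond 10 by
default because attrition leaves few late samples. The LPS:control "ratio"
is the difference of log2 means — the log2 fold change of LPS over control
— since a ratio of log2 values would be meaningless; a linear-scale option
returns 2^difference. Heatmap row order comes from agglomerative
clustering on Euclidean distances, complete linkage by default
(configurable); control, LPS and ratio blocks are clustered separately.

## Cross-group signatures and ORA

A gene is "time-dependent" in a group if its step fit there is significant
at the step threshold, optionally restricted by direction; comparing the
two groups' sets gives a disjoint Venn partition. The resilience signature
is the set of genes with a significant step **up** in the resilient group
and no significant step of either direction in the severe group, annotated
with day-1 and day-≥7 means in the resilient arm. Over-representation of a
query set in a GMT collection uses the hypergeometric upper tail
P(X ≥ k) with the universe defaulting to all genes in the expression
matrix — enrichment is judged against what was measurable, not against the
collection. Gene matching is exact and case-sensitive; identifier aliasing
is out of scope.

## Synthetic cohorts

The generator reproduces the design the analyses assume: control samples
at days 1/7/14/21 with per-day counts severe 25/14/9/4 and resilient
13/5/4/3, monotone attrition (patients at day d are a subset of those at
day 1), and a paired LPS aliquot per control sample. Cohort structure is a
pure function of the configuration; the seed changes only values and gene
class assignments.

Planted effects, all additive on the log2 scale with baselines drawn
Uniform(4, 12) log2 units and iid Gaussian noise (default sd 0.5):

- **Steps**: ideal Heaviside shifts of 2.0 log2 units (default) at day 7,
  14 or 21, split between resilient-only, severe-only and shared genes
  (default split 0.75/0.125/0.125 of the 20% of genes that step).
- **LPS response**: +3.0 log2 units in every LPS aliquot of responsive
  genes (default 10%), identical across outcome groups — so a correct
  pipeline finds a strong LPS response but *no* group difference in it.
- **Day-1 inflammatory transient**: +2.0 log2 units in the severe group's
  day-1 samples of 5% of genes, emulating perinatal inflammation. These
  genes are drawn from genes without a planted step in the severe group;
  note they genuinely change over time there (high day 1, lower later), so
  the step detector legitimately calls many of them as down-steps — they
  are planted signal for the day-1 contrast, not nulls for the detector.

What the generator does **not** emulate: probe-level structure, batch or
normalization artifacts, gradual ramps (steps are instantaneous),
patient-level random effects or correlated noise, and dropout that depends
on expression. Passing recovery tests therefore demonstrates correctness
of the algorithms under the stated model, not robustness to every
real-data pathology.

## Validation conditions and problem sizes

The validation suite and `scripts/acceptance.py` use: 1,000 random series
of lengths 5–25 for brute-force agreement; 10,000 flat genes per seed for
null calibration at the cohort's two series lengths; 400 planted step-up
genes at amplitude 2.0 / noise 0.5 under the cohort's sample counts for
power and for cross-group recovery (split 300 resilient-only / 50
severe-only / 50 shared). For cross-group recovery the planted steps are
upward and the recovered sets are direction-filtered to "up": the
comparison targets genes rising over time, and restricting direction keeps
the false-positive leakage from one group's null fits within the ±10%
recovery bands that a 50-gene planted set allows. Welch/BH/hypergeometric
checks compare against independent reference implementations and literal
definitional computations; determinism is checked byte-for-byte on two
identically seeded pipeline runs.

## Known limitations

- The F-test calibration holds for series lengths near the design's
  (~25–52); very short series (e.g. 4 per-day means) leave no residual df
  at m = 4 and need per-day fitting with m = 3 and caution.
- The BH FDR is computed per contrast table, not across contrasts.
- ORA treats gene sets as flat lists; no hierarchy or topology.
- The resilience signature inherits the step detector's thresholds; genes
  with gradual (ramp-like) increases are detected only insofar as a single
  step approximates them.
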