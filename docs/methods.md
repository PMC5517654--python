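# Methods

## Model and procedure

The pipeline treats each brain-region dataset as a gene × sample log2
expression matrix with per-sample metadata (individual, age in days,
data source, region). Each dataset is split at a turning age τ (default
20 years, converted as τ × 365.25 days; a sample at exactly τ belongs to
aging) into development and aging sub-datasets. Expression change within
a sub-dataset is modeled monotonically: the per-gene statistic is the
Spearman correlation ρ of expression with age in days, so any strictly
monotone transform of ages or expression leaves the analysis unchanged.
Two-sided p-values use the t-approximation for n ≥ 10 samples and exact
enumeration of age orderings below that; Benjamini–Yekutieli adjustment
(valid under arbitrary dependence) is applied per sub-dataset. Constant
expression rows have no defined correlation and are reported as ρ = 0,
p = 1, direction "flat"; flat genes are excluded from all consistency
and classification statistics, since a zero has no sign.

Reversal classification maps the sign pair (direction in development,
direction in aging) to up-down, down-up, up-up or down-down, with no
effect-size or significance cutoff. Consistency across datasets is
unanimity: a gene must be present and carry the same direction (or
pattern) in every dataset.

## The structured permutation null

Datasets from one source share individuals across regions, so neither
genes nor datasets are independent. The null of "no age effect" is
simulated by permuting individual ages uniformly within each
(source, period) block and propagating each individual's permuted age to
all of its samples in every region of that source. Expression is never
touched, so the full gene–gene and dataset–dataset correlation structure
is preserved; period membership is preserved because permutation stays
within the period block. Every permutation replicate re-runs the full
trend → classification → statistic chain. Because expression ranks do
not change under age permutation, the engine pre-ranks expression once
per sub-dataset and each replicate costs one matrix–vector product per
sub-dataset, which keeps 1,000-replicate tests at interactive speed.

One-sided significance uses the add-one estimator
p = (1 + #{null ≥ observed}) / (1 + N), so the smallest attainable p is
1/(N+1); the expected count is the null mean, and the FDR estimate is
expected/observed capped at 1.

**Calibration diagnostics.** The consistency statistic is an integer
count that takes few distinct values in small studies, so the add-one p
is discrete and conservative: its distribution under the null is a valid
but atomic sub-uniform law, and a continuous-uniformity test applied to
it would reject for discreteness alone. `PermutationResult.randomized_p`
therefore implements the randomized p-value
(#{null > obs} + U·(1 + #{null = obs})) / (1 + N), U ~ Uniform(0,1),
which is exactly Uniform(0,1) whenever the observed statistic is
exchangeable with the null draws. Calibration tests use the randomized
p; all reported decisions use the conventional add-one p.

## Conditional enrichment

For a gene set in one dataset, the 2×2 table holds the reversal pattern
vs. the developmental-direction-matched monotone pattern (up-down vs
up-up, or down-up vs down-down) against set membership, over the genes
classifiable in that dataset. OR = (a·d)/(b·c) on raw counts; a single
zero in b or c yields an infinite OR, which satisfies the only criterion
ever applied (OR > 1), so no continuity correction is used. Tables with
an empty margin are undefined and such sets cannot count as shared in
that dataset. Sets smaller than 10 members are skipped by default
(configurable to 1). The shared-set count (OR > 1 in every dataset) is
tested with the same structured permutations. Identical-membership sets
are deduplicated to the lexicographically smallest name before scoring.

## Trajectory clustering and peak ages

Per gene and dataset, expression is standardized to mean 0, s.d. 1
within that dataset (per-dataset standardization keeps datasets with
different dynamic ranges commensurable), then a smoothing spline of the
standardized values against the fourth root of age in days is fitted
with the GCV-selected smoothing parameter (`scipy.interpolate.
make_smoothing_spline`; duplicate ages are averaged first) and evaluated
at 20 equally spaced grid points spanning the dataset's observed
fourth-root range. The fourth-root scale spreads individuals roughly
evenly over the lifespan. Genes with fewer than four distinct ages in a
dataset cannot support the spline and are dropped with a log entry;
constant genes standardize to the zero trajectory. Concatenated grids
(20 × n_datasets features per gene) feed best-of-restarts k-means
(default 10 restarts, seeded, ties at equal distance resolved by scikit-
learn's lowest-index convention). A cluster's peak age in a dataset is
the grid age of its mean trajectory's maximum (earliest grid point on
ties), converted back to years; the cross-dataset median is reported as
the cluster summary.

## Deconvolution

Each bulk sample's profile over the genes shared with the signature
matrix is regressed by OLS, with intercept, on the per-cell-type mean
expression profiles: Z = α + Σ βₖ ζₖ + ε. Coefficients are deliberately
unconstrained — no non-negativity, no sum-to-one — because the βₖ are
interpreted only as relative contributions whose *age trends* matter; a
normalized view β/Σβ is available for reporting. Near-collinear
signatures are flagged with the design condition number, and fewer than
50 shared genes triggers a warning. Age trends are Spearman correlations
of each coefficient with sample age, with coefficient vectors whose
spread is at rounding-error level treated as constant (ρ = 0).

## Cross-study comparisons

Differentiation series have three ordinal stages (iPSC, neurosphere,
neuron); stage trends are Spearman correlations against the stage index
and the differentiation-up set is {q < 0.05, ρ > 0}. The conditioned
reversal proportion in a dataset is n(up-down)/(n(up-down) + n(up-up))
among the conditioning genes (down-up vs down-down for disease sets
conditioned on down-regulation); the ">50% reversal" criterion is
strict. Two permutation schemes assess it:

- structured age permutations of the age-series (aging ages only when
  the question is about aging behavior of development-defined genes, and
  vice versa), per dataset and overall (count of datasets above 50%
  against joint permutations);
- label permutations of the external study with top-N surrogates: after
  shuffling stage or case/control labels, genes are re-ranked by the
  permuted effect (stage ρ; or cross-cohort consistency count with mean
  shift as tie-break) and the top N genes — N fixed at the observed
  conditioning-set size, intersected with the required developmental
  direction where the proportion demands it — replace the conditioning
  set. This keeps null proportions on sets of the observed size instead
  of the unstably small significant sets of permuted data. With
  unshuffled labels the construction reproduces the observed statistic
  exactly (significance thresholds are monotone in the ranking effect).

Disease (AD-style) per-dataset direction is the sign of the case-mean
minus control-mean difference; consistent disease genes are unanimous
across cohorts. The development/disease overlap proportion is
|dev-up ∩ ad-down| / (|dev-up ∩ ad-down| + |dev-up ∩ ad-up|), reading
"proportion of A to B" as A/(A+B); the plain A/B ratio is also emitted.

Note a deliberate property of the overall ">50% in k datasets" count:
when the transcriptome background itself is rich in reversal (as when
many reversal genes are planted), random same-size surrogate sets also
exceed 50%, so the overall count can stay non-significant even when the
conditioning set is itself almost purely reversal — the statistic
measures *excess over the background*, which is exactly the control it
is designed to provide.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the structure of real multi-laboratory brain
age-series: n_sources sources, each with its own individuals shared
across that source's regions, ages drawn uniformly on the fourth-root-
of-days scale from 0 to 98 years so both periods are dense, one sample
per individual per region. Planted genes follow one of the four patterns
as trends linear in the within-period age rank with amplitude equal to
the period effect size (so rank-based statistics see exactly the planted
effect); noise is Gaussian, independent across genes and regions, with
aging noise (default s.d. 1.0) above development noise (default 0.5) to
reproduce the empirically higher aging-phase stochasticity. Defaults — 2
sources with (2, 3) regions, 20 development + 25 aging individuals per
source, 2,000 genes, 5% of genes per planted pattern, unit effect sizes
— keep full analyses at minutes scale; per-period effect-size
distributions of real tissue are unknown, so these are calibration
choices, not estimates.

Deliberately not emulated: probe-level microarray structure, batch and
platform effects, gene–gene co-expression beyond shared individuals,
discontinuities at the turning age (each period's trend is generated
independently), and region-specific biology. Passing tests therefore
demonstrate statistical correctness — calibrated nulls, recovery of
planted signals, agreement with closed-form oracles — not robustness to
real-data artifacts.

Two generator-dependent consequences are worth noting. First, because
planted trends are linear in the within-period rank, splitting earlier
than the true turning age leaves both periods sign-consistent; in
turning-age sweeps the consistent-reversal count therefore plateaus up
to the true turning age and declines beyond it, rather than peaking
sharply at it. Second, auxiliary generators (gene sets, differentiation,
case/control) can draw their planted genes from the planted reversal
genes to create genuine conditional overlap, or from null genes to
create calibrated independence.

## Numerical choices and limitations

- Ages are stored in days; year thresholds convert at 365.25 days/year.
- Rows with missing values are dropped at load with a logged count.
- Quantile normalization maps midranks onto the across-sample mean of
  sorted columns, interpolating fractional (tied) ranks.
- PCA centers features (genes), never scales; each component is oriented
  so its largest-magnitude loading is positive, for reproducible output.
  Outliers beyond 4 s.d. on PC1/PC2 are reported, never auto-removed.
- All randomness flows from seeded `numpy.random.Generator` streams; the
  pipeline derives per-stage seeds from one root seed (CRC-mixed, below
  2³¹), and reruns with identical configs are byte-identical.
- Problem sizes in the test suite and acceptance script (hundreds to a
  few thousand genes, 10–20 individuals per period, 99–200 permutations,
  100–200 calibration replicates) are chosen to exercise every code path
  at minutes scale; statistical conclusions at these sizes carry the
  quoted Monte-Carlo error bars (3 binomial s.e. bands, KS at 200
  replicates).
- The overall cross-study count statistic saturates with few datasets
  (its null maximum is not rare below ~5 independent sources); per-
  dataset p-values remain informative there.
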