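# Methods

This note records the statistical conventions the package implements, the
choices that were genuinely open, and what the synthetic benchmark does and
does not demonstrate.

## Input model

The pipeline consumes a label-free quantification (LFQ) intensity table:
proteins × samples, nonnegative intensities typically between 10⁶ and 10⁸,
with peptide-evidence counts per protein and a sample → group annotation
(`resilient`, `susceptible`, `control`). A stored `0` or blank is treated as
*missing*, not as zero abundance — the standard LFQ encoding for "not
quantified in this run". The reader is non-destructive: evidence filtering,
imputation and scaling are explicit downstream stages, never side effects of
I/O.

## Preprocessing conventions

- **Evidence filter.** A protein is kept only if it has ≥ 2 peptides *and*
  ≥ 2 unique peptides; a single peptide match or a single unique peptide is
  each sufficient for exclusion. Defaults are configurable
  (`min_peptides`, `min_unique`).
- **Imputation.** Each missing cell is replaced by the mean of that
  feature's non-missing values across *all* samples. Using the all-sample mean
  rather than a per-class mean avoids writing the class labels into the
  features before classification; the median is available via
  `impute="median"`. A feature with no observed value cannot be imputed
  from itself and is dropped with a warning. Imputation is idempotent.
- **Standardization.** Per feature: subtract the mean, divide by the
  population SD (divisor *n*, the usual ML-preprocessing convention;
  `sd_divisor="n-1"` selects the sample SD). Zero-variance features map to
  all-zeros and their SD is recorded as 0. Standardization is fit once on
  all samples before the cross-validated stages; this mirrors common
  practice in small-n omics pipelines but does leak fold-external
  information into the scaling — `standardize_train_only` provides the
  fold-scoped alternative for sensitivity analyses.

## Differential expression

Fold change is the ratio of group means of the imputed *raw* intensities,
oriented numerator/denominator (default resilient/susceptible). The test is
a two-tailed unpaired *t*-test — pooled-variance Student by default, since
that is what the unqualified term means; Welch via `variant="welch"`.
Multiplicity is handled by Benjamini–Hochberg step-up adjustment. The
regulation call requires all three gates: FC ≥ 1.2 (up) or FC ≤ 0.80
(down), *p* < 0.05 and *q* < 0.05. The p-gate is redundant given the q-gate
under BH but is enforced as stated. Degenerate zero-variance features get
*p* = 1 when the group means agree, and the smallest positive float
otherwise (logged). Volcano coordinates use −log₁₀ of the adjusted
*q*-value by default (`volcano_y="p"` exports the raw-p variant, since
either reading of a volcano y-axis is common). PCA treats samples as
observations of the standardized features; explained fractions are
eigenvalue shares.

## Class separation

A feature separates the classes when min(class A) > max(class B) or vice
versa, with *strict* inequality — a shared boundary value does not count.
The separating flag depends only on the ordering of values, so it is
invariant under any strictly increasing transform. The score is the
absolute difference between the two nearest standardized values from
different classes; for a separating feature this equals the standardized
gap high_class_min − low_class_max, and it is invariant under positive
affine transforms of the raw feature because standardization absorbs them.
Under the null of exchangeable continuous values, the chance that 8 + 8
samples produce disjoint supports is 2/C(16,8) ≈ 1.6 × 10⁻⁴ per feature,
so a ~1,400-feature screen produces ≈ 0.2 false flags per dataset; the test
suite checks the Monte-Carlo rate against this combinatorial value.

## Sequential feature selection

The base learner is a linear SVM with L1 penalty (squared hinge,
C = 1.0 by default and configurable, tol 1e-4, deterministic solver
settings). Classifier quality is the **unweighted mean of per-fold test
accuracies** under stratified 7-fold CV. On 16 samples the folds have sizes
3,3,2,2,2,2,2, which makes the characteristic score values visible in
ranked outputs: six perfect folds plus 2/3 on a size-3 fold give
(6 + 2/3)/7 ≈ 0.952, and the complementary gains 1 − 0.952 ≈ 0.048 and
1 − (6 + 1/2)/7 ≈ 0.071. Pooled sample accuracy (x/16) cannot produce these
values, which is why the fold-mean convention was adopted.

The greedy search starts from the empty set, whose baseline accuracy is
defined as **0**, so the first selected feature's score equals its full CV
accuracy while every later feature's score is a small increment. This
reproduces the two regimes seen in repeated runs — first-pick scores
clustering near 0.94–0.952 and later-pick scores near 0.048–0.071 — and
their mixtures (a feature sometimes picked first, sometimes second, shows a
bimodal score distribution with a large SD).

Selection stops when accuracy reaches 1.0 or when the best candidate's gain
is ≤ 0. Ties in accuracy are broken by the earliest position in the
shuffled candidate order, which is what makes the 100 repetitions with
re-shuffled order informative; fold assignment is also reseeded each
repetition. Child seeds derive from the master seed via
`SeedSequence(master, spawn_key=(stream, repetition))`, so repetitions are
independent and the whole procedure is reproducible from one integer.
Class-separating features are masked out of the candidate pool before the
search: each of them alone ends the search at 100% accuracy in one step and
would hide jointly-informative, non-separating feature sets.

Implementation detail: per-candidate CV evaluation is abandoned as soon as
even perfect remaining folds could not strictly beat the incumbent best.
This branch-and-bound pruning is exact for the argmax and preserves the
tie-break, and the inner fold fit calls liblinear directly (coefficients
identical to `LinearSVC.fit`, asserted in the test suite, with a public
fallback path).

## Random-forest ranking

Importances are mean decrease in Gini impurity from a bootstrapped,
random-subspace forest, normalized to sum to 1 per repetition.
Hyperparameters (trees ∈ {100, 300, 500}; subspace rule ∈ {√p, log₂p,
0.1p}; min leaf ∈ {1, 2}) are chosen once by maximizing out-of-bag
accuracy, ties broken by grid order. The ranking statistic across the 100
repetitions is per-feature mean importance ("RF score"), its population SD,
and **times selected**, defined here as the number of repetitions in which
the feature ranked inside the top-k importances (k = 50 by default,
configurable and recorded in the report). A membership criterion is needed
because "selected" is not intrinsic to an importance vector; top-k
membership yields counts well below the repetition total for mid-ranked
features, with never-entering features reported as 0, matching how such
tables are usually read.

## Synthetic data

The generator emulates the study conditions the pipeline targets: 1,400
proteins over 8 + 8 samples; per-protein log₁₀ abundance drawn from
N(7.0, 0.6) with within-feature log₁₀ noise SD 0.15 (≈ 35–40% CV, a
realistic LFQ technical-plus-biological spread); 350 differential proteins
with |log₂FC| uniform on [0.4, 2.0] applied multiplicatively to the
susceptible group (so resilient-vs-control is a null contrast), signs
alternating; 45 class-separating proteins with standardized margin ≥ 1,
directions alternating between classes; and 2 planted feature pairs that
overlap marginally one-by-one while their sum separates the classes with a
comfortable margin. Missingness is completely at random at rate 0.05
(an intensity-dependent left-censoring mode exists for stress testing),
capped so every feature keeps ≥ 2 observed values per group; 5% of noise
proteins get deficient peptide evidence to exercise the filter.

Generator contract worth stating explicitly: planted-role features
(differential, class-separating, pair-separable) are exempt from
missingness and from the low-evidence fraction, and differential features
are nudged to keep overlapping class supports. Without this, feature-mean
imputation could place an imputed value inside a planted gap, the evidence
filter could delete planted signal, and strong mean shifts could create
*accidental* separators — all of which would make ground truth ambiguous.
The class-separating and pair-separable features are written to the
intensity scale by a positive affine map of their construction scores, so
standardizing the stored table reproduces the planted standardized geometry
exactly.

The phenotype labeling rule is included as a single operation: an animal is
susceptible iff its sucrose-preference decrease from baseline is ≥ 30%
(boundary inclusive), resilient otherwise; a zero baseline is an error.
The companion idea of "not significantly different from baseline" is *not*
implemented as a test — the generator needs labels, not inference.

What passing on synthetic data does **not** show: real LFQ matrices have
correlated features, batch structure, intensity-dependent missingness and
heavier tails; the generator's features are independent given their roles
and its missingness is MCAR by default. Recovery results here validate the
*machinery* (the screen finds exactly the disjoint-support features; the
masked SFS finds a jointly-separable pair; RF ranks strong effects on top),
not field performance on any particular real dataset.

## Problem sizes and numerics

The bundled checks run the repeated SFS at 100–300 features × 16 samples ×
100 repetitions and the repeated RF at ≈ 200 features × 100 repetitions —
sizes chosen to exercise every code path at interactive runtimes (roughly a
minute each on one CPU) while matching the 8 + 8 sample geometry that fixes
the fold arithmetic. Determinism is end-to-end: one master seed, derived
child seeds per stage and repetition, `svd_solver="full"` for PCA, and
fixed float formatting in all outputs, so identical configs produce
byte-identical result bundles. Oracle cross-checks (BH step-up definition,
brute-force nearest-pair margins, eigendecomposition PCA fractions,
exhaustive first-pick scans) are kept in the test suite at 1e-8 or tighter.

## Known limitations

- No between-sample normalization stage (median/quantile); the pipeline
  assumes comparably scaled columns, as its target data were.
- Global standardization leaks scaling information across CV folds (see
  above); the fold-scoped variant is provided but not the default.
- The SFS explores single additions only — no backward steps, no floating
  search, and C is not tuned inside the CV.
- With control samples present, all screening is pairwise per contrast;
  no three-group statistics are attempted.
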