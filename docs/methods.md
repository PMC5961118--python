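# Methods

This note documents the statistical machinery in `phenoinfer`, the choices
made where the design was genuinely open, and what the simulation-based
tests do and do not demonstrate about real data.

## Data model and contracts

The feature unit is the *expressed region*: a contiguous genomic interval
with coverage above a cutoff in annotation-agnostic RNA-seq
summarization. `ExpressionMatrix` holds a |regions| × |samples| matrix of
non-negative values with BED-convention coordinates (0-based, half-open;
region IDs `chrom:start-end` use these literally; strand is ignored).
Coverage discovery and library-size normalization are upstream of this
package.

Raw coverage is transformed as `log2(1 + x)`. The pseudocount keeps the
transform defined at zero and order-preserving; it maps 0 → 0. Because the
original transform convention of any given upstream pipeline may differ,
the transform is explicit, refuses double application, and users with
pre-transformed matrices simply skip it. The choice is recorded in model
provenance.

Phenotype tables never drop rows. Each cell is canonicalized against a
per-column synonym map (e.g. "M"/"Male"/"m" → male) and classified as
usable, missing, or non-meaningful ("not collected", "Unknown", ...). The
distinction matters because the evaluation denominators depend on *why* a
value is unusable, and because predictions are still made for samples
without usable reported values — filling those gaps is the point.

## Variance moderation

Per-region one-vs-rest regressions at genome scale have few residual
degrees of freedom each, so region variances are shrunk by empirical
Bayes: true variances are modeled as scaled inverse-χ²(d₀, s₀²), the
hyperparameters fitted by the standard method of moments on
`e_r = log s²_r − ψ(d_r/2) + log(d_r/2)` (with a Newton inversion of the
trigamma function), and each region receives the posterior

    s̃²_r = (d₀·s₀² + d_r·s²_r) / (d₀ + d_r).

Moderated t = α̂_r / (s̃_r·c_r) is referred to t with d_r + d₀ degrees of
freedom; when the moment estimate implies no excess spread, d₀ = ∞, every
variance collapses to s₀² and the reference distribution is normal. One
test verifies the whole chain against Bioconductor limma's `eBayes` on a
shared fixture (agreement ~1e-15); limma is an oracle there, never the
implementation.

Two numerical edge cases: regions with zero variance across the design
samples get t = 0 and p = 1 and are never selected (their statistic is
undefined and they carry no signal); and when all observed variances are
equal, the fitted common scale is s²·exp(log(d/2) − ψ(d/2)) — the
finite-df log-scale bias correction — rather than s² itself, which matches
the reference behaviour and leaves all rankings unchanged.

## Marker selection

Selection is per level, one-vs-rest, two-sided (markers may be under- or
over-expressed in a level), with covariates supported in the design but
off by default so the selected markers generalize across datasets. The
ranking is deterministic: p ascending, then |t| descending, then region
index. Per-level top-n lists are pooled and deduplicated; |S| ≤ n × L.

A structural note for two-level phenotypes: the two one-vs-rest
indicators are complements, so the two fits are the same regression up to
sign and the per-level rankings coincide; the union then has exactly n
regions, and capturing all planted markers in simulations requires n at
least the total marker count.

### Chunked selection

Genome-scale inputs arrive chunk-wise (e.g. per chromosome).
`filter_regions` fits and ranks within a chunk, keeping the top `n_keep`
per level together with each region's raw coefficient and sample variance
— reusable because per-region fits do not depend on other regions — plus
the chunk's *sufficient moments* of the adjusted log variances over all
fitted regions. `merge_input` pools the moments, which reproduces the
global method-of-moments hyperparameters exactly, recomputes p-values for
the retained regions under that global prior, and re-ranks. A single-chunk
partition is therefore exactly equivalent to unchunked selection by
construction; multi-chunk partitions are equivalent whenever `n_keep`
retains every globally top-n region, for which `n_keep ≥ n` per level is
required and `n_keep = 2n` is a comfortable default in practice.

## The categorical predictor

On the selected set S, expression is regressed per region on the L
disjoint level indicators with no intercept under β ≥ 0 (solved as
constrained least squares, so the contract survives covariate extensions;
with disjoint indicators the solution is the clipped per-level mean). The
constraint is β ≥ 0 rather than a strict inequality — a strict constraint
has no least-squares meaning — and all-zero rows/columns are flagged
rather than dropped.

Prediction projects each sample onto the profiles by non-negative least
squares. The membership vector γ is reported raw: it is produced by
constrained projection, not a probability model, so it is not normalized
to sum to one (normalization would silently change tie behaviour), and the
projection residual norm is exposed alongside. The label is the level of
the unique maximum; the tie rule needs an operational definition because
floating-point maxima never tie exactly, so "tied" means two or more
weights within a relative tolerance (default 1e-8, user-settable) of the
maximum, and a zero maximum always abstains.

`extract_data` restricts a new matrix to exactly S, in order — regions are
never re-selected on new data, which bounds overfitting. Strict mode
errors on any missing region; lenient mode zero-fills, warns, and records
the count in provenance.

## Continuous phenotypes

Knots are placed at equally spaced quantiles of the observed values
(l knots for an l-function basis). Coverage is zero-inflated, so the
quantile grid often collapses at the minimum; the rule then pins the first
knot there (zero for coverage) and spreads the remaining l − 1 knots over
the quantiles of the strictly larger values. The basis is the *cardinal*
natural cubic spline basis on those knots: the l natural splines
interpolating the unit vectors. It spans the full natural-spline space —
including constants, since cardinal functions sum to one — which makes the
intercept implicit. Evaluation is exactly linear beyond the boundary knots
(the defining natural-spline tail), implemented as value-plus-slope
continuation.

Region selection regresses expression on the spline basis of the
phenotype (intercept plus the l − 1 non-redundant columns) and ranks by
the moderated F over the spline coefficients jointly — the joint test was
chosen over best-single-coefficient because it is the natural two-sided
notion of "associated with the trait in any smooth way"; under the null it
follows F(l−1, d+d₀), which the test suite verifies by KS across 20 seeds.

The predictor is one joint least-squares fit of the phenotype on the
concatenated per-region expansions. Each region's block spans constants,
so the joint design is rank-deficient by |S| − 1 at minimum; collinear
columns are pruned by pivoted QR (threshold `max(n,p)·eps·|R₁₁|`), their
indices recorded, and their coefficients set to zero. Knots derive from
each region's *training* expression and are frozen thereafter; re-deriving
them on new data would silently change the model. Predictions beyond a
region's boundary knots use the linear tails and set a per-sample
extrapolation flag. Accuracy is summarized by RMSE and R² as the squared
Pearson correlation of observed and predicted (the convention used for
reporting; the sklearn estimator's `score` keeps the coefficient of
determination).

`n_regions·l` must not exceed the training sample count; the default of
100 regions × 5 basis functions suits cohorts of ≥ 500 samples, and the
error message says to select fewer regions otherwise.

## Tuning and evaluation

`optimize_num_regions` evaluates a candidate grid (default
{10, 20, 40, 60, 80, 100, 150, 200}, spanning 10–200) by resubstitution
accuracy and returns the *smallest* candidate attaining the maximum —
prediction cost grows with |S|, so ties break toward fewer regions.
Degenerate candidates record NaN and leave the argmax. The result is
invariant to candidate order.

Accuracy counts only samples whose reported value is usable and among the
model's levels; exclusions are tallied by reason (missing,
non-meaningful, level-not-in-model). Unassigned predictions remain in the
denominator as errors — the conservative reading, since abstention on an
annotated sample is a failure to recover its annotation. In one-vs-rest
sensitivity/specificity, unassigned counts as a negative for every level
(FN of the true level, TN of the rest); undefined ratios are NaN, never 0.
A predictor is marked releasable at ≥ 85% training accuracy.

The sequencing-strategy audit cross-checks reported single/paired layout
against counted reads and archive spots. The default rule flags
reported-single with reads > spots as actually-paired and reported-paired
with spots = 2 × reads as actually-single, exactly as specified upstream;
because paired runs semantically yield reads = 2 × spots, the second
condition looks inverted, so an `inverted` rule (paired with
reads = spots flagged) is exposed without silently changing the default.

## The synthetic generator

`simulate_categorical_dataset` draws baseline region means from a
lognormal (right-skewed, like coverage), adds an effect δ to m disjoint
marker regions per level, adds Gaussian noise, floors at zero, and zeroes
entries with probability π. Reported labels are deliberately messy (mixed
synonyms, "Unknown", blanks) to exercise canonicalization. Reference
conditions: 2 levels in equal proportion, m = 20, δ = 3.0 (log2 units),
σ = 1.0, π = 0.05, 400 samples × 500 regions. The continuous generator
plants regions whose expression follows a linear or smooth nonlinear
function of an age-like trait (uniform on [20, 70]).
`simulate_mislabeled_dataset` flips a fraction of reported labels while
expression still follows the truth, reproducing the situation where
measured accuracy understates true accuracy.

What the generator does *not* emulate: correlated regions, batch and lab
effects, within-level heterogeneity (tissue mixtures, disease states),
library-size artefacts, or realistic zero-inflation structure (dropout
here is uniform, not expression-dependent). Passing tests therefore show
the machinery is correct and well-calibrated under its assumed model —
separable level-specific mean shifts — not that any particular accuracy
will be achieved on archive data, where misannotation, heterogeneity and
batch structure dominate the error budget.

Two attenuation effects of the generator are worth knowing when reading
tests: zero-inflation and flooring pull observed region means below the
planted means, so estimator-consistency checks (coefficient recovery,
planted-marker capture) run with π = 0, where the model's mean structure
is exactly the planted one.

## Problem sizes and numerical choices

Simulation-backed tests and the acceptance script use 20 replicate seeds
at the reference conditions above; these sizes give binomial/sampling
noise comfortably inside the asserted margins (e.g. SD ≈ 0.8 percentage
points for the across-seed mean of null accuracy) while keeping the whole
suite around ten seconds. Null-model comparisons are made on across-seed
means, because a single 200-sample held-out accuracy carries ±3.5-point
noise.

Serialization: expression TSVs use 10 significant digits (readable,
reproducible round-trips); predictor coefficient tables use 17
significant digits and are re-read with round-trip float parsing, so a
deserialized model reproduces predictions bit-identically — the archive
is the model, not an approximation of it. Model JSON records the level
order or knot vectors, the pruned columns, the tie tolerance, and
provenance (seed, region count, transform flag, version). CLI stages
derive their seeds from the global seed as
`(seed·1000003 + crc32(command)) mod 2³¹` so each stage is independently
reproducible.

## Known limitations

- Tissue-style predictors with many levels are supported but the bundled
  generator only exercises small level counts; cancer-vs-healthy shifts
  and other within-level structure are out of scope.
- γ is a membership weight, not a calibrated probability; no multi-label
  assignment is attempted.
- The moderated model has no duplicate-correlation/random-effect or
  variance-trend extensions.
- Chunked selection is exactly equivalent to global selection only when
  chunk `n_keep` retains the global top-n per level; the package cannot
  detect a violation after merging, so choose `n_keep ≥ n` (ideally 2n).
- Age-like continuous traits showed essentially no held-out signal in the
  motivating application; the continuous machinery is included and
  verified on synthetic signal, but real continuous phenotypes may simply
  not be predictable from coverage.
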