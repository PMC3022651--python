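# Methods

## The statistical model

The package asks one question of a collection of expression studies:
which genes co-vary with a chosen target gene (the motivating use case
is *Nnat* in mouse white adipose tissue)? Evidence is combined across
studies at the statistic level rather than by pooling samples, because
the studies use different platforms, tissue depots and designs.

Per dataset *i* with *n<sub>i</sub>* samples, every gene's profile is
correlated with the target's profile (Pearson *r*). The correlation is
mapped to a t-statistic,

    t = r * sqrt(n - 2) / sqrt(1 - r^2),   df = n - 2,

and normalized to a z-score *T<sub>i</sub>* by pushing *t* through its
CDF and back through the standard-normal quantile. The per-dataset
z-scores are combined with sample-size weights w<sub>i</sub> = n<sub>i</sub>:

    Z = sum_i(w_i * T_i) / D

with two denominator conventions, both implemented and switchable:

* `sum_weights` (default): D = Σ w<sub>i</sub>. This is a weighted
  *mean* of z-scores; under the null its variance is
  Σw²/(Σw)² &lt; 1, so it is conservative.
* `rss_weights`: D = sqrt(Σ w<sub>i</sub>²), the classical Stouffer
  denominator that makes Z exactly standard normal under the null.

The default follows the sum-of-weights form; the Stouffer form is kept
because it is the convention that actually delivers the unit-variance
null the two-tailed p-value assumes. The combined Z is converted to a
two-tailed normal p (via `erfc`, accurate beyond |z| = 6) and
Bonferroni-adjusted over the universe *m* of genes that survive
filtering in at least one dataset. The family-wise cut is
p·m &lt; alpha (default 0.05).

A gene missing from a dataset (not on the platform, or filtered out
there) is combined over the datasets where it is present, with the
missing dataset's weight dropped from the denominator.

An alternative combination via Fisher's variance-stabilizing transform
is provided: ζ = atanh(r), var(ζ) ≈ 1/(n−3), combined as
Σ(n<sub>i</sub>−3)ζ<sub>i</sub> / sqrt(Σ(n<sub>i</sub>−3)). On well-behaved
data it ranks genes nearly identically to the weighted-Z route (checked
by a Spearman-correlation test).

### Filtering and probeset collapse

Microarray probesets are filtered per dataset before combination, all
rules independent and order-free:

| rule | default | meaning |
|------|---------|---------|
| mean intensity ≥ `expr_min` | 100 | drop background-level probesets |
| &#124;r&#124; ≥ `abs_r_min` | 0.2 | drop uninformative correlations |
| present fraction ≥ `present_frac_min` | 0.30 | drop undetected probesets |

"Mean intensity" is the across-sample mean (the conventional abundance
filter; the choice of mean over median is a design decision). Marginal
(M) detection calls count as *not* present — the conservative reading
of a present/absent filter. Datasets without a call matrix skip the
third rule.

Genes measured by several probesets are collapsed to the probeset with
the largest |r| (signed value reported); ties break to the
lexicographically smallest probeset id so results are reproducible.
The target gene's own representative probeset is chosen by most P
calls, then highest mean intensity, then smallest id.

The tested-gene universe excludes the target itself (it is never a
hypothesis). An optional exclusion list (e.g. genes without an ortholog
in a species needed downstream) is applied *after* the significance
cut, so the run log reports both pre- and post-exclusion counts.

## The synthetic-data generator

The generator exists so every stage runs offline under known truth. Its
construction mirrors the single assumption the meta-analysis makes — a
per-dataset Pearson correlation with the target:

* Per dataset, a latent standard-normal target factor *f* per sample.
* A planted gene's latent value is β·f + sqrt(1−β²)·ε (population
  correlation exactly β); a null gene's is independent noise.
* Latent values map to intensities affinely around a per-gene lognormal
  baseline (median ≈ 500, log-sd 0.7): intensity = b·(1 + 0.15·latent).
  The map is monotone-linear, so the latent correlation *is* the
  intensity correlation — no attenuation bias from the intensity model.

Defaults are the study conditions the pipeline is validated under: four
datasets of 40/28/35/13 samples, 1000 genes, a 20-gene module planted
at β = 0.8.

Realism knobs, each tied to a filter it exercises:

* `low_expr_fraction` (0.05): null genes with baselines drawn in
  (20, 80), below the intensity filter. Restricted to null genes so the
  intensity filter is exercised without silently deleting the module
  the recovery tests measure.
* Present/absent calls drawn with probability
  logistic((intensity − 100)/25); a quarter of non-present calls are
  coded M. Low-baseline genes therefore also fail the present-call rule.
* `dropout_fraction` (0.1): each gene independently absent from a
  dataset (never the target; a planted gene always keeps ≥ 1 dataset),
  producing the partial-evidence rows the combiner must renormalize.
* `probesets_per_gene` > 1 adds probe-level latent noise per extra
  probeset: sd 0.05 for the designated winner, 0.8 for the others
  (correlation attenuation 1/sqrt(1+sd²) ≈ 0.78, emulating a poorly
  hybridizing secondary probeset). The gap is what makes the intended
  collapse winner statistically identifiable at the smallest dataset
  size (n = 13); with a smaller gap the max-|r| choice is dominated by
  sampling noise, which would test luck rather than the collapse rule.
* Per-gene baselines are drawn independently per dataset (platforms
  differ), so a single unlucky baseline cannot remove a gene from every
  dataset at once.

Measured behavior under the defaults (recomputed by
`scripts/acceptance.py`, not asserted here): full recovery of the
planted module with ≈ 0–0.2 false positives per run, and ≥ 90% of null
(β = 0) replicates reporting zero significant genes.

What the generator does **not** emulate: probe-sequence effects,
batch/array effects, correlated null genes (co-expression among
non-module genes), heavy-tailed noise, or normalization residuals.
Passing tests therefore demonstrate correctness of the statistical
machinery under its own assumptions, not robustness to real microarray
artifacts.

## Gene-set enrichment

Genes are ranked by decreasing correlation with the target (gene-level,
after collapse; the abundance and present-call filters apply, the |r|
filter does not — a ranking needs its weak tail). Gene sets are kept
when their overlap with the ranked universe is strictly between the
size bounds (defaults 15 and 500).

The enrichment score is the weighted Kolmogorov–Smirnov statistic: a
hit at rank *i* adds |s<sub>i</sub>|^p normalized by the sum over hits,
a miss subtracts 1/(N − N<sub>hits</sub>); ES is the running sum's
signed maximum deviation. Exponent p = 1 by default (score-weighted);
p = 0 gives the classic KS statistic. Degenerate sets (overlap 0 or N)
are errors. If every in-set score is exactly zero at p > 0 the hit
weights fall back to equal increments.

The null permutes the *target profile* across samples (phenotype
permutation) rather than gene labels, because the ranking metric is a
correlation with a continuous profile; gene-label permutation would
break inter-gene correlation structure the statistic should respect.
The probeset-to-gene collapse is fixed from the observed profile and
only the ranking is recomputed per permutation — re-collapsing per
permutation would let probeset choice absorb null variation and is
much slower. The p-value uses the add-one rule over same-sign nulls,
p = (1 + #{|ES*| ≥ |ES|, same sign})/(1 + n<sub>perm</sub>), so p is
never 0 and is bounded below by 1/(n<sub>perm</sub>+1). NES divides ES
by the mean |null ES| of the same sign. A q-value computed from the
pooled same-sign null NES distribution is reported for completeness and
is explicitly approximate (it ignores inter-set correlation).

## Interaction-network stage

The interaction graph is simple and undirected; SIF relation types are
ignored, self-loops dropped, duplicate edges collapsed. Around the
significant genes (seeds) the *induced* subgraph on mapped seeds plus
their first neighbors is taken — neighbor–neighbor edges are kept,
which is what makes reported edge counts exceed seed-incident edges.
The tissue-expression filter keeps nodes with expression strictly
greater than the threshold (default 200); nodes absent from the
expression table fail the filter (unknown ≠ expressed). The filter is
idempotent and monotone in the threshold, both property-tested.

## Numerical choices

* t→z uses `norm.isf(t.sf(|t|, df))` with the sign reattached: both
  tails are computed as upper tails, so the transform stays accurate
  and exactly antisymmetric for large |t|.
* Two-tailed p uses `erfc(|z|/sqrt(2))` directly, not `1 − cdf`,
  keeping precision for |z| > 6 (p ≈ 1e-10 territory).
* Vectorized Pearson correlations clip to [−1, 1] to absorb rounding;
  constant profiles yield NaN and are removed by the |r| filter. The
  scalar `pearson_r` raises on constant input instead, as an explicit
  domain error.
* Fixture TSVs are written with `repr(float)` (shortest round-trip
  representation) and parsed back with numpy's correctly-rounded
  parser, so generate → write → read is bit-exact.
* All randomness flows through `numpy.random.default_rng(seed)`; a
  fixed seed reproduces generator output and permutation p-values
  bit-for-bit.

## Problem sizes used in validation

The validation suite runs the generator at its default size (4 datasets,
1000 genes; 10 seeds for recovery, 200 replicates for the null study),
oracle-equivalence fixtures at ≤ 50 genes against a straight-line
brute-force re-implementation, the enrichment Monte-Carlo check at
10 000 permutations against an exhaustive 720-permutation enumeration
on a 6-sample toy, and network property checks on random graphs of up
to 30 nodes against exhaustive edge recounts.

## Known limitations

* The weighted-Z default (Σw denominator) is conservative; switch to
  `rss_weights` for a calibrated standard-normal null.
* Bonferroni is the only multiplicity correction for the meta-analysis,
  by design; there is no Benjamini–Hochberg option.
* The enrichment q-value is a pooled approximation, not the full
  per-set null matching of the reference GSEA procedure.
* Fold changes are plain ratios of group means on the linear intensity
  scale, with the gene represented by its highest-mean probeset; no
  shrinkage or moderated statistics.
* The pipeline consumes already-normalized matrices; no normalization,
  batch correction or CEL-level processing is performed or checked.
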