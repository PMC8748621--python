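# Methods

## Scope and model

`germdiv` evaluates the phenotypic diversity of a germplasm cohort — an
individuals × traits table mixing coded qualitative classes and continuous
quantitative measurements — and ranks individuals for selection.  The five
stages (diversity, correlation, Ward clustering, correlation-matrix PCA,
composite scoring) are the conventional toolchain of fruit-crop germplasm
surveys; the package's contribution is a tested, reproducible implementation
of that chain plus a synthetic-cohort generator matching the published
summary statistics of a 151-tree Calamansi seedling survey.

## Diversity statistics

**Shannon–Wiener index.**  `H′ = −Σ Pᵢ ln Pᵢ` in nats with `0·ln 0 := 0`.
Natural logarithm, verified by recomputing the survey's pulp-color row
(frequencies 5.30/17.51/33.63/37.23/6.33 % → H′ = 1.37); a base-10 logarithm
does not reproduce it.  Frequencies are "effective percentages": computed
over non-missing individuals only.  Declared classes with zero count are
retained in tables and contribute 0 to H′.

**Quantitative grading.**  A trait with sample mean `x̄` and sample SD `s`
(n−1 denominator throughout; the convention for the published SDs is
unstated, and sample SD is standard practice) is discretized into ten
levels: level 1 for `x < x̄ − 2s`, level 10 for `x ≥ x̄ + 2s`, and eight
interior half-open intervals of width `0.5s`, left-closed/right-open, so the
mean itself falls in level 6.  Only the outer rules are fixed by convention
in the field; the half-open interior convention is this package's choice and
is pinned by tests.  Grading is scale-free: any positive affine rescaling of
a trait leaves all levels (hence H′) unchanged.  Under this grading a normal
trait has bin probabilities Φ-differences
{0.0228, 0.0441, 0.0919, 0.1499, 0.1915, 0.1915, 0.1499, 0.0919, 0.0441,
0.0228} and the large-sample limit H′ = 2.0878, which is why observed values
near 2 indicate rich, evenly spread phenotypes while H′ ≪ 2 flags skewed or
clumped traits.

**Coefficient of variation.**  `CV = 100·s/x̄` (percent), undefined at
`x̄ = 0` (a named error).  CV > 10 % is conventionally read as high
inter-individual variability and breeding potential.

**Group subtotals.**  H′ subtotals over named trait groups; the bundled
default group "fruit" comprises the fruit-form qualitative traits
(FS, FBS, FTS, PC).

## Correlation

Pairwise-complete Pearson `r` (each pair uses the individuals complete for
both traits — this maximizes data use with missing values), with two-sided
p-values from the exact null transform `t = r√(n−2)/√(1−r²)` on `n−2`
degrees of freedom.  No multiple-testing correction: raw significant-pair
counts are the field's reporting convention, and the counting alpha
(default 0.05) is configurable.  Traits constant over their observed values
are excluded with a warning.  Under an independent-traits cohort the
fraction of pairs with p < α is calibrated to α (property-tested).

## Ward clustering

Complete-case analysis: individuals missing any quantitative trait are
dropped with a warning.  Traits are z-scored first by default — trait SDs in
the reference survey span 0.04 to 103, and unscaled Ward would be dominated
by yield and tree height; a flag disables this.  The agglomeration itself is
delegated to `scipy.cluster.hierarchy.linkage(method="ward")`; scipy's Ward
distances `d` are converted to merge heights `ΔSS = d²/2` so that the merge
tree reports within-cluster sum-of-squares increments directly.  Two
consequences are used as run-time checks and test invariants: heights are
nondecreasing (Ward reducibility) and the n−1 heights sum exactly to the
total sum of squares about the grand centroid.  Tie-breaking between
equal-ΔSS candidate merges follows scipy's nearest-neighbor-chain order;
ties have probability zero for continuous data, and the test oracle (an
exhaustive re-agglomeration recomputing every candidate ΔSS from raw
points) compares merged member-sets, which is insensitive to tie order on
the instances used.

Cutting undoes the last k−1 merges (default k = 4, configurable); groups are
labeled 1..k by decreasing size, ties by smallest member index, making
labels deterministic and permutation-equivariant.  Group profiles report
per-trait means and deviation scores `(group mean − overall mean)/overall
SD` on the *original* trait scales; traits with |deviation| ≥ 0.5 (configurable)
are flagged salient with direction.  Dendrograms are exported as rooted
binary Newick with the midpoint branch convention: each child's branch is
half the height difference to its parent, so two singletons merged at
height 2 get branches of 1.

## PCA and composite scoring

The Pearson correlation matrix of the complete-case quantitative block is
eigendecomposed (`numpy.linalg.eigh`).  Eigenvalues sort descending and sum
to q (trace); eigenvector signs are fixed so each vector's
largest-magnitude element is positive, making repeated runs bit-identical.
The per-trait coefficients reported per component are **loadings**
(eigenvector × √Eⱼ): their column sums of squares recover Eⱼ and row sums
of squares are 1 (communalities), both run-time invariants.  Contribution
rates are `100·Eⱼ/q` percent with a running cumulative; retention defaults
to the Kaiser rule (Eⱼ > 1), with fixed-k and cumulative-threshold
alternatives.

Component scores default to projections of **raw** trait values
(`Fⱼ = Σₜ loading[t,j]·xₜ`): this is what reproduces the hundreds-scale
component scores and the printed composite values of the reference survey.
A standardized mode projects z-scores instead; in that mode the sample
variance of component j equals Eⱼ² exactly (z-scores have sample
correlation R, so `var(Z·vⱼ√Eⱼ) = vⱼᵀRvⱼ·Eⱼ = Eⱼ²`).

The composite value is `F = Σⱼ wⱼFⱼ` with **unnormalized** weights
`wⱼ = Eⱼ/q`; the weights sum to the retained cumulative contribution
(≈ 0.72 for nine components of 29 traits), not to 1.  This was verified
arithmetically against the reference survey's printed score table; a
normalized-weights option exists but is off by default.  Ranking is by
descending F with ties broken by individual ID; the default selection flags
individuals strictly above the median F, with top-k and fixed-threshold
alternatives.

## Synthetic cohorts

The generator emulates the reference survey's marginal structure: 29
quantitative traits as a multivariate normal with the published means/SDs
(covariance factored from a configurable correlation matrix, Cholesky with
an eigenvalue-clipping fallback for semidefinite inputs), and 8 qualitative
traits as independent categorical draws with the published class
frequencies (normalized to probabilities; two published rows total 99.99 %).
Defaults: n = 151, identity correlation.  A "blocks" preset adds moderate
within-block correlations (tree-size traits 0.5, leaf-size 0.5, fruit-size
0.6) so clustering and PCA demos have structure; these values are arbitrary
and are not estimates of the real crop.  Draws are untruncated by default
because grading and CV use the sample mean/SD and truncation would bias
parameter-recovery tests; `clip=True` clips to the published per-trait
ranges.  All randomness flows from one integer seed through
`numpy.random.SeedSequence` (separate child streams for the two blocks), so
identical configs give bit-identical cohorts.

What passing tests on these cohorts does **not** show: real phenotype data
are not jointly normal (counts, ratios, bounded percentages), qualitative
and quantitative traits are not independent, and the real trait correlation
pattern is unknown.  Cohort-level published outcomes that depend on the
unpublished raw data — the exact significant-pair count, the 32/7/25/87
cluster sizes — are therefore out of reach by construction and are not
asserted anywhere.

## Numerical choices and degenerate inputs

- Sample statistics use the n−1 denominator everywhere.
- Probability vectors must sum to 1 within 1e−6 (Shannon input) / 1e−9
  (generator configs); correlation matrices must be symmetric with unit
  diagonal and eigenvalues ≥ −1e−10.
- Constant traits: CV is 0 with sd = 0 but mean ≠ 0; grading and
  z-scoring raise named errors; correlation excludes the trait with a
  warning; validation reports a warning beforehand.
- Missing data: diversity uses per-trait non-missing values; correlation is
  pairwise-complete; clustering and PCA are complete-case (no imputation).
- Result tables are written with 2–3 decimals matching field conventions;
  matrices round-trip at full precision (`repr` floats).

## Problem sizes

Tests and the acceptance script use cohorts of n = 151 (the reference
survey's size) for pipeline runs, n = 10,000 for parameter-recovery bounds,
n = 100,000 single-trait draws for categorical frequency recovery, and a
200,000-draw sample for the grading-limit check; the brute-force Ward oracle
runs on all instance sizes n ≤ 10.  These sizes make every statistical
tolerance a comfortable multiple of its sampling error while keeping the
full suite to a few seconds.

## Known limitations

- Ward tie-breaking is scipy's, not a documented lexicographic rule; only
  relevant for data with exact ties.
- No multiple-testing correction, no alternative correlation measures, no
  non-Ward linkages, no rotation/factor analysis, no automatic k selection.
- Above-median selection flags at most ⌊n/2⌋ individuals; with heavily tied
  composite values it can flag far fewer.
- The bundled qualitative class codes are positional ("1", "2", …); the
  survey's verbal class definitions are not part of the schema.
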