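# Methods

This note documents the models, conventions and numerical choices behind
`emtspectrum`, and what the synthetic validation does and does not
demonstrate.

## Preprocessing

Raw UMI counts move through a fixed, layer-checked chain: cell/gene filtering
(defaults: a cell must express ≥ 200 genes, a gene must appear in ≥ 3 cells —
dataset-dependent in practice, so both are arguments and logged), library-size
normalization (`target_sum` defaults to the median of per-cell totals),
`log1p`, and optionally per-gene scaling. Scaling uses the population
(n-denominator) standard deviation and clips at ±10, the common single-cell
convention; zero-variance genes become all-zero columns. Highly-variable-gene
selection is the classical dispersion method: per-gene mean and
dispersion (variance/mean) on `expm1` of the log layer, 20 equal-frequency
mean bins, dispersion z-scored within bin, thresholds
`min_mean = 0.0125`, `max_mean = 5`, `min_disp = 0.8`. With fewer than 20
genes a single bin is used and a warning logged. Gene symbols are uppercased
everywhere so mouse and human data hit the same signatures; no ortholog
mapping beyond casing is attempted.

Statistical comparisons between subtypes (Mann–Whitney) operate on the
log-normalized layer, not the scaled one.

## ssGSEA scoring

For each cell, genes are ordered by expression (descending; ties get average
ranks). Two CDFs accumulate down the list — the in-set CDF weighted by
`rank^α` and the uniform out-of-set CDF — and the enrichment score is the sum
of their difference over all positions (the full running sum, not the maximum
deviation; variants differ and this choice is deliberate and tested against a
position-by-position enumeration oracle). The sum telescopes to a closed form
linear in the bottom-up ranks, which is what the vectorized code evaluates;
agreement with the enumeration is exact up to floating-point summation order
(≤ 1e−12 in practice).

`α = 0.25` by default (the usual ssGSEA weight); `α = 0` gives the
unweighted statistic used by the exact oracle tests. Optional normalization
divides all scores in a run by their max − min across cells. The score is a
rank statistic: it is invariant under any strictly monotone transform of a
cell's expression vector (property-tested), which makes it robust to
normalization details.

The E and M signatures share genes with the subtype-signature matrix used for
archetype labeling. To show the E/M–subtype association is not an artifact of
that overlap, `exclude_overlap` removes the intersection and the scoring is
repeated; on synthetic data with the planted 20-gene overlap the before/after
Spearman correlation exceeds 0.99 per axis.

## Non-negative PCA

The first loading maximizes `var(Xw)` over unit vectors with non-negative
entries, on the gene-set-restricted, column-centered matrix. The EM
formulation alternates `y = Xw` with the constrained least-squares M-step,
whose closed form is `w ∝ max(Xᵀy, 0)` followed by renormalization —
equivalent to projected power iteration on the covariance, so the objective
is non-decreasing (checked on every test fit). Choices:

* **Initialization**: normalized absolute value of the leading right singular
  vector of the current (deflated) matrix. Deterministic; the `seed` argument
  is accepted for interface stability but no step is stochastic.
* **Convergence**: ∞-norm change in `w` below `tol = 1e−6`, `max_iter = 500`.
  Non-convergence is logged, not fatal.
* **Degenerate fallback**: if `max(Xᵀy, 0) = 0` (no feasible non-negative
  direction, e.g. two perfectly anticorrelated genes), the component falls
  back to the basis vector of the highest-variance gene — the constrained
  optimum in that case, verified against a grid search over the non-negative
  quarter circle — with ties broken by lowest index.
* **Orthogonality** is enforced by projection deflation: after each
  component, the score direction is projected out of every gene column
  (`X ← X − y(yᵀX)/‖y‖²`), which makes successive score vectors orthogonal by
  construction even when the non-negativity constraint is active. Rank-one
  deflation `X − ywᵀ` only guarantees this at an unconstrained fixed point.
* **Variance explained** is `var(y_k)` divided by the total variance of the
  centered input *before any deflation*; this denominator convention is
  recorded in the serialized model file.
* Scores are not shifted or re-signed: loadings are non-negative but centered
  data give signed scores, and the raw first-ranked component is reported.

Component ranking for E/M scoring is two-stage: the five components with the
highest variance explained are re-ranked by the variance of their
per-subtype mean scores, so the top component is the one that best separates
the subtype populations. Ties break by variance explained, then index.

## Archetype enrichment test

Cells whose archetype weight strictly exceeds 0.95 are specialists (the
threshold must exceed 0.5 so assignment is unique). For each (archetype,
signature score) pair: `m` = mean score of the specialists; B = 1000 resamples
of the same size are drawn with replacement from the non-specialist cells,
allocated evenly across strata (time points), remainder cells going to the
largest strata (name order on ties); `p` = fraction of null means ≥ m.
Counting ties as "≥" rather than strictly ">" means constant data yield
p = 1, not p = 0; a `strict_greater` flag restores the literal reading, and
optional `(count+1)/(B+1)` smoothing is available but off by default.
P-values are Holm-adjusted across the whole family and q < 0.1 is
significant; an archetype significant for several signatures receives the
merged class label ("A/N", "P/Y"), and one significant for none is
unassigned.

Null calibration (random specialists from the same score distribution) gives
an approximately uniform p distribution; the family-wise false-labeling rate
with five independent null signatures stays near the nominal 0.1. The
resampling pool excludes the specialists themselves, which makes the test
slightly anticonservative when specialists are a sizeable fraction of the
cohort — visible as a false-labeling rate a couple of points above nominal in
the Monte-Carlo checks, and inherent to the procedure.

## M1/M2 divergence and correlations

Each mesenchymal gene is compared between the N class and the Y class
(two-sided Mann–Whitney on log-normalized expression; exact enumeration when
both groups have ≤ 8 values and no ties, tie-corrected normal approximation
otherwise). Benjamini–Hochberg adjustment runs across the M set; genes with
q < 0.05 are M1 if the N−Y mean difference is positive and M2 if negative.
Holm is reserved for the archetype test (a family-wise question); BH is used
here (a discovery-rate question). Classification is per dataset; consensus
across datasets is reported as the Pearson correlation of per-gene mean
differences over the shared genes rather than by intersecting significance
calls.

Score correlations are Spearman, per stratum; strata can be metadata levels
(treatment) or marker positivity, defined as log-normalized expression > 0
(any detected transcript — the threshold is configurable since "positive" has
no canonical cutoff). Strata with fewer than 3 cells are skipped with a log
entry.

## Synthetic data

The generator emulates a five-subtype tumor with negative-binomial UMI
counts. Per-gene baseline log-rates are N(0, 0.5); planted shifts (in units
of `effect_size`, default 1.0) move the epithelial program up in A2 (+1),
mildly up in A (+0.5) and down in P/Y (−0.5); M1 up in A and N (+1); M2 up
in P and Y (+1); both M programs down in A2 (−1); each 21-gene subtype
signature up (+1) in its own subtype. Twenty signature genes are shared with
the EMT sets (10 with E via the A2 signature, 5 each with M1/M2 via the N and
Y signatures), reproducing the 20/510 Jaccard overlap. A per-cell latent
factor (N(0, 0.5), loading 0.7) scales the E genes and the A2 signature genes
within neuroendocrine cells, so the A2–epithelial correlation exists inside a
single subtype and within ASCL1⁺ cells. `ASCL1` itself is a planted marker,
high in A/A2 and essentially undetected elsewhere. Treatment increments the
M2 program by 0.5 in treated cells (a cisplatin-like EMT shift); time points
are uniform. Counts are NB with shared dispersion θ = 10 around lognormal
library sizes (log-mean 9.2 ≈ 10k counts, log-sd 0.35). Specialist cells
(60%) get archetype weights with their own coordinate in (0.955, 0.995);
generalists draw from a Dirichlet tilted toward their subtype.

Default sizes are 500 cells per subtype, 232 E / 96 M1 / 97 M2 genes, a
105-gene signature and 1500 background genes; the smaller sizes used in some
tests (40–80 cells/subtype, a few hundred background genes) keep individual
fits fast while preserving all planted structure.

What passing tests show: the pipeline recovers planted subtype labels,
program memberships, effect directions and couplings under NB noise at
realistic depth. What they do not show: robustness to batch effects,
doublets, ambient RNA, non-NB overdispersion structure, or
mouse-to-human ortholog mismatch — none of which the generator emulates.

## Known limitations

* Archetype-vertex discovery and the construction of the bulk signature
  matrix are upstream of this package; archetype weights and any per-cell
  signature score column are accepted as inputs.
* The enrichment test's mild anticonservatism at large specialist fractions
  (see above).
* nnPCA components after the first few can fail to converge on nearly
  isotropic residual matrices; this is logged and the component is still
  returned with its variance share.
* Gene-ontology enrichment of the M1/M2 groups requires an external
  annotation database and is out of scope.
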