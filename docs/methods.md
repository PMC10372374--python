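# Methods

This note records the statistical models the package implements, the
choices made where a convention was genuinely open, and what the synthetic
generators do and do not emulate.

## Study design

All defaults mirror a maternal-hyperglycemia pig study layout: two groups
(PHG = offspring of hyperglycemic mothers, PNG = controls) crossed with sex
on an unbalanced design (PNG 6 F + 4 M, PHG 5 F + 4 M), plus 5 pooled-QC
injections and 3 extraction blanks for the lipidomics assay. `StudyDesign`
validates that every group retains at least two samples whenever a variance
is needed downstream.

## Lipidomics quality control

The four filters run sequentially, each on the survivors of the previous
stage, so a species failing several criteria is counted once, at the first
stage that catches it. Conventions:

- Pool missingness removes at strictly **> 35%** missing among QC pools;
  group missingness removes at **≥ 50%** missing in *every* biological
  group (the stricter of the two plausible readings of "50% in all
  groups"; the boundary is inclusive and both thresholds are arguments).
  Groups are the two biological group labels, not group × sex cells;
  blanks and pools are excluded from the group computation.
- CV and the D-ratio use linear-scale concentrations, observed values
  only, and n−1 denominators. The D-ratio is σ_tech/√(σ_biol²+σ_tech²);
  the degenerate 0/0 case is defined as 0 with a warning, and the statistic
  is monotone increasing in σ_tech and decreasing in σ_biol.
- kNN imputation is observation-selective: candidate neighbours must be
  observed in the target sample; distances are Euclidean on per-species
  standardized profiles restricted to jointly observed samples; votes are
  1/distance-weighted means of raw neighbour values, with zero-distance
  neighbours taking the cell outright and ties sharing weight equally.
  Fewer than k eligible neighbours triggers a warning and uses all
  available; none at all falls back to the species mean.
- The cleaned table keeps biological and QC-pool columns; blanks exist
  only for fixture realism and never enter a computation.

## Proteomics post-processing

The chain is fixed: FDR filter → charge aggregation → MaxLFQ → detection
filter → imputation.

- Filtering keeps precursor rows with global, run-specific and
  protein-group q-values all ≤ 0.01, proteotypic and non-contaminant. A
  signal-quality floor is available but off by default: it only applies
  when the report carries a quality column and a threshold is configured,
  since no universal cutoff exists.
- MaxLFQ estimates each pairwise sample log2-ratio as the median over
  shared peptides (even counts average the central log-ratios, i.e. the
  geometric midpoint on the linear scale) and solves the least-squares
  system over all valid pairs per connected component of the pair graph.
  The anchoring constant — the least-squares system fixes only
  differences — is the mean log2 peptide sum of the component's samples;
  any constant cancels in downstream fold changes. Samples in no valid
  pair stay missing, and a protein with observations but no shared pair is
  flagged with a missing profile. The estimator is scale-equivariant and
  reproduces exact peptide ratio structure exactly.
- The detection filter keeps proteins observed in ≥ 60% of all samples,
  boundary inclusive (12 of 19 stays, 11 of 19 goes).
- Imputation is iterative regression (scikit-learn's iterative imputer
  with a near-OLS ridge, tolerance 1e-4, ≤ 10 cycles, seeded): each
  protein with missing values is regressed on the others across samples,
  in log2 space, until the imputed values stabilise. Observed values are
  never altered. This implements the contract of a model-based iterative
  imputer rather than replicating any specific random-forest variant; with
  many more proteins than samples the regressions are regularised
  projections, which is why validation compares against a mean-imputation
  baseline on aggregate RMSE rather than cell-exact values.

## Differential abundance

Per feature, a 2×2 linear model on log2 abundances with effects group, sex
and group×sex, computed for all features at once via QR projections of the
relevant design matrices. Because the design is unbalanced, Type I
(sequential) sums of squares depend on term order and are rejected as a
default; **Type II** (each main effect adjusted for the other, interaction
last) is the default with Type I/III switchable, and Type III uses
sum-to-zero contrasts. Constant features return p = 1 with a warning. The
implementation is verified against `statsmodels.anova_lm` at 1e-10 for all
three types on balanced and unbalanced designs.

All three effects' p-values of one omics dataset are pooled into a single
BH step-up; missing p-values are excluded from the hypothesis count.
Pooling is per dataset (proteome, metabolome, lipidome separately), never
across datasets. Features with a significant interaction are followed up
with Tukey HSD over the four cells (scipy's studentized-range
implementation, which applies the Tukey–Kramer form to unequal cells).

Fold change is log2 of the ratio of linear-scale group means (PHG over
PNG), computed after imputation; a difference-of-log-means variant is
available by flag. The significance rule is adjusted p ≤ 0.05 **and**
linear fold ≥ 1.5 (|l2fc| ≥ 0.585), both bounds inclusive, applied to the
group effect with the PHG/PNG fold and to the sex effect with an F/M fold;
the interaction flag uses the adjusted p alone, since a 2×2 interaction
has no single two-group fold. The fold filter is interpreted on the linear
scale: a log2 threshold of 1.5 would contradict reported calls of
significant features well below |l2fc| = 1.5.

HOMA-IR and QUICKI use their exact formulas; QUICKI takes base-10
logarithms (the standard for that index — natural logs would redefine the
0.45 sensitivity cutoff) and errors on non-positive inputs.

## Multivariate statistics

Scaling is explicit and recorded: `pareto` divides centered log2 values by
√SD, `uv` by SD, `standard` is the per-feature z-score used for heatmap
displays. Sensible per-analysis defaults follow common practice: PCA on
log2 (optionally unit-variance) data, OPLS-DA and co-inertia on log2 +
Pareto, each block scaled separately.

PCA is a column-centered SVD with a deterministic sign convention (the
largest-magnitude loading of each component is made positive) so repeated
runs are comparable. Ward clustering standardizes features and uses
scipy's Ward linkage on Euclidean distances; merge heights are
non-decreasing and equal an exhaustive greedy agglomeration on small
inputs.

OPLS-DA encodes the two classes as ±1 and fits one predictive NIPALS
component after removing k orthogonal components. k is selected by
leave-one-out cross-validation: it grows from 0 while the LOOCV Q² = 1 −
PRESS/TSS improves by at least 0.01, capped at min(5, n−2) — the "best
fitted model" rule had to be fixed somewhere, and maximizing cross-
validated predictive ability with an improvement floor is the conservative
choice. R²X counts predictive plus orthogonal X-variance; R²Y is the
fitted class variance explained; VIP is computed over the predictive
component and satisfies mean(VIP²) = 1 by construction (asserted on every
fit). Permutation tests re-fit the model statistic on label permutations
and use the add-one estimator p = (1 + #{perm ≥ obs})/(1 + n_perm), whose
attainable floor with 200 permutations is 1/201 ≈ 0.005; smaller printed
p-values from other software imply a fitted-distribution estimator, which
this package deliberately does not use.

Co-inertia takes the SVD of the cross-covariance of two centered blocks on
identical samples; per-axis fractions are squared singular values over
their sum, axis signs are fixed jointly for the paired coordinates, and RV
= tr(XX'YY')/√(tr((XX')²)·tr((YY')²)) ∈ [0,1], invariant to rotation and
positive scaling of either block. The permutation p row-permutes one
block.

## Network analysis

- STRING-style input scores above 1 are treated as the 0–1000 integer
  dialect and divided by 1000; the high-confidence threshold is strict
  (score > 0.7). Self-loops are dropped and duplicate edges keep the
  maximum score.
- LCC significance compares the seed-induced subgraph's largest component
  against uniformly sampled node sets of the same size (no degree matching
  for this statistic), reporting the null mean/SD, z, the add-one
  empirical p and a normal-approximation p — the empirical estimator
  cannot go below 1/(n_random+1), so extreme printed significances are
  only reachable through the normal approximation, and both are reported.
  Cores are the ≥ 2-node components of the seed subgraph, each scored at
  its own size.
- RWR iterates p ← α·p₀ + (1−α)·W·p with a column-normalized adjacency,
  uniform seed restart vector and α = 0.9; degree-zero columns redistribute
  their mass to p₀. Scores conserve mass (sum to 1) at every step.
  Expansion adds non-seed nodes one at a time in decreasing RWR score
  (ties: higher degree, then lexicographic symbol, for determinism) until
  ≥ 90% of the seeds share one connected component, with an optional
  additions cap that flags the result when reached.
- Network proximity is the directed closest-distance measure: d_c = the
  mean over the dysregulated set s1 of the minimum shortest-path distance
  into the disease set s2 (a symmetric variant is a one-line change; the
  directed form matches the query-set-averaged convention). Unreachable
  pairs are excluded from the average with a logged count by default; a
  numeric penalty is available. The null replaces **both** sets with
  random sets drawn to preserve each set's exact degree-bin composition,
  using log2-width degree bins merged upward until every bin holds ≥ 100
  candidates (configurable; small test graphs use smaller bins). Distances
  run through scipy's multi-source Dijkstra on a cached sparse adjacency,
  and the result carries its full null distance array so independent
  BFS oracles can verify it draw by draw.
- Disease screening filters the catalogue at GDA score strictly > 0.3,
  collapses duplicate (disease, gene) pairs to their maximum score,
  computes Jaccard on the raw gene sets and proximity on the mapped sets,
  and BH-adjusts the empirical proximity p-values across diseases.
- ORA is the hypergeometric upper tail P(X ≥ k) per GMT set with BH
  adjustment and enrichment ratio (k/|query|)/(K/|universe|), replacing
  any web-service enrichment backend with file-based gene sets.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* the analysis stages
care about, with planted, ledgered truth:

- Omics matrices are log-normal — log2 intensities Normal(baseline +
  effects, σ_bio) with feature-specific baselines (default mean 20, SD 2,
  σ_bio 0.5) — with planted group/sex/interaction shifts whose linear fold
  is drawn from 1.5–5.3 (the magnitude range of prominently reported
  effects) with random sign. Missingness, when enabled, is left-censored:
  dropout probability decays sigmoidally above the 20th-percentile
  intensity, approximating intensity-dependent MNAR dropout.
- The raw lipid fixture plants, in pipeline order, a configured number of
  species violating exactly one QC stage while passing all earlier ones.
  Construction parameters (e.g. pool SD = 0.4·mean for CV violators;
  pool SD = 0.2·mean with biological SD = 0.1·mean for D-ratio violators,
  giving D ≈ 0.894 with pool CV 20%) are verified *post hoc* on the
  realized finite sample using the same predicates the QC module applies,
  resampling a species up to 1,000 times until its constraints hold — so
  the planted per-stage counts are exact by construction, for any seed.
  Survivors carry ~2% incidental biological missingness (mirroring the
  real table's ~2% post-QC missingness), capped so it can never trip the
  group-missingness rule.
- PPI graphs are preferential-attachment (Barabási–Albert) graphs —
  connected, heavy-tailed — with planted dense modules whose internal
  edges appear with probability 0.9 and carry combined scores > 0.7;
  background scores are uniform on [0,1]. Disease catalogues draw gene
  sets from the graph with configured overlaps against planted modules;
  shared genes always score above the 0.3 screening threshold.
- Clinical tables draw insulin/glucose per group × sex cell; the default
  cell means are chosen to reproduce the qualitative insulin-resistance
  contrast (PHG resistant, males more affected, QUICKI below the 0.45
  cutoff) at realistic magnitudes.

What the generators do **not** emulate: mass-spectral artefacts (isotope
interference, retention-time drift, batch effects), correlated feature
blocks beyond those induced by shared planted effects, ortholog mapping
between species identifier spaces, or the literature-driven topology of a
real interactome. Passing recovery tests therefore demonstrates that the
statistics recover the effects they model under their own assumptions —
not that those assumptions hold in any particular real dataset.

## Problem sizes and numerics

Monte-Carlo validation uses sizes chosen to make the sampling error small
relative to the margins being tested: differential-abundance recovery runs
100 replicate matrices of 100 features (20 planted fold-4 group effects,
σ_bio 0.3) through the full ANOVA → pooled-BH → fold-filter chain;
network recovery runs 100 replicate 1,000-node graphs with a planted
10-node module against 50-disease catalogues (LCC null 200 draws,
proximity null 50 draws per disease — the ranking statistic, not the tail
p, is what that test consumes). The full-size 1,204-species lipid fixture
is regenerated from scratch wherever its counts are asserted.

Numerical conventions worth knowing: ANOVA uses QR-based projections (no
explicit inverses); BH adjustments go through statsmodels; the RWR stops
at an L1 change below 1e-8; permutation and resampling loops consume a
single `numpy.random.Generator` seeded explicitly, and every stochastic
result object records its seed and draw count. Pipeline sub-seeds are
SHA-256 hashes of (global seed, stage name) reduced below 2^31, so adding
a stage never shifts another stage's stream, and a re-run with the same
configuration is byte-identical (asserted on file hashes in the tests).

## Known limitations

- MaxLFQ solves one least-squares system per protein in Python; for
  reports with tens of thousands of proteins a vectorised or compiled
  implementation would be preferable.
- The OPLS-DA component selection (LOOCV with a 0.01 floor) is one
  defensible reading of "best fitted model"; other software may select
  differently and report slightly different R²/Q².
- Empirical permutation p-values are floored at 1/(n+1); analyses that
  need smaller tail probabilities must rely on the normal approximation,
  which assumes an approximately Gaussian null.
- The iterative imputer is a contract-level stand-in for tree-ensemble
  imputation; in heavily non-linear missingness regimes a forest-based
  imputer may perform better.
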