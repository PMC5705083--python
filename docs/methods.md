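# Methods

`mixclust` clusters both the samples and the variables of a table whose
columns live on different scales — quantitative, ordinal, nominal,
binary — and draws integrative displays from the resulting distance
matrices. This note records the models, the numerical choices, and what
the simulation-based validation does and does not establish.

## Sample distances: Gower's coefficient

The similarity of samples *i*, *j* over *p* variables is

s(x_i, x_j) = Σ_k s_k(x_ik, x_jk) δ_k w_k / Σ_k δ_k w_k,

where δ_k = 0 whenever either cell is missing and w_k ≥ 0 are optional
variable weights (default 1). Per-variable scores:

- qualitative (nominal/binary): 1 on agreement, else 0;
- quantitative: 1 − |x_ik − x_jk| / R_k, with R_k the observed range;
- ordinal (rank-based extension): 1 − |r_k(x_ik) − r_k(x_jk)| /
  (max_m r_k − min_m r_k), with midranks over the nonmissing values.

Distances are d = 1 − s ∈ [0, 1]. Numerical choices:

- **Ties** in ordinal ranks use midranks (average ranks); the rank-based
  score is otherwise silent on ties, and midranks are the standard
  resolution.
- **Degenerate variables** (zero quantitative range, single observed
  ordinal rank) carry no pairwise information and contribute δ = 0
  everywhere, with a warning, rather than a constant score of 1 which
  would inflate similarity. Constant *qualitative* variables are kept:
  the agreement score 1 is the rule's literal meaning and matching on a
  constant is harmless (it shifts all similarities equally).
- A sample pair with no comparable variable (all δ = 0) is an error
  naming the pair.
- Binary variables use the symmetric qualitative score; the asymmetric
  presence/absence variant of the original coefficient is out of scope.

With complete data and equal weights, d is an (unweighted) mean of
per-variable metrics and is itself a metric. With missing data the
pair-specific denominators can in principle break the triangle
inequality; the metric checks in the test-suite therefore run on
complete data.

## Variable dissimilarity 1: association-measure combination ("ama")

Pairwise similarity s_kl ∈ [0, 1] is picked by the scale combination:

| pair | coefficient |
|---|---|
| quantitative–quantitative, quantitative–ordinal | absolute Spearman ρ |
| ordinal–ordinal, quantitative/ordinal–binary | absolute Goodman–Kruskal γ |
| quantitative/ordinal–nominal | gated category reordering, then abs Spearman / γ |
| nominal/binary–nominal/binary | gated cross-table diagonalization, then abs γ |

γ = (n_c − n_d)/(n_c + n_d) over concordant/discordant observation
pairs. Binary variables enter γ as two-level ordinal factors.

**Category reordering.** A nominal factor X against a ranked variable Y
is turned into an ordered factor by sorting categories by the mean
midrank of Y within category (ties keep the original order). Because
this is optimistic under independence, a Kruskal–Wallis pre-test gates
it: only when p < α (default 0.05) is the reordering applied; otherwise
the coefficient is computed on the original (effectively arbitrary)
category order, which concentrates near 0. The gate uses the asymptotic
chi-square null with tie correction; no multiple-testing adjustment is
applied — the gates are per-pair heuristics.

**Cross-table diagonalization.** For two unordered factors, both
category orders are rearranged to concentrate counts on the diagonal,
maximizing |γ|, gated by a Pearson chi-square pre-test (no continuity
correction). Search strategy: exhaustively permute the category order of
the factor with fewer categories (cap `max_exhaustive_categories = 6`);
for each permutation score its categories by position and order the
other factor's categories ascending by count-weighted mean score; keep
the arrangement with maximal |γ|, ties resolved to the first
permutation in lexicographic order. Above the cap, categories start in
frequency order and two rounds of reciprocal mean-score reordering are
applied. The goal (large diagonal frequencies) admits no canonical
algorithm; exhaustive-on-the-smaller-side is exact for the category
counts (≤ 8) used throughout.

**Missing data.** Every coefficient and pre-test uses the
pairwise-complete observations of its pair; pairs with fewer than 3
complete cases get similarity 0 with a warning.

**Euclidean embedding.** The assembled S need not be positive
semidefinite. It is replaced by the nearest (Frobenius) unit-diagonal
PSD matrix S′ via Higham's alternating projections with Dykstra
correction (tolerance 1e−7 on the smallest eigenvalue, 100-iteration
cap, diagonal re-pinned each iteration, final eigenvalue floor plus
diagonal renormalization). By Gower's theorem d_kl = √(1 − s′_kl) is
then Euclidean, so all triangle inequalities hold (validated to 1e−9
slack). An already-PSD matrix is returned unchanged.

## Variable dissimilarity 2: generalized distance correlation ("dcor")

Each variable induces n × n sample distances under a scale-appropriate
metric: discrete 0/1 (nominal/binary), |x_i − x_j| (quantitative),
midrank differences (ordinal). Both the Euclidean and the discrete
metric are of strongly negative type, so the generalized distance
correlation characterizes independence.

From the double-centered matrix A and the modified matrix

A\*_ij = n/(n−1) · (A_ij − d_ij/n) (i ≠ j),
A\*_ii = n/(n−1) · (rowmean_i − grandmean),

the bias-corrected squared sample distance covariance is

Ũ_kl = (n−3)/n · ( Σ_ij A\*_ij B\*_ij − n/(n−2) Σ_i A\*_ii B\*_ii ),

which requires n ≥ 4 and may be negative. The coefficient is

R̃_kl = sign(Ũ_kl) · √|Ũ_kl| / (Ũ_kk Ũ_ll)^{1/4},

a correlation-scale quantity with R̃_kk = 1 and
R̃² = |Ũ_kl| / √(Ũ_kk Ũ_ll). The dissimilarity is d_kl = 1 − R̃_kl;
negative R̃ is propagated, so d can slightly exceed 1 (flagged in the
docs, not truncated).

Choices and caveats:

- The square-root placement in the normalization is a documented
  convention. The alternative "linear" convention R̃ = Ũ/√(Ũ_kk Ũ_ll)
  (the squared-scale bias-corrected statistic) is exactly mean-zero
  under independence but measurably degrades two-group variable
  clustering relative to the correlation-scale form; the
  correlation-scale form is used throughout. A consequence worth
  knowing: although Ũ itself is exactly centered under independence,
  the concave sign-sqrt transform gives R̃ a small negative
  finite-sample bias (about −0.01 at n = 200).
- R̃ is invariant to rescaling any variable's metric by a positive
  constant, so the range-normalized Gower summands may be substituted
  for the raw metrics with identical results (tested to 1e−12).
- Constant variables get R̃ = 0 / d = 1 with a warning.
- Missing data: pairwise-complete per pair, ordinal ranks recomputed on
  the complete subset; pairs with fewer than 4 complete cases are an
  error.
- With complete data all p modified matrices are computed once and the
  p × p statistic matrix is assembled by inner products (O(p²n²) but
  fully vectorized).

## Clustering and evaluation

Agglomeration runs on the distance matrix via the Lance–Williams
recurrences (scipy). "Ward" follows the ward.D2 convention — input
entries treated as Euclidean distances, the minimum-variance criterion
applied to their squares — the textbook reading for distance-matrix
input; which variant the original analyses used is not documented, but
at the simulated effect sizes results are insensitive. Merge
tie-breaking is scipy's (deterministic). Trees cut into exactly k
clusters; Newick export places each internal node at half its merge
height (ultrametric convention).

Two-class recovery is scored from a 2 × 2 cluster-vs-truth table a_ij:

MCR = (a_12 + a_21)/Σ a_ij, BER = ½ (a_12/(a_11+a_12) + a_21/(a_21+a_22)),

each minimized over the two cluster↔class matchings since cluster labels
are arbitrary.

## Synthetic data: what is emulated

**Correlated pair.** Bivariate normal with population correlation ρ on
the grid {0, 0.25, 0.5, 0.75, 0.95} and n ∈ {40, 96, 200, 400} (sizes
divisible by 8 keep an 8-category cut balanced). Categorized copies are
quantile cuts in "perfect agreement" with the parent — median cut for
binary, j/K-quantile cuts for K categories — so the categorization
preserves exactly the ordering information and the imposed association.
Ordinal copies keep cut order as level order; nominal copies get a
seeded random level order.

**Two variable groups.** p variables (p ∈ {50, 100, 200}, n ∈ {25, 50,
100}) in two equal groups; within a group of size g, corr(a, b) =
ρ·(1 − |a−b|/(g−1)) decays linearly in index distance from ρ ∈ {0.25,
0.5, 0.75} down to 0 (the decay *shape* is unspecified in the design;
linear-in-index is this package's choice). A fraction (0/20/40%) of
inter-group correlations, sampled symmetrically without replacement, is
set to 0.5 ("noise"). The assembled target is repaired to the nearest
PSD correlation matrix when indefinite, and samples are drawn from the
multivariate normal via an eigendecomposition root. A fraction of
variables is then quantile-categorized with K ~ uniform{2..8}, ordinal
or nominal with probability ½ each. Baselines: Euclidean distance
between the pre-categorization quantitative columns, and simple
matching (mismatch proportion) on median-binarized data. Binarization
of nominal variables (needed only for general inputs, not the study)
takes most-frequent-category vs rest, ties by level order.

Reproducibility: replicate r of a study with root seed s draws from
`SeedSequence(s, spawn_key=(r,))`.

These generators emulate the validation conditions, not real data: all
dependence is linear-Gaussian in origin, categorization is exactly
order-preserving, group sizes are balanced, and missingness (where
injected in tests) is completely at random. Passing tests therefore
demonstrate correctness of the estimators and recovery under the stated
conditions; they do not certify behavior under non-monotone dependence,
informative missingness, or unbalanced group structure.

## Visualization

The integrative heatmap shows samples × variables with dendrograms on
both axes, one color family per scale: blue sequential for quantitative
rows (min–max scaled per row — raw values are deliberately not shared
across rows), green sequential for ordinal rows by level order,
discrete reds for nominal rows, white for missing cells. It is capped
at 200 variable rows. The variable-similarity heatmap orders a
similarity matrix by its dendrogram with a monotone blue map. The
predictor–outcome scatter places every other variable at (similarity to
predictor, similarity to outcome), with the anchors at
(s(outcome, predictor), 1) and (1, s(outcome, predictor)). Exact
palettes are cosmetic; only the family assignment is contractual.

## Problem sizes used in validation

The acceptance checks run at: 50 random mixed datasets (n = 20, p = 4)
for equation-level oracle agreement; 20 datasets for scale invariance;
500 replicates at n = 400 (ρ = 0.75) and n = 200 (ρ = 0) for the
normal-case bound and the centering measurement; 200 replicates per ρ
and type combination at n = 400 for association recovery; 100 random
datasets each for the Gower and PSD metric guarantees; and 20/25
replicates of the two-group design at (n = 100, p = 100, ρ = 0.75,
noise 0) and (n = 50, p = 100, ρ = 0.5, noise 20%), both with half the
variables categorized — a deliberately scaled-down replicate count per
setting relative to the original 100-replicate grids, chosen to keep
the full validation run in the minutes range while leaving the medians
stable.

## Known limitations

- The ama pre-tests are marginal per-pair gates; no error-rate control
  across the O(p²) pairs is attempted (by design).
- d_kl = 1 − R̃_kl can exceed 1 and, unlike the ama distances, carries
  no Euclidean guarantee.
- Different scale combinations may sit on systematically different
  similarity scales (e.g. γ vs Spearman); the matrices are combined
  as-is.
- The heatmap caps at 200 variables; reduce or summarize features
  first.
- `simple_matching_distance` requires all-binary input and compares
  codes, so the low/high orientation of each variable matters.
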