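# Methods

## Problem

Functional-diversity indices depend on which traits enter them, yet trait
choice is usually ad hoc. `fdtraitkit` implements a complete workflow for
choosing quantitative traits before computing community functional
diversity: estimate how many latent dimensions the trait matrix has,
select a trait subset of that size by an explicit statistical criterion
(or fall back to principal-component pseudo-traits), compute four
standard indices on the chosen subset, and — as a benchmark — sweep every
possible trait combination against an ecosystem property to see how much
the conclusion depends on the choice.

Species richness is the default ecosystem property; any per-community
numeric response can be substituted where a richness vector is accepted.

## Data model and preprocessing

Inputs are a species × trait table of quantitative traits and a
community × species abundance table (delimited text, header row, first
column the ID). Replicated individual-level measurements are collapsed to
species means. Traits are z-standardized (mean 0, unit variance) over the
full species pool so each trait weighs equally and units drop out; the
sample standard deviation (n−1) is the default denominator, switchable to
n. The subset criteria below are invariant to that choice and to trait
order (asserted numerically in the test suite). Standardization happens
once over the full pool; a trait subset is then a column selection, never
a re-standardization, so index values for different subsets are
comparable within one search.

Missing trait values are rejected by default (`missing="drop"` discards
affected species instead); species that appear in the community table but
not in the trait table are an error, never a silent drop.

## Trait dimensionality

Three eigenvalue-based stopping rules on the trait correlation matrix:

* **Kaiser's rule** — eigenvalues strictly greater than 1.
* **Parallel analysis** — thresholds are the mean (default) or the 95th
  percentile (`rule="p95"`) of the rank-ordered eigenvalues of `n_iter`
  (default 1000) random standard-normal n×p matrices; retention proceeds
  from the top while the observed eigenvalue exceeds its threshold and
  stops at the first failure. Seeded and bit-reproducible.
* **Scree elbow** — the rank just before the sharpest bend, located as
  the maximum second difference of the eigenvalue profile; ties go to the
  smallest rank. Cattell's test is visual, so this automation is labelled
  advisory and never drives the consensus alone.

The consensus is the simple majority of the three; if all disagree,
parallel analysis decides. A user override is recorded next to the
consensus, not substituted for it. One caveat worth knowing: on pure
noise the *mean* rule retains ≥2 components in roughly a fifth of seeds
(each rank is passed with ~50% probability, sequentially), while the p95
rule almost always retains none. The mean rule remains the default
because it is the common default in the field's implementations, but the
p95 rule is the conservative choice when a hard noise floor matters.

## Subset-selection criteria

With X the n×p standardized matrix, S = (1/n)XᵗX, κ a k-subset of trait
indices, S_κ the principal submatrix, and [S²]\_(κ) the corresponding
submatrix of S², the three criteria are

* RM  = √( tr([S²]\_(κ) S_κ⁻¹) / tr(S) ) — matrix correlation between X
  and its orthogonal projection onto span(X_κ); 100·RM² is the
  percentage of total trait variation the subset retains;
* GCD = tr([S_{G}]\_(κ) S_κ⁻¹) / √(g·k) — Yanai's generalized coefficient
  of determination between span(X_κ) and the span of the g principal
  components indexed by G (default G = the first k PCs), where S_{G}
  keeps only the G-terms of the spectral decomposition of S;
* RV  = √( tr( ([S²]\_(κ) S_κ⁻¹)² ) ) / √( tr(S²) ) — configuration
  similarity between XXᵗ and its subset-projected counterpart.

All three lie in [0, 1]; RM and RV are monotone nondecreasing under
subset inclusion. The cached-submatrix forms are verified against
explicit projection-matrix oracles to 1e-10 in the acceptance tests.
Collinear subsets make S_κ singular; the Moore–Penrose pseudo-inverse is
used with a warning so the complete search can sweep collinear subsets.

`best_subset` scans all C(p, k) subsets exhaustively for p ≤ 15 (the
target datasets have 7–13 traits); beyond that a seeded simulated
annealing (swap-one neighborhood, geometric cooling, 5 restarts) takes
over. Ties break to the lexicographically smallest subset.

The **HL** route takes, for each of the first k principal components, the
trait with the largest absolute loading; duplicate picks collapse, so the
subset may hold fewer than k traits. The **PC** route uses the first k PC
scores themselves as pseudo-traits; their per-axis variances (the
eigenvalues) are deliberately kept, because rescaling them would break
the isometry that makes k = p PC scores reproduce the full-trait indices
exactly.

## Functional-diversity indices

All four indices operate on Euclidean distances in standardized
(subset) trait space:

* **FAD** — sum of pairwise distances among the species present.
* **FD** — total branch length of the part of a UPGMA (average-linkage)
  dendrogram spanning the community. The dendrogram is built once per
  trait subset over the full species pool and pruned per community; node
  heights are half the cophenetic merge distances, so two species at
  distance d contribute total length d. The pruned subtree excludes any
  path above the community's last common merge (monoculture FD = 0);
  `include_root=True` switches to the root-inclusive variant found in
  part of the FD literature. Per-community re-clustering is available by
  calling `functional_dendrogram` on a community-restricted distance
  matrix, but the pool-dendrogram route is the default and the one the
  complete search uses.
* **Q** (Rao's quadratic entropy) — Σ_{i<j} d_ij p_i p_j with relative
  abundances p. Flags expose the ordered-sum (doubled) and squared
  d²/2 conventions used by other software.
* **FDis** — Σ p_i ‖x_i − c‖ with c = Σ p_i x_i, the abundance-weighted
  centroid.

All are 0 for single-species communities; FAD and FD are monotone under
species addition; all four are invariant to species order and to rigid
rotation of trait space (tested).

UPGMA merging follows scipy's deterministic ordering; for tied distances
this fixes the merge order reproducibly, and merge heights are identical
under any tie-break.

## Association and the complete search

Each index is regressed (OLS) on species richness; the closeness of
association is the coefficient of determination R² (COD), with the
two-sided slope p-value binned into six classes
(≤1e-20, (1e-20,1e-11], (1e-11,1e-5], (1e-5,0.01], (0.01,0.05], >0.05)
for landscape displays. A constant index (possible for single-trait
subsets over monocultures) is flagged degenerate: the row is kept, its
COD is excluded from summaries rather than recorded as 0.

The complete search enumerates all 2^p − 1 nonempty subsets (cap p ≤ 15,
override explicit), computes all requested indices per community with a
vectorized kernel, and records the full COD landscape, per-index best
subsets (ties → smaller subset, then lexicographic — trait identity over
trait number) and by-size marginals. No multiple-testing correction is
applied across the 2^p − 1 regressions: the landscape is descriptive, and
the p-bins are display categories, not inferences.

Methods are compared by a two-way fixed-effects ANOVA of COD on method,
index and their interaction, with datasets as replicates (type-II sums of
squares; equivalent to sequential on the balanced grid), followed by
per-index Tukey HSD at α = 0.05 rendered as compact letters. The CS cell
for each (dataset, index) is that dataset's maximum COD over all subsets,
which makes CS dominance (CS ≥ every method) structural; it is asserted
in every end-to-end test. Whether to include the interaction term and how
to letter the groups were open choices; both are fixed here as stated.

## Synthetic data

`simulate_trait_matrix` draws X = FΛᵗ + ε with standard-normal factors F
(n×g), block loadings Λ (trait j loads factor j mod g with magnitude
0.8 by default) and Gaussian noise (sd 0.6 by default) — defaults chosen
so that ~64% of each trait's variance is common, a strong but realistic
level of trait integration that parallel analysis recovers reliably at
n = 200. `simulate_communities` draws per-community richness uniformly
over a range (default 2–30 on 150 species, 100 communities), members
uniformly without replacement, and abundances equal or lognormal (sd 1).

`plant_association` gives the complete search a known truth. A naive
"nested by distance to the σ*-centroid" assembly turns out not to work:
with full strength every equal-richness community is identical, so every
subset's index is an exact function of richness, and a dispersion ball
whose radius grows with richness makes the planted FAD–richness curve
more convex than the generic quadratic pair-count growth — a linear R²
then ranks the planted subset behind the unplanted ones. The generator
therefore steers each community directly at the measured quantity: it
starts from a random species set and greedily swaps members (seeded)
until the community's σ*-space FAD lies within tolerance of a straight
line in richness whose endpoints are the random-assembly means at the
richness extremes. Off-target subsets keep ordinary sampling noise, so
only σ* carries a tight linear association. `strength` scales the
acceptance tolerance from one random-assembly standard deviation
(strength 0 ≡ random assembly) down to ~0 (strength 1).

What the generator does not emulate: real trait distributions (skewness,
bounded supports), phylogenetic signal, environmental filtering beyond
the planted axis, and observation error on traits. Passing tests show the
machinery recovers planted truth under the factor-model conditions; they
do not certify performance on any particular field system.

## Numerical choices and limitations

* Criterion values are clipped to [0, 1] against roundoff; subset
  submatrix inversion falls back to pseudo-inverse at condition > 1e12.
* Parallel analysis, annealing and all generators take explicit seeds and
  are bit-reproducible.
* Problem sizes in the shipped tests and the reproduction script (pools
  of 40–200 species, 10–13 traits, 100–150 communities, 20–50 replicate
  seeds) were chosen as the smallest scales at which the planted-truth
  recovery rates are stable.
* Qualitative/ordinal traits, Gower distances and PCoA axes are out of
  scope, as are FRic/FEve/FDiv and trait imputation.
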