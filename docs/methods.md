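# Methods

## Scope and model

`agecoex` implements a differential co-expression analysis of cross-sectional
cohort transcriptomes, of the kind used to study immune aging in PBMC
(peripheral blood mononuclear cell) samples across ethnic cohorts. The
pipeline has seven stages, each usable on its own:

1. **Preprocessing** — expression filtering on a linear scale (e.g. keep
   genes with FPKM > 1), log2 transform, optional quantile normalization,
   and outlier-sample removal by average-linkage clustering of sample
   profiles.
2. **Weighted co-expression network** — Pearson correlations are raised to a
   soft power β (unsigned `|r|^β` by default, signed `((1+r)/2)^β`
   optionally); β is chosen as the smallest candidate whose connectivity
   distribution fits a scale-free form with R² above 0.8 and negative slope.
   The topological overlap matrix
   `TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with
   `l_ij = Σ_u a_iu a_uj` combines direct adjacency with shared-neighbour
   strength; genes are clustered by average linkage on `1 − TOM`.
3. **Module summaries** — the module eigengene (ME) is the first principal
   component of the module's standardized expression, rescaled to unit
   sample variance and oriented to correlate non-negatively with the
   module's mean profile. Modules whose eigengenes correlate above
   `1 − merge_cut_height` (default 0.8) merge iteratively. Module–trait
   association is the Pearson correlation of the ME with numerically
   encoded traits (age in years; sex F=0/M=1; multi-level ethnicity as
   one-vs-rest indicators), with two-sided p from
   `t = r·√(n−2)/√(1−r²)` on n−2 df. Gene significance (GS) and module
   membership (MM) are per-gene correlations with a trait and with each ME.
4. **Differential expression** — log2 fold change old − young, a Welch t or
   a moderated t whose pooled per-gene variance is shrunk toward a common
   value `s̃² = (d₀s₀² + d_g s_g²)/(d₀ + d_g)`, where (d₀, s₀²) are
   method-of-moments estimates from the spread of `log s_g²` across genes
   (the inverse-trigamma construction); Benjamini–Hochberg step-up FDR;
   significance requires `|logFC| ≥ 0.5` and adjusted p < 0.05 by default.
5. **Hub ranking** — Maximal Clique Centrality,
   `MCC(v) = Σ_{C ∈ S(v)} (|C|−1)!` over the maximal cliques containing v,
   computed with Bron–Kerbosch enumeration and exact integer arithmetic
   (a single 9-clique already scores 40 320; floats are never used).
   Hub ranking runs on the PPI subnetwork induced by a module or
   intersection gene list, with STRING-style score filtering at 900/1000.
6. **Enrichment** — hypergeometric upper-tail over-representation of a query
   list against user-supplied GMT collections, BH-corrected within each
   collection, flagged significant at adjusted p below the collection's cut
   (0.05 GO-like, 0.01 KEGG-like) and overlap count strictly greater than 6.
7. **Age trajectories and cross-cohort comparison** — a module eigengene's
   age trend is fitted as continuous piecewise-linear least squares over a
   1-year grid of candidate breakpoints (0, 1 or 2 breaks, ≥ 10 years
   apart), selected by BIC with `2 + 2·breaks` parameters; a cubic smoothing
   spline is kept for plotting only. Cohorts are contrasted by PC1 scores
   with Wilcoxon rank-sum tests (exact for n ≤ 8 without ties, otherwise
   normal approximation with tie and continuity corrections). The shared
   signature of two cohorts is the intersection of their age-related module
   genes, its chance level assessed by the hypergeometric upper tail within
   the common gene universe. A `2^-ΔΔCt` helper supports qPCR re-validation
   of hub genes.

The network stage and the trajectory stage are exposed as model/results
pairs (`CoexpressionNetwork.fit() → CoexpressionResults`,
`PiecewiseAgeTrajectory.fit() → TrajectoryFit`) with `summary()` tables;
the combinatorial and IO operations are plain functions.

## Synthetic data: what it emulates and what it does not

Because the real inputs (a public microarray compendium and an undeposited
RNA-seq cohort) are not redistributable, every stage is validated against a
synthetic generator with known truth. Expression follows a factor model:
each planted module has a latent eigengene
`e = standardize(effect(age)) + N(0, σ_e)` — with `effect` linear, piecewise
linear with a breakpoint, or absent (an age-independent standard-normal
draw) — and each module gene is `loading·e + N(0, σ_g)` with loadings
drawn from (0.6, 0.95). Background genes are i.i.d. N(0, 1). The factor
model is chosen deliberately: the pipeline's module summary is a first
principal component, so the planted eigengene and the estimand coincide and
recovery is well defined.

Default study conditions, fixed once: 10 modules × 50 genes over 500
background genes, n = 60 donors with ages uniform on 21–93 years,
σ_e = 0.3, σ_g = 0.5. The two-cohort design plants a shared 95-gene module
(linear age effect, two hubs) plus one 150-gene cohort-specific module each,
over 1600 background genes per cohort — keeping planted age-gene sets near
a tenth of the ~2000-gene universe, the approximate geometry of the real
cohorts (age modules of 1.7–2.6k genes in 19–29k-gene universes), so the
overlap test has a meaningful chance level. Ages are uniform rather than
age-stratified (stratification available via explicit age lists); sex is a
balanced label with no expression effect by default. PPI graphs plant each
hub at the centre of two 6-cliques drawn from its own module (a windmill),
with background edges at probability 0.02: with a single planted clique
every member would score exactly (c−1)! and the hub would be
indistinguishable from its neighbours, so the two-clique construction is
what makes "the planted hub ranks first" a property of the graph rather
than of tie-breaking.

What the generator does **not** emulate: count noise (values are Gaussian
on a log-like scale; an exponential `to_fpkm_like` transform exercises the
linear-scale filter path only), cell-type composition shifts with age,
batch structure, correlated background genes, and probe-level artefacts.
Passing recovery tests therefore demonstrates the pipeline's correctness
and statistical calibration under its own model, not robustness to every
failure mode of real PBMC data.

Two structural facts about the generator matter when designing planted
truths. First, linear age effects of any slope standardize to the same
eigengene base, so two linear-effect modules are collinear up to noise and
no correlation-based method can separate them; planted sets therefore use
effects distinct in *shape* (linear vs. breakpoints at different ages vs.
none). Second, in an unsigned network, modules with opposite-signed
age trends are |r|-identical and fuse; the default module set avoids
opposite-slope pairs for the same reason.

## Module detection: persistence selection

The original method family uses dynamic tree cutting because, on realistic
data, no single dendrogram cut height separates modules: module–module,
module–background and background–background merges interleave within a few
1e-4 of dissimilarity near the top of the tree (we observe exactly this on
the default synthetic conditions, where every static quantile cut either
fuses modules or caps recovery well below ARI 0.8). The package's default
(`cut_modules(..., method="adaptive")`) instead scores every internal
dendrogram node by its *persistence* — the height interval between the
merge that completes the cluster and the merge that fuses it onward, the
root dying at dissimilarity 1 — and greedily selects non-nested clusters of
size ≥ `min_module_size` in decreasing persistence. An assembled module
survives unchanged from its formation (low height) to the final
coalescence, while transient background agglomerates live only between
consecutive merges, so persistence cleanly separates the two without a
tunable height. A static cut at a quantile of merge heights
(`method="quantile"`, `--cut-quantile`) is retained for reference and for
cleanly separated data. On uniform-random TOM input the persistence rule
returns at most one (meaningless) module; the module–trait stage is then
the guard against over-interpretation.

## Numerical choices

- Correlation p-values use the t transform; |r| = 1 maps to the smallest
  positive float rather than 0 so p stays in (0, 1]. A permutation oracle
  (10⁵ permutations) validates the transform in the tests.
- The hypergeometric upper tail is summed in log space (log-gamma +
  logsumexp); tests verify agreement with exact rational arithmetic to
  1e-10 relative error for every instance with N ≤ 60.
- BH adjustment is the standard step-up with a reverse cumulative minimum,
  capped at 1, mapped back to input order.
- MCC scores are Python integers throughout; clique enumeration refuses
  graphs above 2000 nodes unless the ceiling is raised explicitly.
- Degenerate DE genes: zero variance in both groups gives p = 1 when the
  means agree and the minimum representable p when they differ.
- Trajectory BIC uses `n·log(RSS/n) + k·log(n)` with `k = 2 + 2·breaks`
  (each breakpoint contributes a location and a slope change); RSS is
  floored at 1e-12 so noiseless fits select the most parsimonious exact
  model. Breakpoints are restricted to the open observed age range.
- Module labels are deterministic: clusters ordered by size (ties by
  smallest gene ID) are named from a fixed color palette, then numeric
  suffixes — repeated runs are byte-identical.
- Outlier cut height defaults to mean + 2.5 SD of the merge heights; the
  value is exposed because the convention is not standardized.
- Quantile normalization resolves within-sample ties by averaging the
  reference values at the tied rank positions, making it idempotent.

## Deliberately open points, resolved as follows

- The unsigned network is the default (`network_sign="signed"` available).
- The FPKM expression filter reads "expressed in all samples"
  (`min_fraction=1.0`) but the fraction is configurable, since the source
  convention is ambiguous between "all" and "any".
- The DEG |logFC| threshold defaults to 0.5 with 1.0 in common use for
  RNA-seq cohorts; it is a per-run setting.
- Enrichment "count > 6" is strict (k ≥ 7), and each GMT collection forms
  its own BH family.
- The enrichment universe is the set of genes surviving preprocessing, not
  an annotation-wide background.
- Isolated PPI nodes score MCC 1 (their singleton maximal clique);
  configurable to 0.
- Soft-threshold selection on planted-module data usually cannot reach the
  scale-free target — block-structured truth gives a bimodal connectivity
  distribution — and then falls back, with a logged warning, to the
  candidate maximizing R² among negative-slope fits. The target-reaching
  branch is exercised on genuinely scale-free correlation structure.

## Problem sizes

The test battery and the acceptance script run everything at desk scale,
chosen as the smallest sizes at which each property is statistically
crisp: 30-gene exact-oracle checks for TOM, ≤ 12-node exhaustive oracles
for MCC, 1 050-gene single-cohort and 1 995-gene two-cohort recovery
experiments over 5 seeds, 5 000-gene × 20–60-sample DE calibrations, and
100-sample trajectory fits. The network stage is dense (O(p²) memory) and
is intended for ≤ ~5 000 genes after filtering; blockwise approximations
for larger gene sets are out of scope.

## Known limitations

- Module detection is the package's own persistence rule, not the original
  dynamic-hybrid algorithm; on data with strong nested substructure the two
  can differ.
- The DE moderated test assumes roughly equal group variances (it pools);
  the Welch option drops that assumption but is not moderated.
- No covariate adjustment (sex, batch) in the DE model.
- Breakpoint inference assumes piecewise-linear trends; smoothly quadratic
  aging trajectories will be approximated by one or two kinks.
- Enrichment is set-based ORA only: no topology-aware GO methods, no
  ranked GSEA.
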