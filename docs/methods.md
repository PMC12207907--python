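# Methods

This note documents the models, conventions, and numerical choices behind
the package, and what its synthetic-data tests do and do not establish.

## The synthetic gradient metacommunity

The generator emulates an amplicon survey of a one-dimensional
river–estuary–sea transect. Defaults describe the emulated survey scale:
50 sites evenly spaced over 1900 km, a linear salinity-like gradient over
0–33.7 PSU, 200 taxa, 2000 reads per sample, and up to three sample
fractions — free-living (FL), particle-associated (PA), and sediment —
that differ only in dispersal scale (multipliers 1.0 / 0.5 / 0.2,
reflecting that benthic and particle-attached organisms disperse less
readily than free-living cells).

**Phylogeny and niches.** Taxa arise on a pure-birth (Yule) tree with
exponential waiting times, scaled to depth 1 (ultrametric). Each taxon's
niche optimum μ_i evolves as Brownian motion along the tree and is
affinely mapped onto the gradient range, so optima are phylogenetically
conserved; `phylo_signal='shuffled'` permutes optima across tips,
destroying the signal while preserving the marginal distribution. On a
depth-1 Yule tree roughly half of all tip pairs coalesce at the root, so
the *pairwise* trait–distance correlation of a single realization is
positive but modest (≈ 0.1–0.25); the conservatism that matters for
bin-based null models lives inside clades and is clearly recovered by the
process-recovery tests.

**Abundances.** Expected relative abundance at site *s* is

    p_i(s) ∝ exp(−(E_s − μ_i)² / (2σ²))^λ · m_i(s),
    m_i(s) = Σ_t exp(−d_st / δ_f) · A_i(t),

with σ the niche breadth (default 5 PSU ≈ 0.15 of the gradient span),
λ ≥ 0 the selection strength (λ = 0 is the neutral limit), and m_i(s)
immigration from a fixed latent regional pool A (independent log-normal
abundances per taxon per site) under an exponential dispersal kernel at
scale δ_f = δ × fraction multiplier. `dispersal_scale=inf` is the exact
uniform-mixing limit. Counts are one multinomial draw of N reads per
sample; finite-N sampling is the model's only drift term — enough to
create RC_bray-detectable stochasticity without birth–death dynamics.
The latent-pool and multinomial random streams are independent of the
parameter values, so changing λ alone leaves pool and sampling noise
fixed — the handle used by the monotonicity tests.

**Regime labels** (bookkeeping, not science claims): selection-dominated
when λ ≥ 2; dispersal-limited when λ < 0.5 and δ ≤ 0.1 × transect;
otherwise drift-dominated. Thresholds are recorded in the parameters.

**What the generator does not emulate:** hydrodynamics, particle
aggregation, temporal dynamics, sequencing error, compositional biases of
library prep, or real taxonomic structure. Passing recovery tests shows
the estimators respond correctly to known selection/dispersal/drift
signals of this simple form; it does not validate them on real data.

## Conventions and numerical choices

* **Community tables** are samples × taxa, non-negative integers, exact
  case-sensitive ID matching; relative abundances are recomputed at point
  of use, never stored. Missing branch lengths read as 0 with a warning;
  mid-point rooting of unrooted trees is the caller's responsibility.
* **Shannon** uses natural log; Pielou is base-invariant and reported
  missing for single-taxon samples. **Faith PD** spans observed tips to
  their MRCA by default; `include_root=True` adds the MRCA→root path
  (both conventions are tested; the root-inclusive one matches
  scikit-bio's `faith_pd`). **Rarefaction** subsamples without
  replacement via the multivariate hypergeometric distribution; the
  analytic curve uses E[S] = Σ_i [1 − C(T−n_i, d)/C(T, d)] computed with
  log-gamma for stability.
* **SPEC-OCCU** means are taken over *all* samples of a class, zeros
  included (the plain reading of "average count"), on raw counts by
  default; a `relative=True` variant removes library-size sensitivity,
  which the tests document explicitly. A taxon selected in any class's
  top-n receives records for every class, so its specificity denominator
  always spans all classes and specificities sum to 1.
* **β partitioning** uses the Jaccard-based Podani decomposition
  (additivity is exact by construction). Horizontal β pools presence sets
  by union within a site. Geographic distances are haversine with Earth
  radius 6371.0088 km — linear distance, not along-river distance.
  Distance–decay fits similarity (1 − dissimilarity) on distance, so the
  expected slope under decay is negative; the permutation test (default
  999 permutations, (count+1)/(n+1)) is two-sided by default because a
  one-sided "greater" test has no power against negative correlations.
* **Binning** is post-order: a clade becomes a bin the first time its
  unassigned tip count reaches the limit (64 by default, per the standard
  bin-size choice for this framework); leftover clades merge into the bin
  with the nearest triggering-node MRCA by patristic distance.
  Deterministic for a fixed tree.
* **βNRI/βNTI** use abundance-weighted βMPD (default) or βMNTD, with
  relative abundances renormalized within the evaluated subset. The null
  shuffles tip labels within each bin (the iCAMP convention;
  `shuffle_scope='tree'` shuffles across the whole tree). Randomizations
  (default 999) are generated once per bin and shared across pairs, which
  both matches the framework and makes large pair sets cheap — the βMPD
  null for all pairs is a batched quadratic form against the same stack
  of permuted patristic matrices. A null with sd = 0 (within floating
  tolerance) yields a missing z: with ≤ 2 taxa, or on an equal-distance
  tree, every shuffle reproduces the observed value and no standardized
  effect exists.
* **RC_bray** nulls preserve each sample's richness and read total;
  membership is drawn ∝ metacommunity occupancy, one read seeds each
  member, and the rest are multinomial ∝ metacommunity relative
  abundance. RC = 2·[(#null < obs) + ½·(#null = obs)]/n_rand − 1.
* **Process weights**: a bin's weight for a pair is the mean of the two
  samples' whole-community relative abundance summed over the bin's taxa,
  renormalized across bins; per-pair fractions sum to 1 (an
  `unclassified` category absorbs bins where a sample has no reads, so
  closure is exact). Group fractions are unweighted means over pairs.
* **Networks**: Spearman on per-sample relative abundances by default
  (compositional practice; raw counts by flag), average ranks for ties,
  t-approximation p-values, BH-FDR across all pairs. The RMT scan zeroes
  |ρ| below each candidate threshold, collapses degenerate eigenvalues
  (within 1e-8), unfolds the spectrum with a smoothing-spline fit to the
  cumulative spectral function, and Kolmogorov–Smirnov-tests the
  nearest-neighbour spacings against Exp(1); the smallest
  Poisson-consistent threshold is selected, and degenerate scans return a
  flagged result rather than raising. 0.76 and 0.86 ship as documented
  presets for whole and regional water networks. Topology is a fixed
  11-column vector (nodes, edges, average degree, clustering, average
  path length, modularity, density, diameter, betweenness and degree
  centralization with Freeman normalization, mean closeness); path
  metrics use the largest connected component; modularity uses greedy
  agglomerative (CNM) communities, deterministic for a fixed graph.
  Robustness removes ⌊f·n⌋ random nodes, then iteratively removes
  edgeless nodes (secondary extinction); survivors / initial nodes.
* **PERMANOVA** decomposes squared dissimilarities by the standard
  group-sum identity; p-values permute labels with the (count+1)/(n+1)
  convention. **Partial Mantel** correlates control-regressed residuals
  of the (rank-transformed, for Spearman) distance vectors; a matrix
  fully explained by the control has partial r = 0 by convention.
  **CCA** chi-square-standardizes the count matrix, regresses it onto
  row-weighted environmental variables, and eigendecomposes the fitted
  values (constrained eigenvalues match scikit-bio's CCA to 1e-10).
  **VPA** uses RDA on Hellinger-transformed counts with Ezekiel-adjusted
  R²; fractions close to 1 exactly, may be slightly negative, and are
  flagged rather than clamped. **VIF** elimination drops the
  largest-VIF variable until all are below 10 (the configurable default;
  perfectly collinear variables count as infinite and go first).

## Calibration and test design

Two properties deserve explicit framing:

* **Null calibration.** Within one well-mixed neutral metacommunity all
  sample pairs share a single realized abundance-vs-tree configuration,
  so their βNRI z-scores are strongly correlated — one dataset provides
  roughly one effective draw and cannot estimate a 5 % rejection rate to
  ±2 points. The calibration test therefore pools 50 replicate neutral,
  phylogeny-signal-free metacommunities (each 20 sites × 200 taxa, 50
  pairs, 999 randomizations); pooled z-scores are close to standard
  normal and the pooled |z| > 1.96 rate sits at the nominal level.
* **Saturation and monotonicity.** Selection strength increases the
  coupling between environmental distance and Bray–Curtis dissimilarity,
  but once dissimilarity saturates at 1 the Spearman statistic plateaus
  and fluctuates by rank-tie noise (~0.01); the monotonicity test allows
  that tolerance while requiring a large neutral-vs-selection gap.

Problem sizes in the test-suite and acceptance script (20 sites and
150–200 taxa for null-model runs, 999 randomizations, ≤ 150 pairs,
12–16 sites for pipeline smoke runs) are the package's chosen desk-scale
study conditions; all complete in minutes on one CPU.

## Known limitations

* The RMT unfolding procedure is one defensible implementation of the
  spacing-transition idea; published threshold scanners differ in
  smoothing details, so selected thresholds are comparable only
  qualitatively.
* Modularity values depend on the community-detection algorithm; only
  CNM-greedy values are comparable across runs of this package.
* The exact composition of the "11 interaction indices" used as biotic
  VPA inputs varies between studies; the fixed 11-column schema here is
  documented above, and VPA results depend on which columns survive the
  completeness/variance screen.
* RC_bray null draws are shared per sample across pairs within a bin
  (not redrawn per pair); this matches the shared-randomization design
  and keeps pair sets cheap, at the cost of weak dependence between RC
  values of pairs sharing a sample.
* Distance-based (db-RDA) variation partitioning, Baselga-family β
  decomposition, NST/pNST indices, and abundance-weighted robustness are
  intentionally out of scope.
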