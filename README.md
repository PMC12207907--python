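# continuum-assembly

Tools for quantifying the spatial dynamics and assembly processes of
prokaryotic (16S ASV) communities along strong environmental gradients —
the river → estuary → coastal-sea setting where free-living (FL),
particle-associated (PA), and sediment communities turn over across
hundreds of kilometres and a 0–34 PSU salinity gradient.

The package implements, as one tested library with a CLI:

* **Alpha diversity** — rarefaction (exact without-replacement subsampling
  and the analytic hypergeometric rarefaction curve), Shannon H′ (nats),
  observed richness, Pielou evenness, Faith PD (MRCA-spanning by default).
* **Specificity–occupancy (SPEC-OCCU)** — for taxon *S* and habitat class
  *H*: specificity = mean count of *S* in *H* / Σ over classes of mean
  counts; occupancy = fraction of *H*'s samples containing *S*;
  specialists have both ≥ 0.7.
* **β-diversity partitioning** — Jaccard dissimilarity decomposed
  (Podani family) into species replacement and richness difference:
  β_total = (b+c)/(a+b+c) = β_repl + β_rich with
  β_repl = 2·min(b,c)/(a+b+c), β_rich = |b−c|/(a+b+c); plus "horizontal"
  β against the pooled ASV set of the most upstream site, haversine
  geographic distances, and distance–decay of similarity with a
  Spearman–Mantel permutation test.
* **Bin-based null-model process classification** (iCAMP-style) —
  phylogenetic bins (clades of ≥ 64 tips by default), abundance-weighted
  βMPD/βMNTD against tip-shuffling nulls (βNRI/βNTI z-scores), Raup–Crick
  on Bray–Curtis (RC_bray), and the five-process rule:
  z > +1.96 heterogeneous selection; z < −1.96 homogeneous selection;
  otherwise RC > 0.95 dispersal limitation, RC < −0.95 homogenizing
  dispersal, else drift. Per-pair fractions are abundance-weighted across
  bins and aggregated per group.
* **Co-occurrence networks** — abundance/occurrence filtering (> 0.01 %
  relative abundance, > 20 % occurrence), Spearman edges with BH-FDR,
  random-matrix-theory threshold selection (nearest-neighbour eigenvalue
  spacing vs the Poisson law), an 11-feature topology vector, per-sample
  induced subnetwork features ("interaction indices"), and robustness to
  random removal of 50 % of nodes with secondary extinction.
* **Multivariate statistics** — PERMANOVA, Mantel and partial Mantel,
  CCA, VIF-based variable pruning, and two-matrix variation partitioning
  (abiotic environment vs biotic interaction indices) via RDA on
  Hellinger-transformed counts with Ezekiel-adjusted R².
* **A synthetic gradient-metacommunity generator** — Yule phylogeny,
  Brownian (phylogenetically conserved) niche optima, Gaussian
  environmental filtering of strength λ, exponential distance-decaying
  immigration from a latent regional pool at scale δ (with
  fraction-specific multipliers), and multinomial read sampling. It
  provides ground truth (known regimes: selection-dominated,
  dispersal-limited, drift-dominated) for every analysis stage.

## Worked example

Simulate a 16-site transect under strong selection and classify the
assembly processes behind every pair of communities:

```bash
$ continuum-assembly simulate --params quick.yaml --out demo
simulated 16 samples x 120 taxa (regime: selection_dominated) -> demo

$ continuum-assembly assembly --table demo/community.tsv --tree demo/tree.nwk \
      --bin-size-limit 48 --n-rand 499 --seed 1 --out demo/assembly.tsv
     heterogeneous_selection  homogeneous_selection  dispersal_limitation  homogenizing_dispersal   drift  unclassified
all                   0.5061                 0.1576                0.1148                  0.0792  0.0921        0.0502

$ continuum-assembly beta --table demo/community.tsv \
      --metadata demo/metadata.csv --seed 1 --out demo/beta.tsv
distance-decay slope=-0.0004185 rho=-0.980 p=0.0010
```

Under strong selection most pair/bin combinations are classified as
selection (heterogeneous across the gradient, homogeneous between
similar-environment sites), and similarity decays significantly with
distance (Spearman ρ = −0.98, permutation p = 0.001). The `run`
subcommand executes the whole nine-stage pipeline from one YAML config
(see `configs/example.yaml`) and writes a manifest with per-stage seeds
and checksums; reruns are byte-identical.

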