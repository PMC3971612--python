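# syntropy

Integrative analysis of paired 16S microbiome and UPLC-MS metabolome data
from the same subjects: who covaries with what at the mucosal surface, and is
the covariation more than noise?

The package is for microbiome researchers with two tables per cohort — a
sample x OTU count table (with taxonomy) and a sample x metabolite-feature
intensity table (with m/z, retention time and ionisation mode) — plus,
optionally, per-OTU imputed KEGG pathway profiles and a phylogeny. It
implements the full inter-omic workflow as a library with a thin
command-line front end:

- **Preprocessing** — rarefaction to a common depth, detection filters,
  the 18% prevalence threshold.
- **Metabolite modules** — weighted-correlation-network construction:
  adjacency |cor(x_i, x_j)|^β with β picked by scale-free fit, topological
  overlap dissimilarity TOM, average-linkage branch cutting (minimum module
  size 10), and an *eigenmetabolite* per module: the first left singular
  vector of the standardized module submatrix, with variance explained
  σ₁²/Σσ².
- **Inter-omic network** — Spearman ρ for every (OTU, analyte) pair with
  permutation-calibrated two-sided p-values and Storey q-values
  (q(p₍ᵢ₎) = min₍ⱼ≥ᵢ₎ π̂₀·m·p₍ⱼ₎/j); edges kept at q < 0.2; summaries per
  phylum and per genus (duplicate metabolite correlations collapsed).
- **Global concordance** — symmetric Procrustes on 2-D PCA configurations
  (m₁₂² = 1 − (Σ singular values)²) and the co-inertia RV coefficient
  trace(XᵀYYᵀX)/√(trace((XᵀX)²)·trace((YᵀY)²)), both with row-permutation
  Monte Carlo significance.
- **Metabolite-driven microbial clusters** — complete-linkage Euclidean
  clustering of OTU correlation profiles, cluster number by prediction
  strength, phylum composition, and cross-region overlap via one-sided
  Fisher exact tests with Bonferroni flags.
- **Imputed-function tests** — Kruskal–Wallis pathway differentiation across
  clusters and Pearson concordance between a metabolite's OTU-correlation
  profile and its candidate pathway's genomic abundance.
- **Community structure** — SparCC compositional correlations
  (ρ̂ᵢⱼ = (ωᵢ+ωⱼ−Tᵢⱼ)/2√(ωᵢωⱼ) from log-ratio variances Tᵢⱼ, Dirichlet
  draws, iterative strongest-pair exclusion) and a 1,000-permutation test of
  whether metabolite-associated OTU groups are more structured than random
  groups, with total phylogenetic branch length per group.
- **Putative identification** — adduct-aware exact-mass lookup
  ([M+H]⁺/[M+Na]⁺, [M−H]⁻/[M+Cl]⁻) within 20 ppm, and cross-region feature
  matching at ≤0.005 m/z and ≤0.04 min.
- **Synthetic data** — a paired-region generator that plants modules,
  signed OTU–metabolite links, guilds, concordant pathway profiles and
  shared metabolites, returning the full ground truth for validation.

## Worked example

Each script in `examples/` builds a small synthetic input, runs one
capability and prints what it computes. Discovering planted OTU–metabolite
links (`examples/02_interomic_network.py`):

```text
12000 pairs tested, 19 edges at q<0.2
planted links recovered: 15/15
unique OTU nodes 19, mean edges per metabolite 1.06
```

All 15 planted links (target |Spearman| = 0.7, n = 46) survive the q < 0.2
threshold, with 4 extra calls among 12,000 tests — the FDR level bounds such
extras at roughly one in five of the edge list. Testing whether a planted
two-guild community is more structured than chance
(`examples/06_community_structure.py`):

```text
group of 10 OTUs, total branch length 32.86
mean positive correlation 0.407 (P = 0.001)
mean negative correlation -0.082 (P = 0.576)
pairs with correlation > 0.2: 24 (P = 0.001); < -0.2: 4 (P = 0.777)
```

The group's mean positive SparCC correlation (0.407) exceeds that of all
1,000 random same-size OTU groups (P = 1/1001): the planted within-guild
cohesion is unambiguous, while the cross-guild avoidance is attenuated by
the estimator (see `docs/methods.md`).

A full pipeline run from the shell:

```bash
syntropy simulate --config examples/pipeline.yaml --out demo_data
syntropy run-all  --config examples/pipeline.yaml
```

writes per-stage tab-delimited tables (edges, module assignments,
concordance statistics, cluster assignments and overlaps, pathway tests,
community-structure rows, putative IDs, cross-region matches) plus a
`manifest.json` of SHA-256 hashes; re-running with the same seed reproduces
the hashes exactly.

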