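# Methods

`syntropy` implements an integrative analysis of paired mucosal 16S
microbiome and UPLC-MS metabolome measurements taken from the same subjects
in two colonic regions, together with a synthetic-data generator that plants
every structure the analysis is designed to recover. This note records the
models, the numerical choices, and the limits of what the tests demonstrate.

## The synthetic data model

The generator (`syntropy.synthetic`) emulates a two-region cross-sectional
study: ~46 subjects, one sample per region, 16S counts rarefied-scale deep
(mean read depth 30,000), a few hundred OTUs and metabolite features.

**Microbiome.** Each OTU i has a basis log-abundance
z_i ~ N(mu_i, 1) with mu_i ~ N(0, 1.5) fixed per dataset; guilds are blocks
of OTUs whose basis log-abundances share a correlation `guild_corr`
(optionally a negative `guild_cross_corr` between the first two guilds, the
co-exclusion pattern). Per sample, fractions are the softmax of z and counts
are multinomial at a Poisson(read_depth_mean) depth. This log-normal-basis +
multinomial model is the standard setting in which compositionality-corrected
correlation estimators are analysed, which makes "truth recovery" well
defined: the target of SparCC is exactly the planted basis correlation.
Guild and planted-link OTUs are drawn from the abundant half of the mu
distribution — links among taxa that the detection and prevalence filters
would discard are not informative about the analysis, and real reported
associations concern detectable taxa.

**Metabolome.** Intensities are log-normal. On the log scale, a module
member equals sqrt(w)·F_m + sqrt(1-w)·eps with a per-module latent factor
F_m ~ N(0, I) and w = `module_corr` (default 0.8), so the pairwise
within-module correlation is w. A linked metabolite equals
sqrt(v)·s + sqrt(1-v)·eps, where s is the (sign-carrying, averaged over the
linked OTUs) Gaussian-score transform of the observed relative abundance of
its OTU(s), and v = (2·sin(pi·s*/6))^2 converts the target Spearman
correlation s* (= `link_effect`) into the latent Pearson weight via the
bivariate-normal rank-correlation identity rho_S = (6/pi)·asin(rho/2). The
coupling is monotone in the OTU's abundance rank, so Spearman — not Pearson —
is the natural detector. With `link_otus_from_guilds`, one metabolite is tied
to several OTUs of the same guild ("metabolite-associated community").

**Pathways, tree, taxonomy, regions.** Each linked metabolite is assigned a
pathway whose per-OTU relative genomic abundance is exp(1.5·effect + noise),
row-normalised — a monotone image of the planted link effects, so the
metabolite-metagenome concordance test has a recoverable positive target.
The phylogeny is a pure-birth (Yule) tree with strictly positive branch
lengths; taxonomy strings use seven GreenGenes-style ranks with
Bacteroidetes/Firmicutes-dominant phylum frequencies and ~60% genus-level
resolution. A configurable fraction of metabolite identities is shared
between regions; shared features reappear with Gaussian m/z jitter
(sd 0.001) and retention-time jitter (sd 0.01 min), and region-unique
identities sit on a mass grid separated by >0.01 m/z.

**What the generator does not emulate** — and hence what green tests do
*not* establish about real data: realistic zero-inflation beyond multinomial
sampling, sequencing batch or extraction effects, heavy-tailed or censored
MS intensities, ionisation suppression, chimeric features, subject-level
covariates (age, disease), or any biochemical relationship between the
planted pathway labels and real KEGG content.

## Preprocessing

Rarefaction subsamples each sample without replacement to a fixed depth
(default 30,000 reads); shallower samples are dropped with a logged warning.
Detection filters keep features with value above a background threshold
(default 0) in at least `min_samples` samples (boundary inclusive);
the prevalence filter removes analytes detected in *fewer than* 18% of
subjects, so exactly 18% is retained. "Above background" is operationalised
as strictly positive after upstream processing, with the threshold
configurable, since upstream tools differ in what they emit for
non-detections. All filters are idempotent.

## Inter-omic network

Spearman's rho is computed for every (OTU, analyte) pair as Pearson
correlation of midranks, vectorised over the full matrix; zero-variance
vectors give undefined rho and are excluded with a logged count.

**p-values.** Below 10 samples the exact permutation distribution is
enumerated. At cohort scale the default is a *pooled permutation-calibrated*
p-value: the sample rows of the analyte table are permuted 50 times, all
pairs' |rho| values pooled into one empirical null (the permutation
distribution of rho is pair-exchangeable to good approximation: its variance
is exactly 1/(n-1) for any tie pattern), and each observed |rho| is referred
to that pool with an add-one correction. The classical t approximation is
kept as an option but is not the default because its far tail is measurably
anti-conservative at this n (about 1.3-1.45x at the thresholds where the
smallest order statistics of 6·10^4 tests live, by 4·10^6-draw simulation at
n = 46), which quietly inflates the realized false-discovery rate of the
q-value stage. An Edgeworth-type correction was evaluated and rejected: the
series becomes negative exactly in the far tail this application needs.

**q-values.** Storey's procedure: pi0(lambda) = #{p > lambda}/(m(1-lambda))
on lambda = 0.05..0.95, extrapolated to lambda -> 1 by a least-squares cubic,
clamped to (0, 1] with fallback pi0 = 1; q(p_(i)) = min_{j>=i}
pi0·m·p_(j)/j. With pi0 = 1 this is exactly Benjamini-Hochberg. The
significance threshold is strict: q < 0.2.

Genus binning collapses duplicate metabolite correlations so a genus
correlating with one metabolite through many OTUs counts once; genus is the
sixth taxonomy rank, with empty or bare `g__` entries excluded as
unresolved. Network summaries report per-phylum ratios over the detected-OTU
universe and mean edges per node.

## Metabolite modules

Unsigned weighted-correlation-network construction: adjacency
a_ij = |cor(x_i, x_j)|^beta. The soft threshold beta is the smallest
candidate whose scale-free fit index (signed R^2 of log10 p(k) on log10 k
over 10 connectivity bins) reaches 0.8, else the argmax; the candidate grid
spans 1-10 and even values to 40. Topological overlap
TOM_ij = (L_ij + a_ij)/(min(k_i, k_j) + 1 - a_ij), L = A^2 restricted to
off-diagonal paths; 1 - TOM is the clustering dissimilarity.

Modules are branches of the average-linkage tree cut at 0.99 of the maximum
merge height, with branches smaller than `min_module_size` (default 10)
returned as `unclustered`. This static branch cut is the parameter-light
simplification of dynamic tree cutting: on TOM dissimilarities background
metabolites merge within a fraction of a percent of the maximum height, so
the 0.99 cut isolates exactly the coherent branches, and it is deterministic
and order-invariant. After cutting, module membership is pruned: members
with |cor(member, eigenmetabolite)| < 0.5 (the conventional core-membership
kME cutoff) return to unclustered and the eigenmetabolite is recomputed;
without this step a handful of chance-correlated background metabolites
(kME ~ 0.4 at n = 46) attach to otherwise clean branches.

The eigenmetabolite is the first left singular vector of the per-metabolite
z-scored sample x member submatrix, unit norm, sign-oriented so its mean
correlation with members is positive; variance explained is the first
squared singular value over the total. Validation reports mean silhouette on
1 - Pearson distances, cophenetic correlation of the module tree, and
adjusted-Rand agreement with plain 1 - Pearson average-linkage clustering
and with k-means at the same k. Downstream analyses use the module
eigenmetabolites concatenated with the raw columns of unclustered
metabolites.

## Global concordance

PCA is the SVD of the column-centered table (classical scaling of Euclidean
distances); Procrustes operates on the first two principal-component
configurations, matching two-dimensional ordination overlays. Symmetric
Procrustes centers both configurations, scales each to unit sum of squares
and takes m12^2 = 1 - (sum of singular values of X'Y)^2; significance
permutes the sample rows of one configuration,
p = (1 + #{congruence >= observed})/(1 + n_perm), default 999 permutations.
Co-inertia concordance is the RV coefficient
trace(X'Y Y'X)/sqrt(trace((X'X)^2)·trace((Y'Y)^2)) on column-centered
tables (a PCA-reduced variant is available behind a flag; the default is the
raw centered tables), with the same row-permutation test; per-feature
weights are the loading norms on the first two co-inertia axes, giving the
covariance-strength ranking of individual OTUs and metabolites.

## Metabolite-driven microbial clusters

OTUs are described by their full, unthresholded rho profile against analytes
that carry at least 2 significant OTU edges; undefined cells are imputed as
0 (count logged) because Euclidean clustering needs complete rows.
Complete-linkage hierarchical clustering on Euclidean distances is cut to
exactly k groups by undoing the last k-1 merges, which coincides with the
minimal-height cut when one exists and otherwise splits the largest cluster
at its topmost internal merge (logged). The cluster number is chosen by
prediction strength: repeated random 2-fold splits, k-means on both halves,
test points classified by nearest training centroid, ps(k) = the
worst-cluster proportion of co-clustered test pairs that the training
centroids also co-assign, averaged over splits; k* is the largest k with
ps(k) >= 0.8 (threshold exposed in config). Cross-region cluster overlap
uses one-sided (greater) Fisher exact tests — computed as exact
hypergeometric tails — on 2x2 membership tables over shared OTUs, flagged at
Bonferroni-corrected P < 0.05 over all k1·k2 cells.

## Imputed-function analyses

The pathway profile (OTU x KEGG pathway relative genomic proportions) is an
input; `single_count_profile_convention` emits the OTU x OTU identity count
table used to obtain per-OTU metagenomes from external imputation tools.
Pathway differentiation across clusters uses tie-corrected Kruskal-Wallis
per pathway, Bonferroni over pathways, with per-cluster enrichment/depletion
directions from mean ranks; clusters with fewer than 2 profiled OTUs are
excluded with a warning. Metabolite-metagenome concordance: for each
metabolite with >= 5 significant OTU edges and >= 1 putative compound, the
vector of its Spearman correlations against *all* detected OTUs is compared
(Pearson) with the candidate pathway's abundance across the same OTUs;
undefined rho cells drop pairwise; Bonferroni runs over all tested
(metabolite, pathway) records and each record is labelled positive /
negative / not significant at corrected P < 0.05.

## Community structure of metabolite-associated microbes

SparCC: per Dirichlet draw (posterior fractions under a uniform prior,
20 draws), the log-ratio variation matrix T_ij = Var log(f_i/f_j) is formed
and basis variances solved from the sparsity-approximation linear system
((D-2)I + J) omega = row sums of T; the strongest-|rho| pair is then
iteratively excluded (its T contribution zeroed, the system matrix
decremented) up to 10 rounds or until no pair exceeds 0.1; rho_ij =
(omega_i + omega_j - T_ij)/(2 sqrt(omega_i omega_j)), medianed over draws
and clipped to [-1, 1]. Basis variances are floored at 10^-4. All stages are
batched over draws.

**A documented identifiability limit.** A *homogeneous* equicorrelated group
analysed alone is nearly invisible to this decomposition: with
T_ij = 2 sigma^2 (1 - rho) for all pairs the solved basis variances absorb
the common correlation and the estimate cancels to zero; only finite-sample
heterogeneity plus the exclusion mechanism recovers part of it, so power
against a lone uniform guild is modest. Heterogeneous structure — two
cohesive sub-communities that exclude each other, the pattern of interest in
metabolite-associated groups — is detected with near-maximal evidence. The
exclusion budget corrects the strongest pairs first, so when positive and
negative structure coexist the weaker side is attenuated.

The group test scores a metabolite-associated OTU set (>= 4 members, drawn
from the table filtered to OTUs present in >= 6 samples) by mean positive
and mean negative off-diagonal SparCC correlation plus counts above +0.2 and
below -0.2 (ordered-pair counts by default, i.e. each unordered pair twice;
an unordered option exists). The null re-scores 1,000 random same-size OTU
sets from the same table; "stronger" means larger positive mean/count, more
negative mean, larger below-count; p-values carry the add-one correction and
are never zero. Total branch length of a group is the sum of branch lengths
of the induced subtree rooted at the tips' most recent common ancestor (stem
excluded; a single tip has length zero).

## Putative identification and cross-region matching

Adduct rules are fixed: [M+H]+ (+1.007276, the proton, i.e. H minus the
electron mass — electron-mass handling is folded into this constant) and
[M+Na]+ (+22.989218) in ESI+; [M-H]- (-1.007276) and [M+Cl]- (+34.968853) in
ESI-. For each rule of the acquisition mode the implied neutral mass is
matched against the compound table within a relative window of 20 ppm
(inclusive), candidates sorted by |ppm error|; an origin-class post-filter
(mammalian/bacterial/plant) is available. The bundled
`data/compounds_demo.tsv` is a small demonstration table of gut-relevant
compounds with masses computed from their formulas and hand-assigned KEGG
pathway labels; it stands in for the large public compound databases and is
intended for examples, tests and pipeline runs on synthetic data, not for
annotating real experiments.

Cross-region matching requires |d m/z| <= 0.005 AND |d RT| <= 0.04 min
(both inclusive) within the same ionisation mode; qualifying candidate pairs
are resolved one-to-one greedily by ascending combined normalised distance
(ties by smaller mass difference), which makes the matched set symmetric in
the two tables.

## Pipeline

Stage order: preprocess -> modules -> network -> concordance -> clusters ->
function -> community -> identify. One master seed deterministically spawns
per-stage, per-region seeds, so reruns are hash-identical and single stages
can be recomputed without disturbing others. Every output is tab-delimited
with headers; `manifest.json` records SHA-256 hashes of all outputs. Stage
parameters default to the canonical values: depth 30,000, detection in >= 2
samples, prevalence 0.18, q < 0.2, minimum module size 10, 1,000 community
permutations, 999 ordination permutations, 20 ppm, match tolerances 0.005
m/z and 0.04 min, SparCC thresholds +/-0.2.

## Problem sizes used in the test suite

The recovery and calibration checks run at the emulated study scale — 46
subjects, 300 OTUs, 200 metabolites, 30 planted links at target Spearman
0.6, modules of 15/20/25 members at within-correlation 0.8, guilds of 10 at
basis correlation 0.7 — with Monte-Carlo sizes chosen for stable verdicts:
20 null replicates for the false-discovery check, a 500-replicate power
oracle for link sensitivity, 100 re-simulations (and a median over 5
observed replicates, which drops the intrinsic interval-miss rate of a
single draw from 5% to ~0.03%) for SparCC recovery, 200 random groups at 200
permutations for permutation-test calibration, and 200 null replicates at
199 permutations for ordination-test calibration. End-to-end determinism is
exercised on a 30-subject, 50-OTU toy dataset generated at test time.

## Known limitations

- The all-null false-discovery check inherits the ~alpha probability that a
  Benjamini-Hochberg-type procedure makes at least one call on a fully null
  table; averaged over 20 replicates its expected value sits near 0.2, so
  individual reruns fluctuate.
- SparCC on small homogeneous groups under-estimates shared correlation (see
  above); group-level conclusions are strongest for heterogeneous structure.
- The pooled permutation p-values treat all pairs as sharing one null
  |rho| distribution; this is exact in variance and very close in shape, but
  extremely heavy tie patterns (features present in only a few samples)
  are served slightly conservatively.
- Prediction strength assumes roughly balanced, compact clusters; for
  elongated correlation-profile geometries it under-picks k.
- The static 0.99 branch cut assumes modules are tight relative to the
  background; diffuse modules (within-correlation well below ~0.5) merge
  with the background and are returned unclustered rather than split.
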