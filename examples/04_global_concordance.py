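"""Test global microbiome-metabolome concordance.

Procrustes superimposes the two 2-D PCA configurations and reports the
residual m12^2 (0 = identical shapes); co-inertia reports the RV matrix
correlation in [0, 1]. Both p-values come from permuting sample rows.
The metabolome here is partially generated from microbial abundances, so
both tests should reject.
"""
import numpy as np

import syntropy as sy

cfg = sy.SynthConfig(seed=4, n_subjects=46, n_otus=100, n_metabolites=80,
                     n_modules=0, n_planted_links=40, link_effect=0.6,
                     n_guilds=0, guild_size=0, shared_metabolite_fraction=0.8)
bundle, _, _ = sy.generate_paired_dataset(cfg)

rel = bundle.otus.relative_abundance()
mets = np.log(bundle.metabolites.intensities + 1.0)

pro = sy.procrustes_test(sy.pca_euclidean(rel, 2), sy.pca_euclidean(mets, 2),
                         n_perm=999, seed=0)
print(f"Procrustes m12^2 = {pro.statistic:.3f}, P = {pro.p_value:.3f} "
      "(small m12^2 and small P mean the ordinations share shape)")

coi = sy.coinertia_rv(rel, mets, n_perm=999, seed=1)
print(f"co-inertia RV = {coi.statistic:.3f}, Monte Carlo P = {coi.p_value:.3f}")
w = coi.per_feature_weights
top = w[w["table"] == "x"].nlargest(3, "weight")
print("microbes with strongest inter-omic covariance:")
print(top.to_string(index=False))
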