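"""Build the OTU-metabolite Spearman network with q-value control.

Prints how many of the ~OTU x metabolite correlations survive the q < 0.2
threshold, how many planted links were recovered, and the genus-level
interaction counts (each metabolite counted once per genus).
"""
import numpy as np

import syntropy as sy

cfg = sy.SynthConfig(seed=2, n_subjects=46, n_otus=120, n_metabolites=100,
                     n_modules=0, n_planted_links=15, link_effect=0.7,
                     n_guilds=0, guild_size=0, shared_metabolite_fraction=0.8)
bundle, _, truth = sy.generate_paired_dataset(cfg)

otus = sy.filter_prevalence(sy.filter_min_samples(bundle.otus, 2), 0.18)
analytes = np.log(bundle.metabolites.intensities + 1.0)
net = sy.add_qvalues(sy.spearman_all_pairs(otus, analytes))
sig = sy.significant_edges(net, q_max=0.2)

planted = set(zip(truth.links_for_region("cecum")["otu_id"],
                  truth.links_for_region("cecum")["feature_id"]))
hits = sum((o, a) in planted for o, a in zip(sig.edges["otu_id"], sig.edges["analyte_id"]))
print(f"{net.rho_matrix.size} pairs tested, {len(sig)} edges at q<0.2")
print(f"planted links recovered: {hits}/{len(planted)}")

summary = sy.summarize_network(sig, otus.otu_ids, otus.taxonomy)
print(f"unique OTU nodes {summary.unique_otu_nodes}, "
      f"mean edges per metabolite {summary.mean_edges_per_analyte:.2f}")
genus = sy.bin_by_genus(sig, otus.taxonomy, otus.relative_abundance())
print("top genera by distinct correlated metabolites:")
print(genus.head(5).to_string())
# A genus correlating with one metabolite through several OTUs still counts
# as a single genus-level interaction.
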