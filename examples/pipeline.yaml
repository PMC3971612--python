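# Demo configuration: `syntropy simulate` writes the synthetic paired-region
# dataset described under `simulate:`; the remaining keys drive `syntropy
# run-all` (and the per-stage subcommands) on those files.

simulate:
  output_dir: demo_data
  seed: 11
  n_subjects: 40
  n_otus: 60
  n_metabolites: 70
  n_modules: 2
  module_sizes: [10, 12]
  n_planted_links: 12
  links_per_metabolite: 4
  link_otus_from_guilds: true
  link_effect: 0.8
  n_guilds: 2
  guild_size: 6
  guild_corr: 0.7
  read_depth_mean: 8000
  n_pathways: 12
  shared_metabolite_fraction: 0.8

inputs:
  cecum:
    otu_table: demo_data/cecum_otu_table.tsv
    metabolites: demo_data/cecum_metabolites.tsv
    pathways: demo_data/cecum_pathways.tsv
    tree: demo_data/cecum_tree.nwk
  sigmoid:
    otu_table: demo_data/sigmoid_otu_table.tsv
    metabolites: demo_data/sigmoid_metabolites.tsv
    pathways: demo_data/sigmoid_pathways.tsv
    tree: demo_data/sigmoid_tree.nwk

output_dir: demo_out
seed: 7

# stage parameters sized for the demo; analysis defaults are the canonical
# values (depth 30000, q<0.2, 18% prevalence, 1000 permutations, ...)
rarefaction_depth: 7200
soft_power: 6
n_clusters: 3
k_range: [2, 3, 4]
prediction_strength_splits: 10
n_permutations: 200
ordination_permutations: 199
community_max_groups: 3
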