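# Reference analysis defaults:
# rarefaction depth 500, 999 permutations, 90% bootstrap fraction with
# 999 replicates, |rho| threshold 0.5, rank sweep asv..order.
rarefy_depth = 500
n_perm = 999
n_boot = 999
bootstrap_frac = 0.9
rho_threshold = 0.5
rank_levels = asv,genus,family,order
pseudocount_rule = unit
min_prevalence = 0.2
min_samples = 5
permanova_terms = sample_type,tissue_storage,extraction_kit,host_class,host_order,host_species
seed = 1
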