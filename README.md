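# phylosym

Cross-kingdom phylosymbiosis analysis for paired fungal/bacterial
(ITS + 16S-style) count tables against a dated host phylogeny.

The package provides, as composable library modules and a CLI:

- **io_formats** — strict TSV/Newick readers and writers for feature tables,
  taxonomy, sample metadata, diet tables and host trees, with validation and
  cross-object alignment checks.
- **synthetic_data** — a ground-truth generator: Yule host trees, Brownian
  drift of latent compositions on the tree (`phylo_strength`), tunable
  cross-kingdom coupling (`coupling`, a shared-variance fraction),
  softmax-multinomial sequencing noise, random batch factors, and diet
  covariates.
- **compositional** — rarefaction (without replacement, sub-depth samples
  dropped with a report), CLR transform (unit or half-minimum-nonzero
  pseudocount), Aitchison distances, taxonomic agglomeration, species-level
  merging, alpha diversity (observed richness, Shannon, inverse Simpson)
  and paired-richness summaries with exact binomial CIs.
- **phylo** — patristic distances, grafting of sample tips onto species
  trees at negligible branch lengths, Abouheif's Cmean phylogenetic-signal
  permutation test, Benjamini–Hochberg correction.
- **multivariate** — PCA, sequential (Type-I) PERMANOVA with unrestricted
  label permutations, symmetric Procrustes correlation with PROTEST,
  90%-subsampling bootstrap sweeps across taxonomic ranks (cross-kingdom
  and microbiome-vs-host-phylogeny), Mantel tests, and diet analyses
  (diet PCA, diet–composition Mantel, diversity-on-diet-axis slopes).
- **networks** — Spearman co-occurrence matrices over paired samples,
  |rho|-thresholded signed networks with kingdom/phylum node attributes,
  structural traits (components, communities, modularity, edge-sign
  proportion, per-kingdom betweenness), and permutation nulls for fungal
  betweenness and phylum-pair co-occurrence frequency.
- **pipeline / cli** — a `run-all` orchestrator with a flat key=value
  config, per-stage sha256 manifest, deterministic re-runs, and a markdown
  report.

All permutation p-values use the `(b + 1) / (n_perm + 1)` convention and
every stochastic operation takes an explicit seed.

## CLI

```sh
# simulate a paired dataset with known ground truth
phylosym simulate --seed 1 --outdir data/

# full pipeline (simulates inputs when no paths are configured)
phylosym run-all --config src/phylosym/paper_defaults.cfg --outdir run/
phylosym report --outdir run/

# individual stages
phylosym permanova --table data/fungi_counts.tsv --metadata data/metadata.tsv \
    --terms sample_type,tissue_storage,extraction_kit,host_class,host_order,host_species \
    --out permanova.tsv
phylosym procrustes --fungi data/fungi_counts.tsv --bacteria data/bacteria_counts.tsv \
    --taxonomy-fungi data/fungi_taxonomy.tsv --taxonomy-bacteria data/bacteria_taxonomy.tsv \
    --out procrustes.tsv
phylosym phylosymbiosis --table data/fungi_counts.tsv --taxonomy data/fungi_taxonomy.tsv \
    --metadata data/metadata.tsv --tree data/host_tree.nwk --out phylosymbiosis.tsv
phylosym networks --fungi data/fungi_counts.tsv --bacteria data/bacteria_counts.tsv \
    --taxonomy-fungi data/fungi_taxonomy.tsv --taxonomy-bacteria data/bacteria_taxonomy.tsv \
    --metadata data/metadata.tsv --outdir nets/
```

`src/phylosym/paper_defaults.cfg` holds the reference parameter profile
(rarefaction depth 500, 999 permutations, 90% bootstrap fraction × 999
replicates, |rho| threshold 0.5, rank sweep asv→order).

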