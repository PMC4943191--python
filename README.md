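# islepair

Paired island–mainland molecular-evolution statistics: codon-aware
polymorphism and divergence estimators, relative-value paired inference, and
a founder-bottleneck coalescent generator for end-to-end testing with known
truth.

## What it does

For each island/mainland/outgroup comparison the pipeline computes:

- **Diversity** (`islepair.diversity`): within-species π, π_S, π_N and
  polymorphism counts from codon alignments, using Nei–Gojobori (1986)
  fractional site counting and equal-weight mutational-pathway averaging
  (stop-crossing pathways excluded).
- **Divergence** (`islepair.divergence`): lineage-specific d_N, d_S and ω for
  the island, mainland and outgroup branches, by parsimony assignment of
  codon changes against the outgroup, pathway classification, and
  Jukes–Cantor correction. This is a deliberate counting-based substitute
  for maximum-likelihood branch models and is tagged as such in all outputs.
- **Selection statistics** (`islepair.selection_stats`):
  π_N/(π_N+π_S), the direction-of-selection statistic
  DoS = d_N/(d_N+d_S) − π_N/(π_N+π_S), the N_e proxy π_S/d_S, and the
  gamma-DFE conversion ω₁/ω₂ = (N₁/N₂)^−β (inverted to get the implied N_e
  ratio).
- **Paired inference** (`islepair.paired_stats`): relative island values
  X′ = X(island)/(X(island)+X(mainland)), Wilcoxon signed-rank tests against
  symmetry about 0.5 (exact enumeration for ≤ 20 nonzero differences),
  percentile bootstrap CIs of the mean relative value (1,000 replicates by
  default), and Pearson/Spearman correlations.
- **Synthetic data** (`islepair.synthetic_data`): a haploid structured
  coalescent with a mainland→island split, optional founder bottleneck, and
  a deep outgroup; finite-sites codon mutation with purifying selection
  emulated by rejection of non-synonymous mutations. Known expectations
  (E[π_S] = θ under neutrality, branch lengths in the truth sidecar) make
  every stage testable.
- **Pipeline** (`islepair.pipeline`): per-comparison orchestration,
  longest-alignment genome selection, subgroup summary tables (combined /
  genome / taxon / colonization direction), the zero-diversity exclusion
  re-analysis, and scatter/histogram data for diversity-vs-divergence plots.

Undefined statistics (0/0 relative values, ω with d_S = 0, …) propagate as
explicit missing values with exclusion bookkeeping, never as zeros.

## CLI

```sh
# simulate a synthetic dataset (FASTA + manifest + truth sidecars)
islepair simulate --out data/ --n 20 --seed 1 --theta 0.02

# analyze a manifest (synthetic or your own alignments)
islepair analyze --manifest data/manifest.tsv --out analysis/ --seed 1

# one-shot: simulate then analyze
islepair run-all --out run1/ --n 20 --bottleneck-fraction 0.3 --seed 1

# single-alignment utilities
islepair diversity aln.fasta --code vertebrate-mitochondrial --genome mitochondrial
islepair divergence ortho.fasta --island sp1 --mainland sp2 --outgroup sp3
```

Input manifests are TSVs with columns `comparison_id`, `island_species`,
`mainland_species`, `outgroup_species`, `genome`, `taxon_group`, and optional
`direction`, `island_range_km2`, `mainland_range_km2`,
`polymorphism_files` (`species=path` pairs, comma-separated),
`divergence_file`, `genetic_code`. Alignments are plain FASTA, pre-aligned
and in frame (terminal stop codons are trimmed; codons containing a gap or N
in any sequence are masked for all sequences).

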