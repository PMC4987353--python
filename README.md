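# gutenv

Tools for asking a simple ecological question of 16S rRNA survey data: **how
does a host's gut bacteriome relate to the bacteriome of its surrounding
environment?** The motivating system is a small herbivorous mammal (the pika)
sampled together with the plants it eats and the soil it lives on, at several
sites — but the pipeline applies to any host/plant/soil (or host/environment)
compartment design.

The package implements, as a tested reusable library plus a thin CLI:

- **Rarefaction** of an OTU count table to an even depth (seeded multivariate
  hypergeometric subsampling without replacement) and relative-abundance
  transforms.
- **Alpha diversity** — observed OTUs and Faith's phylogenetic diversity
  (PD), the total branch length of the minimal rooted subtree spanning a
  sample's taxa.
- **Beta diversity** — unweighted UniFrac
  `d = Σ_b L_b·1[present in exactly one] / Σ_b L_b·1[present in either]`
  and weighted UniFrac `Σ_b L_b·|p₁ᵦ − p₂ᵦ|` (raw, and normalized by
  `Σ_b L_b·(p₁ᵦ + p₂ᵦ)`), PCoA ordination via Gower double-centering, and
  the rank-based ANOSIM permutation test
  `R = (r̄_between − r̄_within) / (M/2)`, `M = n(n−1)/2`.
- **Selection analysis** — per-site presence sets and three-compartment Venn
  partitions; unique/shared gut-OTU fractions; prevalence-thresholded core
  microbiomes per host species (`prevalence ≥ τ`, default τ = 0.8);
  most-abundant environmental OTU sets (mean relative abundance > 0.1%);
  core-vs-abundant overlaps; and the 2×2 cross-tabulation of shared-OTU
  abundance in gut vs. environment, whose headline number is the fraction of
  shared OTUs at ≤ 0.1% environmental abundance ("rare in the environment"),
  plus a Spearman ρ between gut and environmental abundance.
- **Taxonomy summaries** — rank-level aggregation with mass conservation,
  dominance lists, and the taxonomic breakdown of gut-environment shared
  OTUs.
- **A synthetic-data generator** with known ground truth: log-normal
  environmental pools, a host core microbiome, and gut colonizers drawn from
  the environment with weight `p^(1−γ)` — γ = 0 is neutral
  (abundance-proportional) colonization, γ > 1 selects for rare
  environmental taxa. This makes every pipeline stage verifiable without any
  sequencing data.

## Worked example

```python
from gutenv import (PipelineConfig, SyntheticConfig, simulate_dataset,
                    run_pipeline)

ds = simulate_dataset(SyntheticConfig(seed=1))     # 4 sites x (8 gut + 4 plant + 4 soil)
report = run_pipeline(ds.table, ds.tree, ds.taxonomy, ds.samples,
                      PipelineConfig(rng_seed=1), out_dir="out")

print(round(report["anosim"]["compartments"]["R"], 3),
      report["anosim"]["compartments"]["p"])
print(round(report["sites"]["site1"]["unique_fraction"], 3))
print(round(report["crosstab"]["pooled"]["rare_in_env"], 3))
```

prints

```
0.193 0.002
0.667
0.972
```

meaning: gut, plant and soil communities are significantly distinct by
ANOSIM on weighted UniFrac (R = 0.193, p = 0.002); two thirds of the gut
OTUs at site 1 were never detected in that site's plant or soil samples; and
97% of the OTUs shared between gut and environment sit at ≤ 0.1% mean
relative abundance in the environment — the signature of a host that selects
for rare environmental taxa (the generator's default selectivity is
γ = 2.5). `out/` additionally holds every distance matrix, PCoA table, Venn
partition, core-set and cross-tabulation TSV, and `report.json`.

The same analyses run from the shell:

```sh
gutenv simulate --seed 1 --out-dir data
gutenv report --table data/otu_table.tsv --tree data/tree.nwk \
    --taxonomy data/taxonomy.tsv --metadata data/metadata.tsv --out-dir out
gutenv core --table data/otu_table.tsv --tree data/tree.nwk \
    --metadata data/metadata.tsv --host-species species1 --prevalence 0.8
```

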