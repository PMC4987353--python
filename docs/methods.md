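# Methods

## The analysis model

The pipeline treats a 16S survey as four aligned objects: an OTU × sample
count table, a rooted phylogeny whose tips are the OTU ids, a taxonomy map
(kingdom…genus, with `unclassified` sentinels), and per-sample metadata
assigning each sample to a *compartment* (host gut `pika`, `plant`, `soil`),
a *site*, and — for gut samples — a *host species*. All statistics are
computed after rarefaction, so "present" always means "count > 0 at the
common depth".

**Rarefaction.** Each sample is subsampled without replacement to a fixed
depth *D* (default 4058 reads) by a seeded draw from the multivariate
hypergeometric distribution; samples below *D* are dropped and logged.
Without-replacement subsampling matches read-subsampling semantics; at equal
depth the draw is the identity, so rarefying an already-rarefied table
changes nothing.

**Relative abundance.** Per-sample proportions; group means are unweighted
arithmetic means of per-sample proportions (never pooled counts), so every
sample carries the same weight regardless of its pre-rarefaction depth, and
group means remain points on the simplex.

**Phylogenetic metrics.** All of Faith's PD and both UniFrac variants are
computed from a single edge index: the tree is sheared to the table's OTU
set (extra tips pruned, path lengths preserved), each non-root branch
becomes a row, and a postorder accumulation converts per-tip counts into
per-branch descendant counts. Faith's PD is the summed length of branches
with a present descendant, which automatically includes the root-ward path
(a deliberate convention, shared with the common QIIME-era pipelines).
Unweighted UniFrac divides branch length unique to one community by branch
length present in either; weighted UniFrac is `Σ L_b |p₁ᵦ − p₂ᵦ|` with
`p_b` the fraction of a community's reads below branch *b*, normalized by
`Σ L_b (p₁ᵦ + p₂ᵦ)` in the default variant so the value lies in [0, 1].
Both the raw and normalized weighted forms are exposed because published
pipelines differ in which they report.

**Ordination.** PCoA Gower-centers −½D∘D and eigendecomposes. Coordinates
are returned only for positive eigenvalues (scaled by √λ); negative
eigenvalues — a signal that D is not Euclidean-embeddable — are reported
unchanged rather than silently corrected (no Lingoes/Cailliez), trading a
tidy eigenvalue spectrum for transparency.

**ANOSIM.** Distances are ranked once (average ranks over ties, so a
constant matrix gives R = 0), and
`R = (r̄_between − r̄_within)/(M/2)`. The p-value permutes labels:
`p = (1 + #{R_perm ≥ R_obs}) / (1 + n_perm)`, never zero and never below
`1/(n_perm+1)`. For tiny designs `n_permutations="exact"` enumerates every
distinct labelling and reports the exact tail fraction (observed labelling
included).

**Selection statistics.** Detection is `count > 0` in at least one group
sample after rarefaction — no minimum-count filter, because singleton
removal is assumed upstream. Boundary conventions follow the verbal
definitions they encode: core membership is inclusive ("at least 80%" →
prevalence ≥ τ, pooled over all of a species' sites), the
abundant-environment set is strict (mean abundance > a*, default a\* =
0.001), and the rare-shared statistic is inclusive (env abundance ≤ a*).
The cross-tabulation splits gut-environment shared OTUs at a\* on both the
gut and the environment axis; its headline is the fraction at ≤ a\* in the
environment, with a tie-aware Spearman ρ quantifying the gut-vs-environment
rank relationship. Table-2-style summaries label each core OTU by its
deepest resolved rank (falling back to "Unclassified Bacteria"), report per
OTU plant prevalence (flagging OTUs below τ there as sporadic), and count
core OTUs never seen in any environmental sample.

## The synthetic generator

`simulate_dataset` emulates the features of the real design the analysis
relies on, with every ground-truth quantity recorded:

- **Design**: 4 sites by default, each with 8 gut, 4 plant and 4 soil
  samples; two host species, one per site, alternating (so both
  species-level and site-within-species contrasts are estimable).
- **Environmental pools**: plant and soil pools of S_env = 2000 taxa each,
  sharing a fraction ω = 0.3 of taxon identities; proportions are i.i.d.
  log-normal (sdlog = 1.5) renormalized to the simplex, redrawn per site
  with shared taxon identities. Plant/soil samples are multinomial draws at
  depth 5000. These sizes give realistic per-sample richness (~1000
  observed OTUs) and put the bulk of taxa below the 0.1% abundance
  threshold, as in diverse real environmental communities.
- **Host core**: S_core = 40 host-specific taxa per species, absent from
  the environmental pools. In each gut sample the core receives mass 1−m by
  a symmetric Dirichlet(1), with each core taxon independently zeroed with
  probability 1 − core_prevalence_sim (default 0.95) before
  renormalization.
- **Colonizers**: per gut sample, K = 100 environmental taxa drawn without
  replacement from the site's combined plant+soil distribution with weight
  `p^(1−γ)` (Gumbel-top-K, an exact weighted draw). γ = 0 is neutral
  colonization, γ = 1 abundance-blind, γ > 1 rare-biased; the default
  γ = 2.5 encodes strong host selection for rare taxa. Colonizers share
  gut mass m = 0.2 via an independent Dirichlet — deliberately decoupled
  from environmental abundance, which is the observed pattern in real
  host-environment comparisons; a coupled mode (gut mass ∝ environmental
  abundance) exists for null comparisons.
- **Phylogeny and taxonomy**: a random sequential-join (coalescent-style)
  bifurcating tree over all taxa with Exp(1) branch lengths; taxonomy is
  assigned by cutting the tree's tip ordering into contiguous phylum and
  genus blocks, so taxonomy and phylogeny are approximately consistent; 10%
  of taxa are left unclassified below kingdom.

What the generator does **not** emulate: overdispersed (Dirichlet-
multinomial) sequencing noise, PCR/chimera artifacts, cross-site
contamination, read-level data, or any quantitative model of real pika
biology — γ and m are simulation knobs, not estimates. Passing tests
therefore demonstrate that the pipeline's statistics recover the structure
they claim to measure when that structure is present, not that any
particular field system has it.

## Numerical and design choices

- All randomized operations take explicit seeds; there is no global RNG
  state, and a fixed seed reproduces every output byte-identically.
- Simplex tolerance is 1e-9 throughout; branch-length round-trip tolerance
  1e-12; PCoA treats eigenvalues below 1e-10 of the spectral radius as zero.
- Hard failure on metadata/table mismatches and on OTUs with reads missing
  from the tree; tree tips absent from the table are pruned (provably
  distance-preserving, and tested as such).
- Mean relative abundance in group summaries averages over *all* samples of
  the group, including those where the OTU is absent.
- The per-site overlap analyses use the globally rarefied table restricted
  to the site's samples, not a per-site re-rarefaction.
- Test problem sizes are scaled to desk scale (hundreds to a few thousand
  taxa, tens of samples); the acceptance checks that need replication use
  50–400 seeded replicates with thresholds stated in each test.

## Known limitations

- A prevalence-only core definition cannot distinguish true host-adapted
  taxa from environmental taxa that colonize persistently: under strongly
  rare-biased colonization a handful of environmental taxa reach ≥ 80%
  prevalence in the gut and are (correctly, by the definition) called core.
  Sensitivity to the true core is near 1 and the false-positive rate over
  non-core gut taxa is ~1%, but users should treat core sets as
  "consistently present", not "host-derived".
- Observed shared-OTU counts are sampling-effort dependent: deeper or more
  even environmental sampling detects more rare colonizers and shifts the
  unique/shared split. The same caveat applies to real surveys.
- ANOSIM R values depend on within-group heterogeneity; with two very
  distinct host species pooled into one "gut" compartment, the compartment
  R is much smaller than either species-level contrast even when separation
  is perfect.
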