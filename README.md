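# riverpop

Population-genetics toolkit for riverine fishes combining mitochondrial
sequence analyses with dominant-marker (polyploid band) microsatellite
analyses:

- **seqcore** — aligned FASTA I/O, marker concatenation, haplotype
  collapsing, per-site classification (variable / parsimony-informative /
  ts-tv / indel), pairwise difference counts with pairwise deletion.
- **diversity** — haplotype diversity (Hd), nucleotide diversity (π), mean
  pairwise differences (K), Kimura two-parameter distances, neighbor-joining
  trees with column-bootstrap support.
- **amova** — one- and two-level analysis of molecular variance from squared
  distance matrices (Excoffier-style variance components, Φ statistics,
  permutation tests with exact enumeration of tiny arrangement spaces),
  pairwise Φ_ST with Bonferroni flags.
- **demography** — mismatch distributions, Rogers–Harpending sudden-expansion
  model fitting (τ, θ0, θ1 by least squares), SSD and raggedness with
  parametric-bootstrap P-values, Fu's Fs via the Ewens sampling formula
  (log-space Stirling numbers) with simulated P-values, and expansion dating
  (u = 2μkT_gen, t = τ/2u, T = t·T_gen).
- **network** — minimum-spanning and median-joining haplotype networks with
  GraphML/GML/CSV export.
- **msat** — tetraploid band phenotypes → binary presence/absence, PPL /
  Nei's H / Shannon's I, Nei's unbiased distance, distance-based F_ST (via
  AMOVA), PCoA, Evanno ΔK post-processing of clustering likelihoods.
- **spatial** — isolation-by-distance Mantel tests of Φ_ST/(1−Φ_ST) against
  log10 river distance.
- **simulate** — self-contained coalescent simulator (piecewise-constant
  size, two-level structured scenarios with optional migration) and
  tetrasomic band-phenotype generator; seeded and byte-reproducible.
- **pipeline / cli** — YAML-config-driven orchestration of all stages with a
  JSON run log; `riverpop` console entry point.

## CLI

```bash
riverpop simulate expansion --n 30 -k 1000 --tau 6 --seed 1 --out-dir sim/
riverpop diversity sim/sequences.fasta sim/populations.tsv
riverpop mismatch sim/sequences.fasta -B 200 --seed 1
riverpop date-expansion --tau 12.345 --rate 1.69 --length 1855 --tgen 10
riverpop amova sim/sequences.fasta sim/populations.tsv --design two-level \
    --perms 10000 --seed 1
riverpop network sim/sequences.fasta sim/populations.tsv --epsilon 0
riverpop msat diversity bands.csv
riverpop ibd phist.csv geo_km.csv --perms 9999 --seed 1
riverpop pipeline config.yaml
```

A pipeline config names the inputs and all analysis parameters explicitly
(seeds included), e.g.:

```yaml
output_dir: out
seed: 7
n_permutations: 10000
gof_bootstrap: 200
fs_simulations: 1000
generation_time: 10
population_table: populations.tsv    # id, population, region
markers:
  - {name: cytb, fasta: cytb.fasta, rate_percent_per_myr: 1.0}
  - {name: cr,   fasta: cr.fasta,   rate_percent_per_myr: 3.6}
concatenated: {name: combined, rate_percent_per_myr: 1.69}
geo_distances: geo_km.csv            # optional, along-river km
bands: bands.csv                     # optional polyploid band phenotypes
structure_lnp: lnp.csv               # optional: K, lnP replicate table
```

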