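# phylogrid

Grid-based comparative phylogeography of organellar haplotypes.

`phylogrid` is for population geneticists comparing the spatial structure of
chloroplast (or mitochondrial) sequence variation across several co-occurring
species.  Starting from one aligned FASTA per species and a table of
georeferenced samples, it computes haplotypes, haplotype networks, per-grid-cell
diversity / endemism / distinctiveness statistics, differentiation with the
phylogeographic-signal test, and cross-species congruence tests — the toolkit
used to ask whether species share diversity hotspots, glacial refugia, or
secondary contact zones.

## What it computes

**Haplotypes.** Aligned sequences over `{A,C,G,T,-,N}` are coded with simple
indel coding (each maximal shared gap run is one binary character, so an indel
of any length counts as a single mutation) and collapsed into haplotypes.
Polymorphism is summarised by the SNP count (indels included) and nucleotide
diversity `π = n/(n−1) Σ p_h p_g d_hg / L` with its Nei-style standard
deviation.

**Networks.** Mutation-step distances (`π_kl` = substitution differences plus
one per differing indel character) feed an ε-relaxed minimum spanning network
and a median-joining network: connected triplets contribute per-character
majority consensus haplotypes (median vectors, `mv1`, `mv2`, …), and medians
that do not shorten the network are pruned.

**Grid statistics.** Samples are binned into degree grids (0.75°, 1.5°, 3° by
default; cells with fewer than three individuals are dropped).  Per cell:

- `NAe` — Nielsen's unbiased effective number of haplotypes
  `(n−1)² / [(Σp̂²)(n+1)(n−2) + 3 − n]`,
- `He` — gene diversity `n/(n−1)(1 − Σp̂²)`,
- `v` — ordered-allele diversity `n/(n−1) Σ p̂_h p̂_g π_hg` (mean mutation
  steps between two individuals),
- `End` — the proportion of individuals whose haplotype has a total
  geographic range (max great-circle distance among all its carriers,
  dataset-wide) of at most 200 km.

Global differentiation uses the Pons & Petit estimators: `GST = (hT−hS)/hT`
on frequencies alone and `NST = (vT−vS)/vT` weighting haplotype pairs by
mutation steps.  `NST > GST` — tested by permuting haplotype labels on the
distance matrix — means related haplotypes co-occur geographically
(phylogeographic signal).

**Distinctiveness.** For each cell pair, the mean between-cell distance
`v_ij = Σ p̂_ih p̂_jg π_hg` and the centroid distance `d_ij` are computed.
`S'_ij` are the residuals of `v_ij` on `ln(d_ij)` when a one-sided Mantel test
finds distance decay (else the centred `v_ij`), and `S'_i`, their mean over
pairs involving cell *i*, flags genetically isolated areas.

**Congruence.** Metrics are centred and reduced within species; congruence
across species is tested by pairwise Pearson correlation on shared cells, a
one-way ANOVA with grid cells as the factor, and Mantel tests between `S'_ij`
matrices; per-cell multi-species means summarise shared trends.

**Synthetic scenarios.** A generator simulates haplotypes on genealogies under
an infinite-sites model and places samples under four spatial scenarios —
`panmixia`, `refugia`, `expansion`, `contact` — with machine-checkable ground
truth, so the whole pipeline is testable without any sequence downloads.

## Worked example

Simulate a two-refuge scenario (120 samples, 12 haplotypes, ~800 bp) and
analyse it on a 0.75° grid:

```bash
phylogrid simulate --scenario refugia --seed 7 --out demo/
phylogrid analyze --fasta sp1=demo/sp1.fasta --samples demo/samples.tsv \
    --out demo_out/ --grid-sizes 0.75 --n-perm 999 --seed 1
```

prints

```
sp1: n=120 haplotypes=12 SNPs(incl. indels)=20 pi×10³=7.056±3.774
```

(120 individuals collapsed into 12 haplotypes over 20 polymorphic characters;
nucleotide diversity ×10³ with its standard deviation), and writes TSV tables.
`differentiation_0.75deg.tsv` shows the refugial signal:

```
species  grid     n_cells  GST       NST       p_NST_gt_GST
sp1      0.75deg  19       0.576001  0.783129  0.006
```

`NST` clearly exceeds `GST` (p = 0.006): related haplotypes cluster
geographically, as planted.  `cell_stats_0.75deg.tsv` holds the per-cell
`n/NAe/He/v/End` values and `distinctiveness_0.75deg.tsv` the `S'_i` scores
with the Mantel branch that produced them (here `residuals`, Mantel r = 0.63,
p = 0.001 — diversity decays with distance).  A median-joining network of the
same data:

```bash
phylogrid network --fasta demo/sp1.fasta --out demo_net
# 12 haplotypes, 0 median vectors, total length 20
```

The same operations are available as a library (`phylogrid.seqio`,
`.network`, `.gridstats`, `.distinctiveness`, `.congruence`, `.synthetic`,
`.pipeline`); `pipeline.analyze_comparative` runs the full multi-species
analysis in one call.

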