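# Methods

This note documents the statistical models and procedures implemented in
`phylogrid`, the defaults and the reasoning behind them, what the synthetic
scenarios do and do not emulate, and the package's numerical conventions.

## Haplotype definition and indel coding

Input alignments are organellar (effectively non-recombining) loci, so a
haplotype is simply a distinct coded sequence.  Two kinds of characters are
extracted:

* **Substitution characters** — every alignment column with at least two
  nucleotide states among the ungapped samples.  `N` and gaps are missing
  data at such a column.
* **Indel characters** — simple indel coding: every maximal gap run with
  identical start and end across the samples sharing it becomes one binary
  presence/absence character.  Overlapping but non-identical runs are
  separate characters, and a sample whose gap strictly subsumes a span is
  coded missing there (the state of the shorter event is unobservable).
  This makes an indel of any length one mutation step.

Samples missing data at any coded character cannot be assigned to a
haplotype unambiguously; they are dropped with a warning rather than
imputed.  Multi-locus haplotypes are concatenations of per-locus coded
vectors keyed by sample id.  A user-supplied list of alignment columns can
be masked before coding (`PipelineConfig.site_mask`), the mechanism intended
for loci with known problematic positions (e.g. sites suspected of recurrent
back-mutation); no automatic detection is attempted.

Nucleotide diversity is `π = n/(n−1) Σ_{h,g} p_h p_g d_hg / L`, the average
number of differences per site between two sequences, with `d_hg` counting
substitution differences plus one per differing indel character.  Its
standard deviation uses the Nei (1987)-style total variance

    V(π) = (n+1)/(3(n−1)L) π + 2(n²+n+3)/(9n(n−1)) π²,

the formula classical population-genetics packages report; it includes the
evolutionary (coalescent) variance, hence it is not a pure sampling error.

## Haplotype networks

Distances between haplotypes are Hamming distances over coded characters.
The **minimum spanning network** at relaxation `ε` contains edge `(u,v)` of
weight `w` iff `u` and `v` are disconnected using only edges of weight
`< w − ε`; at `ε = 0` this is exactly the union of all minimum spanning
trees (ties are never broken arbitrarily, they are kept).

The **median-joining** construction iterates: build the ε-MSN over the
current node set; for every triplet of nodes with at least two MSN links
among them, compute the per-character majority consensus on a binary
character expansion (characters with two states map to one 0/1 column;
rarer multi-state characters, which require homoplasy, are one-hot
expanded) and add it as a median vector if its sequence is new.  After
convergence, median vectors whose removal leaves a network no longer in
total length are pruned, so surviving medians always have degree ≥ 2.
`ε = 0` is the default; processing order is lexicographic in node ids,
which makes the result deterministic and input-order invariant.  Loop
resolution / torso reduction post-processing is out of scope.

## Grids and per-cell statistics

Cells are squares of 0.75°, 1.5° or 3° anchored at (0°E, 0°N), so the three
systems nest; intervals are half-open with the floor rule.  Indexing is on
raw latitude/longitude without projection and cell centroids are coordinate
means — adequate for the equatorial latitudes the defaults target, and
increasingly distorted toward the poles.  Cells with fewer than three
individuals are dropped (`min_cell_n = 3`): the diversity estimators below
need `n ≥ 3`.

With `p̂` the within-cell haplotype frequencies and `π` the mutation-step
matrix:

* `He = n/(n−1)(1 − Σ p̂²)` (unbiased gene diversity),
* `v = n/(n−1) Σ p̂_h p̂_g π_hg` (ordered alleles; equals the mean distance
  over ordered pairs of distinct individuals),
* `NAe = (n−1)² / [(Σ p̂²)(n+1)(n−2) + 3 − n]` (Nielsen et al. 2003
  unbiased effective number of haplotypes; 1 for monomorphic cells,
  `→ 1/Σp²` for large even samples),
* `End` = proportion of the cell's individuals carrying haplotypes whose
  total range — the maximum great-circle distance among **all** carriers,
  dataset-wide, haversine on a 6371 km sphere — is at most 200 km
  (configurable).  A haplotype spread over 300 km is not endemic anywhere,
  even in a cell containing all of its carriers; singletons are endemic by
  definition.

## Differentiation and the phylogeographic-signal test

Global `GST` and `NST` follow the Pons & Petit estimators with every
retained cell weighted equally (the estimator's population convention;
`weighting="size"` is also implemented for comparison with sample-weighted
runs).  Within components are means of per-cell unbiased diversities; total
components use mean frequencies with the published small-sample correction
`hT = 1 − Σ x̄² + hS/(n·ñ)` (`ñ` = harmonic mean cell size), and `vT`
analogously with `π`.  `GST = (hT−hS)/hT`, `NST = (vT−vS)/vT`; a
monomorphic dataset (hT = 0) raises an error rather than returning a
ratio of noise.

The test for phylogeographic signal permutes the haplotype labels on the
rows/columns of `π` while leaving all frequencies untouched, recomputes
`NST`, and reports `p = (1 + #{NST_perm ≥ NST_obs}) / (1 + n_perm)`
(add-one convention; 999 permutations by default, seed mandatory).  Under
this null the distance structure is exchangeable across haplotype labels —
which is also why the panmictic simulator assigns abundances to haplotypes
independently of their genealogical position (see below).

## Distinctiveness

`v_ij = Σ p̂_ih p̂_jg π_hg` deliberately has no self-pair correction (the
two draws come from different cells), and `d_ij` is the centroid distance;
co-located centroids of distinct cells are a degeneracy error.  Because
genetic distance typically grows with `ln` distance, `S'_ij` is defined as
the OLS residual of `v_ij` on `ln(d_ij)` (fitted over unique unordered
pairs) when the one-sided Mantel test of positive association is
significant at `α = 0.05`, else as the centred `v_ij`.  The branch and its
Mantel statistics are recorded in the result.  Either branch leaves the
off-diagonal mean at zero; `S'_i` is the mean over pairs involving cell
*i*.  One-sided testing is used here because only a *positive*
distance-decay justifies regression; the cross-species congruence Mantel
tests are two-sided since congruence could run either way.  The Mantel
permutation applies a simultaneous row/column permutation to one matrix,
statistics are Pearson correlations over upper-triangle entries, and at
least three cells are required (fewer make the decision meaningless).

## Cross-species congruence

Within species, metrics (`NAe`, `He`, `v`, `End`, `S'i`) are centred and
reduced with the sample (n−1) standard deviation; species with fewer than
two retained cells or zero variance are excluded from that metric with a
recorded reason.  Pairwise Pearson tests run on cells retained for both
species and need at least five shared cells (`min_shared_pearson`);
congruence Mantel tests on `S'_ij` need four (`min_shared_mantel`) — sparse
pairs are reported as untested with their shared-cell count rather than
silently dropped.  The multi-species ANOVA is a one-way fixed-effects
analysis with grid cells as the factor and species z-values as
observations; the design is unbalanced by nature (species is not a second
factor), cells with a single observation are excluded from the sums of
squares but reported, and the all-equal degenerate case returns F = 0
exactly.  Multi-species maps are per-cell means of the available z-values
with the contributing-species count.

## Synthetic scenarios

The generator exists so that every stage of the pipeline can be validated
against known truth.  Haplotypes evolve on explicit genealogies under an
infinite-sites model — every mutation hits a fresh alignment column — so
mutation-step distances equal genealogy path lengths exactly and the
network and estimator oracles are exact.  A configurable fraction of
mutations (default 0.1) are single-column indels (kept non-adjacent so the
indel characters stay unambiguous), and an optional homoplasy rate re-uses
columns to stress the network code.

Defaults describe one "study-scale" dataset: a 8–16°E × 6°S–8°N equatorial
box, 20 sites × 6 samples (120 individuals), ~800 bp, 12 simulated
haplotypes, 20 mutations — chosen so emitted haplotype counts (7–19) and
polymorphism match published plastid datasets of rainforest herbs, and so
the default grids yield realistic retained-cell counts (~16–20 at 0.75°).

* **panmixia** — haplotypes drawn i.i.d. from global frequencies
  (geometric profile, ratio 0.65) at every site.  Frequency ranks are
  shuffled over haplotypes so abundance carries no information about
  genealogical position; without this, the NST>GST permutation null is not
  exchangeable and the test is drastically conservative.
* **refugia** — `n_refugia` (2) haplogroup ancestors on a backbone chain at
  least `separation` (5) steps apart (the leftover mutation budget deepens
  the backbone), refuge-core sites carry locally endemic derived
  haplotypes (drawn 50:50 with the ancestor), and all sites mix haplogroups
  with distance-decaying weights (`exp(−d/150 km)`).
* **expansion** — a star genealogy; the ancestor is drawn at 90–95%
  everywhere except at three origin-core sites where derived haplotypes
  reach 60%.
* **contact** — two shallow haplogroups (star within groups, deep backbone)
  with flank-core endemics; band sites mix the two widespread ancestors in
  a deterministic 1:1 ratio, flanks are near-pure with 5% admixture.

Each dataset carries a `ScenarioTruth` (genealogy, haplogroup membership,
site roles, expectations) and `evaluate_expected_pattern` turns it into
machine checks: "top quartile" means at least the ⌈n/4⌉-th largest cell
value (ties included, plus strict positivity for `End`), the contact check
also requires `End` at or below the cell median, and the expansion check
asks the maximum `NAe` cell to be among the origin-core cells (the abstract
origin point may sit exactly on a grid-line corner, so the cell containing
it is not well defined).

What the generator does **not** emulate: coalescent genealogy shapes and
their variance, migration as a continuous process, recombination, sequencing
error, uneven and opportunistic sampling, and real range boundaries.
Passing the recovery tests therefore shows the *statistics* respond to the
planted spatial signals at realistic sample sizes — not that any particular
empirical dataset will carry such signals.

## Numerical conventions

* All permutation p-values use the add-one convention and a mandatory seed;
  comparisons use a `1e-12` slack so exact ties count as "as extreme".
* The pipeline derives every internal seed from the master seed through
  `numpy` seed sequences keyed by (purpose, species index, grid index), so
  reruns are byte-identical; output TSVs are written with `%.6g` floats and
  sorted keys.
* Tie-breaking in networks is lexicographic on node ids; equal-weight MST
  ties are kept (union of MSTs) rather than broken.
* Degenerate inputs raise typed errors (`MonomorphicError`,
  `InsufficientCellsError`, `DegenerateGeometryError`,
  `InsufficientDataError`) instead of returning NaN.

## Validation experiments

`phylogrid.experiments` (used by `tests/test_acceptance.py` and
`scripts/acceptance.py`) re-derives the package's guarantees at run time:
estimator agreement to 1e-12 with naive loop-based oracles on random
instances (≤ 12 individuals per cell, ≤ 5 cells); NST>GST type-I error
within [0.02, 0.09] over 200 panmictic replicates at 199 permutations;
refugial recovery (NST>GST significant and refuge cells in the top End
quartile) in ≥ 90% of 100 replicates; the contact diagnostic in ≥ 80%;
planted divergent-cell top-`S'i` rank in ≥ 90%; exact median-joining and
ANOVA worked examples; Pearson/Mantel null calibrations; and byte-identical
reruns of the eight-pseudo-species pipeline (~960 samples, three grids,
199 permutations — sizes chosen to keep a full validation run under a
minute on one CPU).

## Known limitations

* Degree-grid geometry is unprojected; at high latitudes cells shrink
  east–west and centroid means distort.
* The Pons & Petit total-diversity correction uses the published
  harmonic-mean form for equal weights; alternative software may weight
  populations by sample size (provided as an option, off by default).
* The median-joining implementation targets the small haplotype sets
  typical of organellar data (tens of nodes); it enumerates triplets and
  is not tuned for hundreds of haplotypes, and it does not resolve loops.
* `End` depends on sampling effort: under-sampled haplotypes look endemic
  (singletons trivially so).  The statistic is reported as defined; it is
  the user's job to interpret it in the light of sampling coverage.
* The Mantel branch decision uses a fixed `α = 0.05`; near-threshold
  datasets can switch branches under reseeding of the Mantel permutations,
  which changes `S'_ij` discontinuously.  The branch taken is always
  reported.
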