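# Methods

`ribotax` analyses clone libraries of a hypervariable rDNA fragment
amplified from individual specimens of a single morphospecies. Its goal is
to resolve cryptic diversity below the morphospecies level and to ask two
follow-up questions: does the clade's branching history depart from a
constant-rate (pure-birth) expectation, and does genetic distance between
sampling sites follow geographic distance?

## The molecular taxonomic system

Cloned rDNA sequences mix three sources of variation: divergence between
organism types, intragenomic variation among rDNA copies within one
organism, and PCR/sequencing noise. The hierarchy below handles each scale
explicitly.

**Basetypes.** Within each specimen, character-identical clones collapse to
one sequence pattern. A pattern is retained as a *basetype* only if it
occurs at least `min_occurrences` times (default 2) in the whole dataset —
recurrence is what separates real rDNA variants from one-off polymerase
errors. Counting is at the clone level by default ("occurs at least twice
in the dataset"); a stricter per-specimen recurrence mode
(`count_mode="specimens"`) is available. Discarded singletons are reported,
never silently dropped, and are re-assigned at the end (see below).

**Basegroups.** Basetypes that co-occur inside at least one specimen are
intragenomic variants of the same organism type. Basegroups are the
connected components of the graph joining basetypes that share a specimen.
This is the pivotal structure of the whole analysis: any candidate species
partition that cuts through a basegroup has necessarily split a single
organism's rDNA copies and is repaired by aggregation.

**Genotypes and lineages.** Two delimitation methods run on the basetype
alignment:

- *Barcode-gap partitioning* (`ribotax.abgd`). For each prior maximum
  intra-species divergence P (log-spaced ladder, default 10 steps in
  [0.001, 0.1]), the sorted pairwise distances are scanned for the first
  significant discontinuity above P: a first difference exceeding X
  (default 1.5) times the local slope, estimated as the mean of the
  previous w (default 10) differences (the mean of all differences when no
  trailing window exists yet). Units are the connected components of the
  graph linking pairs below the mid-gap threshold; a recursive pass
  re-applies the scan within each component until stable. The gap rule is
  a declared, deterministic re-statement of the barcode-gap idea; it does
  not claim byte-compatibility with any particular released program.
- *Poisson tree process* (`ribotax.ptp`). Branch lengths (expected
  substitutions) are modelled as two exponential classes: between-species
  edges (a connected set containing the root) and within-species edges
  (everything below the species stems). With the per-class rate MLE
  λ = n/S, the profile log-likelihood of a class is n(ln(n/S) − 1). The
  solver is exact: for a fixed number k of within-class edges the profile
  log-likelihood is convex in the within-class length sum, so the optimum
  sits at an extreme achievable sum, and a bottom-up tree knapsack
  (O(n²)) finds the global ML antichain of species roots. A greedy
  split/merge hill-climb with seeded random restarts runs alongside as a
  cross-check, and an explicit antichain-enumeration oracle
  (`ptp_exhaustive`) backs the tests. Zero-length branches are floored at
  1e-9.

All raw partitions (initial + recursive barcode-gap per prior; tree-process
fits on the rooted and the unrooted tree) are reconciled with the
basegroups: units spanning one basegroup are merged to a fixpoint.

**Level selection.** Lineages are the coarsest reconciled barcode-gap
initial partition that the reconciled rooted tree-process partition
refines; genotypes are the finest reconciled partition nested within the
lineages. Genotype units are then validated on patristic distances
(one-sided Kolmogorov–Smirnov and Mann–Whitney tests of inter- vs
intra-unit distances within the parent lineage, α = 0.05, plus the
median(inter) > median(intra) requirement); invalidated or sub-2-member
units are merged into the unit with the smallest median inter-unit
patristic distance and the result re-validated once. Labels follow the
size order: lineages I, II, …; genotypes a, b, c within lineage; basegroups
numbered within genotype (IIc6 = sixth basegroup of genotype IIc).

**Assignment of leftover clones.** Sequences whose pattern fell below the
recurrence cutoff are assigned the genotype of their highest-identity
basetype (ungapped identity over comparable columns) when identity ≥ 0.97
and the best hit is unique at the genotype level; ties are reported as
`ambiguous`, weak hits as `low_identity`. The 0.97 default is this
package's choice — at ~700 bp it tolerates ~20 substitutions, far beyond
clone noise, while rejecting cross-genotype placements.

## Trees

Tree building is distance-based: K80 distances and neighbor joining (with
optional nonparametric bootstrap over alignment columns; support =
percentage of replicates containing each original bipartition). A
full likelihood tree search is deliberately out of scope — the pipeline
accepts an externally computed newick tree wherever a tree is consumed.
Rooting uses a declared outgroup (root at the midpoint of the separating
edge; outgroup tips are pruned afterwards) or midpoint rooting when no
outgroup exists.

Ultrametricization uses mean path lengths: each node's age is the mean
distance to its descendant tips, child ages are clamped to their parent's
(clamps are logged), and ages are normalized to root = 1, tips = 0. Only
relative time matters downstream: the gamma statistic is invariant under
rescaling, which a property test asserts rather than assumes.

## Diversification

The lineages-through-time curve counts extant lineages at each node age
(simultaneous nodes merge into one step). The gamma statistic is computed
from internode intervals g_k (duration with k lineages extant): with
T_k = Σ_{j≤k} j·g_j and T = T_n,

    γ = [ (1/(n−2)) Σ_{i=2..n−1} T_i − T/2 ] / [ T √(1/(12(n−2))) ].

γ < 0 means internal nodes concentrate early, γ > 0 late; under a
pure-birth process γ is asymptotically standard normal. Null distributions
come from a Yule simulator conditioned on tip count (waiting time
Exponential(kλ) with k lineages, uniformly random lineage splits, a final
Exponential(nλ) interval to the present; λ = 1 since γ is scale-free).
Clades are compared by simulating per-clade Yule γ samples at the observed
tip counts and applying a two-sample Wilcoxon rank-sum test. "Same
properties" for null trees means same tip count — the speciation rate does
not enter γ.

## Geography

Site-pair distances use the haversine formula (R = 6371 km). Pairs whose
direct great circle is ecologically meaningless (e.g. polar routes between
ocean basins) can be re-routed through per-pair waypoint overrides; the
overridden distance is the sum of great-circle legs. For each unordered
site pair, patristic distances between the basetypes observed at the two
sites are summarized (mean/min/max); mean patristic distance is regressed
on geographic distance by OLS. The confidence band is half the mean
within-pair patristic range (the full range is available via
`band="full_range"`; the half-range reading is the default because the
band should reflect a ± deviation around the prediction). Pairs below
prediction − h are *underdispersed* (efficient mixing), above
prediction + h *overdispersed* (suppressed gene flow), otherwise
consistent with distance-driven divergence.

## Synthetic data

The generator (`ribotax.synthetic`) emulates the sampling design the
analysis assumes: 16 sites on a longitudinal gradient, 3–8 specimens per
site, 8–16 clones of a 700 bp fragment per specimen, six genotypes nested
in four lineages (1/3/1/1), each site occupied by exactly one genotype.
Divergence scales (expected substitutions/site): lineage depth 0.10 >
genotype depth 0.04 > within-genotype haplotype divergence 0.005 > clone
noise 0.001. Sequences evolve under K80 (κ = 2), i.i.d. sites, no indels
(data are born aligned; alignment itself is upstream of this package).

Two structural choices matter:

- **Shared haplotype pools.** Each genotype carries a pool of four rDNA
  haplotypes; each specimen samples 1–3 pool haplotypes and its clones
  scatter around them with Poisson clone noise. Recurrent haplotypes
  therefore co-occur within specimens across the genotype, so basegroups
  span specimens — the property that makes basegroup aggregation able to
  repair oversplit partitions. Without sharing, every specimen would be
  its own basegroup and the aggregation step would be vacuous.
- **Non-overlapping divergence bands.** Level trees are Yule, but their
  internal node ages are mapped into the older half of the level's depth
  band ([0.5, 1] × depth). A pure root-rescaled Yule tree can place a
  split arbitrarily close to the tips, making two lineages as similar as
  two genotypes; the generator's objective is separation of scales, not
  demographic realism, so the bands are kept disjoint by construction.

What the generator does *not* emulate: rate heterogeneity across sites
(Γ+I), indels and alignment error, chimeric clones, coalescent stochasticity
within genotypes, migration between sites, or unbalanced clone sampling.
Passing recovery tests therefore demonstrates that the inference chain is
correct and internally consistent under its own assumptions — not that it
is robust to the full noise spectrum of real clone libraries.

Ground truth (tree, per-sequence taxonomy, site→genotype map) accompanies
every dataset; recovery is scored by unit-count equality and the adjusted
Rand index of the genotype partition over all sequences (unassigned
sequences form one extra cluster).

## Numerical and procedural choices

- Distances: columns with gap/N in either sequence are excluded pairwise;
  saturated pairs under JC69/K80 raise rather than returning NaN.
- Neighbor joining: scikit-bio's implementation; negative branch-length
  estimates are clamped to zero.
- Deterministic tie-breaking throughout: units are labeled by size then
  lexicographically smallest member; greedy tree-process moves are
  evaluated in postorder index order; simultaneous node ages are processed
  as one event.
- Every stochastic stage (bootstrap, tree-process restarts, Yule nulls,
  Wilcoxon simulations, data generation) derives its stream from one
  configured seed; pipeline reruns are bitwise identical.
- Degenerate inputs fail loudly with the stage name: empty datasets,
  all-singleton partitions, zero-depth trees, zero geographic variance.

## Problem sizes

Default study-scale runs (16 sites, ~1000 clones, ~25 basetypes) complete
in ~1.5 s; the test suite's 20-seed recovery sweep and the acceptance
script each run in well under a minute on one CPU. Null-model sizes follow
the analysis design: 100 Yule trees per clade for LTT/γ envelopes, 1000
per clade for the Wilcoxon comparison, 1000 trees (n = 50) for the
standard-normal calibration check.

## Known limitations

- The barcode-gap scan is sensitive to dense low-level structure when the
  prior ladder reaches very small values; oversplit partitions are relied
  upon to be repaired by basegroup aggregation, which requires haplotype
  sharing across specimens (true for rDNA clone libraries, not for
  single-copy markers).
- Lineage/genotype level selection is a deterministic rule over candidate
  partitions; datasets whose divergence scales genuinely overlap have no
  well-defined "coarsest supported" level and the selected partition count
  will vary with the data.
- Mean-path-length ultrametricization is a rough clock; absolute node ages
  are not meaningful, only the relative ordering used by γ and the LTT.
- The speciation-by-distance regression treats site pairs as independent
  observations; no Mantel-style permutation correction is applied.
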