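# ribotax

Cryptic-diversity analysis of clone-level rDNA sequences: hierarchical
molecular taxonomy (basetype → basegroup → genotype → lineage), species
delimitation with barcode-gap and Poisson-tree-process methods,
diversification-rate analysis against pure-birth nulls, and
speciation-by-distance testing.

## The problem

Many widespread marine protists — the motivating case is a reef-dwelling
large benthic foraminifer sampled across its entire range — hide deep
genetic structure under one morphospecies. The raw data are PCR clone
libraries of a hypervariable ~700 bp 18S rDNA fragment: several clones per
specimen, several specimens per site, sites spanning ocean basins. Clones
mix true divergence with intragenomic rDNA variation and polymerase noise,
so species-level structure cannot be read off a tree of raw sequences.

`ribotax` implements the full inference chain for this kind of dataset:

1. **Taxonomy.** Collapse clones to recurrent *basetypes*; link basetypes
   that co-occur within specimens into *basegroups* (intragenomic variant
   sets of one organism type).
2. **Delimitation.** Partition basetypes with a barcode-gap scan over a
   ladder of divergence priors and with a two-rate Poisson model on the
   tree (between- vs within-species branches; the ML antichain of species
   roots is found exactly by dynamic programming). Partitions that split a
   basegroup are aggregated; units are validated by one-sided
   Kolmogorov–Smirnov and Mann–Whitney tests on patristic distances and
   invalidated units merged into their closest neighbor. The result is a
   nested nomenclature: lineages I, II, …, genotypes IIa, IIb, …,
   basegroups IIc6, ….
3. **Diversification.** Lineages-through-time curves and the Pybus–Harvey
   γ statistic per clade,

       γ = [ (1/(n−2)) Σ T_i − T/2 ] / [ T √(1/(12(n−2))) ],

   compared against simulated pure-birth (Yule) null distributions; clades
   are contrasted with a Wilcoxon rank-sum test of their null γ samples.
4. **Geography.** Haversine distances between sites (with waypoint
   overrides for ecologically impossible great circles), OLS regression of
   mean patristic on geographic distance, and classification of site pairs
   as genetically *underdispersed*, *consistent*, or *overdispersed*
   relative to a confidence band.

A synthetic-data generator with known truth (six genotypes in four
lineages, mutually exclusive site occupancy along a longitudinal gradient)
backs every test. See `docs/methods.md` for the models and the choices
behind them.

## Worked example

Generate a study-scale synthetic dataset and run the whole pipeline:

```bash
ribotax simulate --out data --seed 1
# wrote 1063 sequences, 16 sites (6 genotypes in 4 lineages) to data

ribotax run --fasta data/sequences.fasta --metadata data/metadata.tsv \
            --sites data/sites.tsv --out out --seed 1
# 1063 sequences -> 24 basetypes, 6 basegroups, 6 genotypes in 4 lineages;
# report in out/report.json
```

Reading the numbers: of 1063 clones, 544 belong to 24 recurrent sequence
patterns (basetypes); patterns seen once (519 clones) are set aside and
later re-assigned to genotypes by sequence identity. The 24 basetypes form
6 basegroups, and delimitation retains 6 genotypes nested in 4 lineages —
matching the generating truth exactly (genotype adjusted Rand index 1.0).
The same steps are available as library calls
(`ribotax.run_full_pipeline`) and as the narrative drivers
`analysis/01_simulate.py` … `analysis/04_geography.py`, which also print
the per-clade γ values, e.g.:

```
clade    I: n= 12 gamma=+1.661 (within the pure-birth 97.5% quantile +2.143)
clade  all: n= 24 gamma=+4.458 (EXCEEDS the pure-birth 97.5% quantile +2.574)
120 site pairs; patristic ~ geographic regression: slope 1.974e-05/km,
intercept 0.0629, R^2 = 0.339 (p = 3e-12)
```

The whole-clade γ far above the pure-birth envelope reflects the late
concentration of nodes that hierarchical divergence scales produce, and
the positive distance–distance regression with overdispersed outliers
reproduces the expected isolation signature of deeply divergent genotypes
at geographically close sites.

## Layout

```
src/ribotax/      library: records/io, seqdist, trees, taxonomy, abgd,
                  ptp, delimit, diversification, geography, synthetic,
                  pipeline, cli
analysis/         numbered narrative drivers writing results/
tests/            pytest suite (unit, property, acceptance)
scripts/          acceptance script
docs/methods.md   models, parameters, assumptions, limitations
```
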