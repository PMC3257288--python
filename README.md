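# equipop

Population-genetic analysis of SNP genotyping-array panels in
breed-structured species, built around the evaluation workflow of a
medium-density equine array: array quality statistics, cross-species
genotype filtering, breed structure, linkage-disequilibrium decay,
SNP-based parsimony phylogeny, and coat-color association mapping.  A
synthetic-data generator with embedded ground truth makes every stage
testable at desk scale without proprietary genotype data.

## Who it is for

Researchers evaluating a genotyping array or running first-pass
population analyses on multi-breed diploid panels: how many markers
convert and validate, how diverse and inbred each subpopulation is, how
far LD extends (and hence what marker density association mapping
needs), how breeds and related species group, and whether a Mendelian
trait can be mapped by case-control association.

## The statistics at its core

- **Conversion / validation rates** — converted = markers with any
  genotype call; validated = converted markers with ≥ 1 heterozygote;
  per-group MAF spectra and expected heterozygosity H_E = mean 2p(1−p).
- **IBS genetic distance** — D = 1 − (IBS2 + 0.5·IBS1)/N over
  jointly-called loci, embedded by classical (metric) MDS.
- **Inbreeding** — method-of-moments
  F = (O_hom − E_hom)/(L − E_hom) on an LD-pruned marker set
  (100-SNP windows, 25-SNP step, r² > 0.2), with the 2n/(2n−1)
  small-sample correction in E_hom.
- **LD decay** — haplotypic r² = D²_AB / (p_A p_a p_B p_b) with two-locus
  haplotype frequencies from an EM over double-heterozygote phase
  ambiguity; binned in 50 kb intervals to 4 Mb; extent of LD = distance
  at which the profile falls (and stays) below twice the 2–4 Mb
  background.
- **Parsimony phylogeny** — genotypes coded AA=0 / AB=1 / BB=2 as
  unordered characters, Fitch two-pass scoring, multi-start SPR/TBR
  hill-climbing, character-resampling bootstrap.
- **Association** — 1-df allelic chi-square and the stratified
  Cochran–Mantel–Haenszel test over concordance-constrained clusters;
  family-wise correction by label-swapping max-T permutations
  (p = (1+k)/(B+1)); genomic inflation λ = median χ²/0.4549;
  coat-color phenotypes inferred from nine epistatically interacting
  loci (gray dominant over all, chestnut epistatic over agouti, cream /
  champagne / silver dilutions, white patterning).
- **Conserved haplotypes** — maximal interval around a causal locus in
  which all mutant homozygotes share one homozygous genotype;
  across-breed block = intersection of per-breed blocks.

## Worked example

```python
from equipop.simulate import SimulationConfig, simulate_panel
from equipop.qc import summarize_assay
from equipop.structure import ibs_distance_matrix, classical_mds, ld_prune, inbreeding_coefficients

cfg = SimulationConfig(n_breeds=3, samples_per_breed=20, n_loci=400,
                       chromosome_lengths=(20_000_000,), seed=1)
panel, truth = simulate_panel(cfg)
s = summarize_assay(panel)
print(f"converted {s.n_converted}/{s.n_assayed} ({s.conversion_rate:.3f}); "
      f"validated {s.n_validated} ({s.validation_rate:.3f})")
```

prints

```
converted 400/400 (1.000); validated 382 (0.955)
```

meaning every simulated marker produced at least one call, and 95.5% of
converted markers showed a heterozygote somewhere in the 60 samples —
the rest drifted to fixation or were too rare to be sampled.  The same
panel through the CLI:

```
$ equipop qc demo.ped demo.map
group   n_samples  n_polymorphic  n_informative  mean_maf  median_maf  expected_heterozygosity
breed1  20         294            288            0.204     0.211       0.286
breed2  20         306            298            0.212     0.200       0.294
breed3  20         306            303            0.216     0.225       0.297
```

Per breed: the number of polymorphic (MAF ≥ 0.01) and informative
(MAF > 0.05) markers, the MAF spectrum location, and expected
heterozygosity — the quantities used to compare genetic diversity
between breeds.  `equipop distance --mds`, `equipop inbreeding` and
`equipop ld-decay` emit the distance/MDS tables, per-individual F, and
the binned r² decay profile with its extent-of-LD estimate.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole pipeline from scratch on a freshly simulated
14-breed panel (with trios, a degraded cross-species panel, and an
embedded recessive coat-color locus riding a 1 Mb founder haplotype):
assay QC, Mendelian agreement, the intensity/individual/marker filter
cascade, IBS distances and MDS, LD pruning and per-breed inbreeding, LD
decay and extent, a parsimony tree over breed representatives, clustered
CMH association with max-T correction, and the per-breed and
across-breed conserved haplotype around the causal locus, printing a
stage-by-stage summary and writing the results JSON to `--out`.
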