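# Methods

This note records the models, estimators, numerical choices and known
limitations of the package, in the order the pipeline runs.

## Synthetic panels (`equipop.simulate`)

The generator produces the statistical features the analyses assume,
with ground truth recorded for parameter-recovery testing. It is a
phenomenological model, not a coalescent simulator.

**Genome and markers.** Loci are scattered uniformly over a configurable
set of chromosomes (default four 50 Mb autosomes, 5,000 loci — about a
40 kb mean spacing, the density class of a medium-density mammalian
array). Positions are 1-based; allele A/B orientation is fixed at
generation.

**Breed differentiation.** Per-locus ancestral frequencies (default
uniform on [0.05, 0.95]) are perturbed per breed by a truncated-normal
update with variance `drift · p(1−p)` — the one-generation
Wright–Fisher drift variance scaled by an intensity in [0, 1]. Default
drift 0.1 gives clearly separable breed clusters in MDS at 20
samples/breed. The default of 14 breeds × 25 samples mirrors a
multi-breed array-evaluation cohort of ~350 animals.

**LD.** Each haplotype is a mosaic copied from a per-breed pool of K
founder haplotypes (default 8), with copying-segment lengths
exponential with mean `ld_copy_length_mean` (default 200 kb, which puts
the within-breed r² = 0.2 crossing at roughly 100–150 kb, the range
reported for most horse breeds). Finite K creates background LD; the
segment length sets how far it extends, so one parameter maps directly
onto the decay scale. Short-range r² is bounded near 1/K: tests that
need the profile to cross r² = 0.2 use K = 4, tests that need
near-independent loci use K in the hundreds. This is the main
deliberate departure from realism — real LD decays from pedigree and
recombination-map structure the model does not contain, so a green LD
test establishes correct *measurement* of LD, not a realistic genome.

**Inbreeding.** Each copying segment of the second haplotype duplicates
the first with probability F (runs-of-homozygosity style). The realized
autozygous fraction per individual is stored as truth; it concentrates
tightly around the target (SD < 0.01 at default segment counts), which
is what makes a ±0.03 recovery tolerance meaningful at 50 samples. An
all-or-nothing per-individual mechanism was rejected because its
realized mean F at n = 50 has SD ≈ 0.05.

**Admixture, ascertainment, missingness.** Admixed breeds draw each
haplotype from a donor pool with the stated proportion (enough to
reproduce the spread-out MDS clusters of admixed breeds). Ascertainment
drops loci rare (MAF < threshold) in *all* designated discovery breeds,
mimicking SNP discovery restricted to a few breeds; it measurably
shifts the discovery-breed MAF spectrum upward. Calls are masked
uniformly at `missing_rate` (default 0.004, i.e. a 0.996 individual
call rate).

**Trios and duplicates.** Offspring transmit one parental allele per
locus; parent pairs are taken round-robin across breeds. Injected
Mendelian errors are planted as parent-*incompatible* genotypes where
one exists; het × het matings admit every genotype, so the expected
agreement is 1 − rate × (plantable fraction), and the tests derive that
expectation from the parents rather than assuming it is 1 − rate.

**Cross-species degradation.** Per taxon: a fraction of loci fail
outright, a fraction are fixed, and a fraction of the remaining calls
draw their fluorescence from a low-mean component (N(500, 200) vs
N(3000, 500), arbitrary units). The two components barely overlap at
the 1000-unit threshold, so the intensity filter removes approximately
the unreliable fraction — by construction, which is what makes the
filter's accounting testable.

**Color spiking.** The mutant allele of a designated color locus rides
a single founder haplotype: carrier haplotypes have their array SNPs
inside a window of configurable length overwritten with one fixed
pattern. A conserved homozygous block therefore exists by construction
and the causal allele is in complete LD with the region. The other
eight loci are drawn independently under Hardy–Weinberg.

## QC statistics (`equipop.qc`)

Converted = locus with ≥ 1 call; validated = converted with ≥ 1
heterozygote; polymorphic per group = MAF ≥ 0.01; informative =
MAF > 0.05. H_E is the unweighted mean of 2p(1−p) over panel-wide
validated loci, computed with group-specific frequencies and no
small-sample correction (the convention is stated rather than inferable
from the source material; the choice is documented and symmetric across
groups, so between-group comparisons are unaffected). Mean and median
MAF are over converted loci including MAF 0. Mendelian agreement
excludes loci missing in any trio member from the denominator — "loci
genotyped" is read as genotyped in all three members.

## Cross-species filter (`equipop.species_filter`)

Fixed cascade: (1) calls with summed raw intensity strictly below 1000
become missing (ties kept); (2) within each suborder-level group,
individuals more than 2 SD below the group-mean call rate are removed
in a single pass (the rule is not iterated — re-running can remove
more, which is documented single-pass semantics); (3) markers called in
strictly more than 90% of remaining individuals are retained (a marker
at exactly 90% is removed). The marker rule applies to whatever panel
is passed; per-species marker counts come from running the cascade on
per-taxon subpanels.

## Structure (`equipop.structure`)

**Distance.** D = 1 − (IBS2 + 0.5·IBS1)/N reduces to mean |g_i − g_j|/2
in dosage coding; pairs below a joint-call minimum are NaN and refuse
MDS. **MDS** is classical Torgerson scaling: double-center −½D∘D,
eigendecompose, keep top-k positive-eigenvalue axes scaled by root
eigenvalue; axis signs fixed by making the first nonzero loading
positive. **Pruning** uses squared Pearson correlation of dosage
vectors over pairwise-complete samples (genotypic r², deliberately
distinct from the EM haplotypic r² used for decay), greedy within
100-SNP windows sliding by 25: of an offending pair the lower-MAF
member is removed, ties to the later map position. **Inbreeding** is
(O_hom − E_hom)/(L − E_hom) over pruned autosomal loci, E_hom from
reference frequencies with the 2n/(2n−1) allele-count correction
(without it F is biased about −0.014 at n = 50). Reference frequencies
are panel-wide by default and switchable to within-group: panel-wide
frequencies under strong structure absorb the Wahlund effect into F, so
per-breed reporting should use the group mode.

## LD decay (`equipop.ld`)

Haplotypic r² via EM over the double-heterozygote ambiguity:
initialization at linkage-equilibrium products, at most 50 iterations,
stop when the largest frequency change is below 1e-8. With no double
heterozygote the haplotype counts are determined and EM equals direct
counting (tested exhaustively). Pairs need ≥ 10 jointly-called samples
and two polymorphic loci, else NaN. Profiles: intra-chromosomal pairs
under 4 Mb, half-open 50 kb bins `[start, end)`, X excluded by default.
Extent of LD: background = mean of populated 2–4 Mb bin means; extent =
left edge of the first bin below 2× background *that no later
foreground bin re-exceeds* (the persistence clause handles noisy dips);
a profile below threshold from the start yields 0, one that never
falls below yields the window start, both with warnings.

## Phylogeny (`equipop.phylogeny`)

Characters are dosage states {0,1,2} treated as unordered (Fitch);
missing is full ambiguity and never costs. An ordered (Wagner, |i−j|
steps) option uses Sankoff dynamic programming. Search is random-
addition starting trees improved by first-improvement SPR passes, then
TBR passes (TBR = SPR plus rerooting of the pruned subtree), repeated
until no rearrangement improves; multi-start, all co-optimal topologies
kept, strict consensus available. Dedicated parsimony programs'
"new technology" heuristics are intentionally not reproduced: at the
package's scale the hill-climber is validated against exhaustive
enumeration (all 105 six-taxon topologies), which is the meaningful
correctness claim. Local optima exist — the six-taxon oracle needs ~5
random starts for 20/20 agreement, and larger problems should use more.
Bootstrap resamples characters with replacement, runs a reduced search
per replicate, and reports the percentage of replicate best trees
containing each reference bipartition.

## Coat color and association (`equipop.colors`)

**Phenotype rules**, applied in order: MC1R M/M ⇒ chestnut base, else
ASIP del/del ⇒ black, else bay; named single-modifier phenotypes
(palomino, buckskin, cremello, smoky black, white patterning); any
other modifier combination ⇒ "modified" (only conventionally named
combinations are guaranteed); STX17 duplication ⇒ gray, epistatically
dominant over everything; breed-level dun override for populations
fixed for dun, below gray. In multilocus mode gray horses are
uninformative (status None) for base-color targets; chestnuts are
uninformative for ASIP. Single-locus mode reads only the target
genotype (chestnut, black recessive; gray and the dilution/patterning
alleles dominant).

**QC.** Sequential: sample call rate ≥ 0.9, locus call rate ≥ 0.9,
MAF ≥ 0.01, exact Hardy–Weinberg p ≥ 0.001 (controls only by default,
standard case-control practice; switchable to all samples),
case/control differential-missingness chi-square p ≥ 0.01. The HWE test
enumerates all heterozygote counts conditional on allele counts, no
mid-p.

**Tests.** Allelic: 1-df Pearson chi-square on the 2×2 allele × status
table, no continuity correction. CMH: 2×2×K allele-count form
(Σ(a−E))²/ΣVar, 1 df, no continuity correction; degenerate strata
contribute zero; at K=1 it equals the (n−1)/n-scaled allelic statistic
(and matches statsmodels' implementation, used as a test oracle only).
Max-T: case/control labels permuted (within strata for CMH), corrected
p = (1 + #{permutation max ≥ observed})/(B + 1) — never zero, and
slightly conservative (measured family-wise error 0.03 at nominal 0.05
over 200 null datasets). λ = median observed χ² / χ²₁ median.

**Clustering.** Complete-linkage agglomeration on IBS distance with a
permutation homogeneity test (mean between- minus mean within-cluster
distance) gating each merge at `merge_p`. Two design points matter.
First, the candidate clusters are selected on a distance matrix from
the even-indexed loci while the merge test evaluates distances from the
odd-indexed loci: without this split the clusters always look
significant on the data that produced them, and a homogeneous panel
shatters. Second, `merge_p ≥ 1` disables the test entirely (the
permutation p can never reach 1.0 exactly, so a literal threshold of 1
would forbid every merge instead of allowing all, contradicting the
intended limit). The gate is a deliberate simplification of
pairwise-concordance clustering, not a reimplementation of any
particular tool's internals.

**Conserved haplotypes.** From the array SNP nearest the causal
position, extend in both directions while every called carrier is
homozygous and all called carriers agree; missing calls are tolerated
(they neither support nor break a block — at high missingness blocks
can overextend). Across-breed block = coordinate intersection of
per-breed blocks. For carrier groups with no homozygotes a
shared-allele mode extends while some allele is present in every
carrier — a deterministic, phasing-free stand-in for haplotype
reconstruction; full statistical phasing is out of scope.

## Degenerate inputs and tie-breaks (summary)

Monomorphic loci: r² undefined (NaN), MAF 0, excluded from F via the
p∈(0,1) guard. Zero-margin association tables: NaN, flagged. Distance
pairs without joint calls: NaN, refuse MDS. Pruning ties: lower MAF
out, then later position. MDS sign: first nonzero loading positive.
Half-missing PED calls: fully missing. Exactly-at-threshold: intensity
1000 kept, marker rate 0.9 removed, MAF 0.05 kept at the ≥ 0.05 coding
filter.

## Known limitations

- The simulator's LD has a single scale per panel; no recombination
  hotspots, no map heterogeneity, no mutation model.
- Within-breed founder pools create family-like substructure at small
  K; analyses that assume unrelated individuals (clustering nulls,
  radiation phylogenies) are tested with large K.
- Parsimony search is heuristic above the exhaustively-verified scale.
- The coat-color engine guarantees only conventionally named modifier
  combinations; everything else is "modified".
- Sex chromosomes are carried but not modelled (no male hemizygosity);
  X is simply excluded where the analyses call for autosomes.
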