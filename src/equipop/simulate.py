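"""Synthetic breed-structured SNP-array panels with known ground truth.

The generator emulates the statistical structure of a multi-breed
genotyping-array study so that every downstream analysis (QC, distance /
MDS, LD decay, inbreeding, phylogeny, association) can be exercised and
verified at desk scale:

* **Breed differentiation** — per-locus ancestral allele frequencies are
  perturbed per breed by a truncated-normal update with variance
  ``drift * p * (1 - p)``, the classical one-generation drift variance
  scaled by a divergence intensity in [0, 1].
* **Linkage disequilibrium** — each individual haplotype is a mosaic
  copied from a small per-breed founder-haplotype pool, with segment
  lengths exponentially distributed (mean ``ld_copy_length_mean`` bp).
  A small pool creates background LD; longer segments propagate it
  further, so one parameter maps directly onto the decay scale.
* **Inbreeding** — each copying segment of an individual's second
  haplotype is an identical copy of the first haplotype with probability
  ``inbreeding_per_breed``, mimicking runs of homozygosity; the expected
  autozygous genome fraction (and hence the excess homozygosity F)
  equals the target, with little individual-level noise.
* **Admixture** — haplotypes of an admixed breed are drawn from a second
  breed's pool with a stated proportion.
* **Ascertainment** — loci that are rare (MAF below a threshold) in all
  designated discovery breeds are dropped after simulation, mirroring
  SNP discovery restricted to a few breeds.

All randomness flows from ``config.seed`` / explicit ``seed`` arguments
through :func:`numpy.random.default_rng`; identical inputs give
bit-identical panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .panel import HET, HOM_A, HOM_B, MISSING, GenotypePanel, IntensityTable, Locus, Sample

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "TaxonDivergence",
    "IntensitySpec",
    "simulate_panel",
    "simulate_trios",
    "simulate_species_panel",
    "spike_color_loci",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model.

    Defaults emulate a 14-breed domestic-horse array study at desk scale:
    ~25 individuals per breed, ~40 kb mean inter-SNP spacing, individual
    call rate ~0.996, and within-breed LD decaying over 100-200 kb.
    """

    n_breeds: int = 14
    samples_per_breed: int = 25
    n_loci: int = 5000
    chromosome_lengths: tuple[int, ...] = (50_000_000, 50_000_000, 50_000_000, 50_000_000)
    ancestral_maf_distribution: tuple = ("uniform", 0.05, 0.95)
    drift_per_breed: tuple[float, ...] | float = 0.1
    inbreeding_per_breed: tuple[float, ...] | float = 0.0
    admixture_spec: tuple[tuple[str, str, float], ...] = ()
    ld_copy_length_mean: float = 200_000.0
    n_founder_haplotypes: int = 8
    ascertainment_breeds: tuple[str, ...] = ()
    ascertainment_min_maf: float = 0.05
    missing_rate: float = 0.004
    seed: int = 0

    def breed_names(self) -> list[str]:
        return [f"breed{i + 1}" for i in range(self.n_breeds)]

    def _per_breed(self, value) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(value, dtype=float), (self.n_breeds,)).copy()
        return arr

    def validate(self) -> None:
        if self.n_breeds < 1 or self.samples_per_breed < 1 or self.n_loci < 1:
            raise ValueError("n_breeds, samples_per_breed and n_loci must be positive")
        if any(l <= 0 for l in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be positive")
        for name, val in (
            ("drift_per_breed", self._per_breed(self.drift_per_breed)),
            ("inbreeding_per_breed", self._per_breed(self.inbreeding_per_breed)),
        ):
            if ((val < 0) | (val > 1)).any():
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.n_founder_haplotypes < 2:
            raise ValueError("need at least 2 founder haplotypes")
        names = set(self.breed_names())
        for a, b, prop in self.admixture_spec:
            if a not in names or b not in names:
                raise ValueError(f"admixture_spec references unknown breed: {(a, b)}")
            if not 0 <= prop <= 1:
                raise ValueError("admixture proportion must lie in [0, 1]")
        unknown = set(self.ascertainment_breeds) - names
        if unknown:
            raise ValueError(f"ascertainment_breeds not in panel: {sorted(unknown)}")


@dataclass
class TruthRecord:
    """Ground truth paired with a simulated panel, for parameter recovery."""

    breed_names: list[str]
    breed_freqs: np.ndarray  # (n_breeds, n_loci) allele-B frequency after drift
    true_f: np.ndarray  # per-sample target inbreeding coefficient
    admixture: dict[str, tuple[str, float]]
    haplotypes: np.ndarray  # (n_samples, 2, n_loci) int8 allele-B indicators
    causal_locus: str | None = None
    causal_region: tuple[str, int, int] | None = None
    carrier_haplotypes: np.ndarray | None = None  # (n_samples, 2) bool

    def subset_loci(self, keep: np.ndarray) -> "TruthRecord":
        return TruthRecord(
            breed_names=self.breed_names,
            breed_freqs=self.breed_freqs[:, keep],
            true_f=self.true_f,
            admixture=self.admixture,
            haplotypes=self.haplotypes[:, :, keep],
            causal_locus=self.causal_locus,
            causal_region=self.causal_region,
            carrier_haplotypes=self.carrier_haplotypes,
        )


def _draw_positions(config: SimulationConfig, rng: np.random.Generator) -> list[Locus]:
    """Scatter loci over chromosomes proportionally to length, sorted."""
    lengths = np.asarray(config.chromosome_lengths, dtype=np.int64)
    weights = lengths / lengths.sum()
    counts = np.floor(weights * config.n_loci).astype(int)
    while counts.sum() < config.n_loci:  # distribute the remainder
        counts[int(np.argmax(weights * config.n_loci - counts))] += 1
    loci: list[Locus] = []
    for c, (length, k) in enumerate(zip(lengths, counts), start=1):
        if k == 0:
            continue
        pos = np.sort(rng.choice(np.int64(length), size=k, replace=False) + 1)
        for p in pos:
            loci.append(
                Locus(
                    id=f"snp_{c}_{int(p)}",
                    chromosome=str(c),
                    position=int(p),
                    allele_a="A",
                    allele_b="B",
                )
            )
    return loci


def _ancestral_freqs(config: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    kind, *params = config.ancestral_maf_distribution
    if kind == "uniform":
        lo, hi = params
        return rng.uniform(lo, hi, size=n)
    if kind == "beta":
        a, b = params
        return np.clip(rng.beta(a, b, size=n), 1e-4, 1 - 1e-4)
    raise ValueError(f"unknown ancestral frequency distribution {kind!r}")


def _mosaic_haplotypes(
    pool: np.ndarray,
    n_hap: int,
    switch_prob: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Copy ``n_hap`` mosaic haplotypes from a founder pool.

    ``switch_prob[j]`` is the probability of starting a new copying
    segment at locus ``j`` (1.0 at each chromosome start).
    """
    k, n_loci = pool.shape
    switches = rng.random((n_hap, n_loci)) < switch_prob[None, :]
    switches[:, 0] = True
    seg_id = np.cumsum(switches, axis=1) - 1
    founders = rng.integers(0, k, size=(n_hap, n_loci))  # one draw per potential segment
    founder_at = np.take_along_axis(founders, seg_id, axis=1)
    return pool[founder_at, np.arange(n_loci)[None, :]]


def simulate_panel(config: SimulationConfig) -> tuple[GenotypePanel, TruthRecord]:
    """Simulate a breed-structured genotype panel with known truth.

    Returns the panel (after ascertainment filtering and missingness
    masking) and the aligned :class:`TruthRecord`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    loci = _draw_positions(config, rng)
    n_loci = len(loci)
    positions = np.array([l.position for l in loci], dtype=np.int64)
    chroms = np.array([l.chromosome for l in loci], dtype=object)

    # per-locus segment-switch probabilities from inter-locus gaps
    switch_prob = np.ones(n_loci)
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        gaps = np.diff(positions[idx]).astype(float)
        switch_prob[idx[1:]] = 1.0 - np.exp(-gaps / config.ld_copy_length_mean)

    breed_names = config.breed_names()
    drift = config._per_breed(config.drift_per_breed)
    inbreeding = config._per_breed(config.inbreeding_per_breed)
    admix = {a: (b, prop) for a, b, prop in config.admixture_spec}

    p_anc = _ancestral_freqs(config, n_loci, rng)
    sd = np.sqrt(drift[:, None] * p_anc[None, :] * (1 - p_anc[None, :]))
    breed_freqs = np.clip(p_anc[None, :] + rng.normal(0.0, 1.0, (config.n_breeds, n_loci)) * sd, 0.0, 1.0)

    pools = [
        (rng.random((config.n_founder_haplotypes, n_loci)) < breed_freqs[b]).astype(np.int8)
        for b in range(config.n_breeds)
    ]

    n_per = config.samples_per_breed
    n_samples = config.n_breeds * n_per
    haplotypes = np.empty((n_samples, 2, n_loci), dtype=np.int8)
    samples: list[Sample] = []
    true_f = np.empty(n_samples)
    row = 0
    for b, name in enumerate(breed_names):
        other = admix.get(name)
        for _ in range(n_per):
            haps = []
            for _h in range(2):
                if other is not None and rng.random() < other[1]:
                    src = pools[breed_names.index(other[0])]
                else:
                    src = pools[b]
                haps.append(_mosaic_haplotypes(src, 1, switch_prob, rng)[0])
            realized_f = 0.0
            if inbreeding[b] > 0:
                # segment-wise autozygosity: stretches of the second
                # haplotype are identical copies of the first (ROH-like)
                switches = rng.random(n_loci) < switch_prob
                switches[0] = True
                seg_id = np.cumsum(switches) - 1
                auto_seg = rng.random(int(seg_id[-1]) + 1) < inbreeding[b]
                auto = auto_seg[seg_id]
                haps[1] = np.where(auto, haps[0], haps[1])
                realized_f = float(auto.mean())
            haplotypes[row, 0] = haps[0]
            haplotypes[row, 1] = haps[1]
            true_f[row] = realized_f
            samples.append(Sample(id=f"{name}_s{row}", group=name, sex="unknown"))
            row += 1

    calls = (haplotypes[:, 0, :] + haplotypes[:, 1, :]).astype(np.int8)

    truth = TruthRecord(
        breed_names=breed_names,
        breed_freqs=breed_freqs,
        true_f=true_f,
        admixture=admix,
        haplotypes=haplotypes,
    )

    # ascertainment: drop loci rare in every discovery breed
    if config.ascertainment_breeds:
        group_rows = {
            name: np.arange(b * n_per, (b + 1) * n_per) for b, name in enumerate(breed_names)
        }
        rare_everywhere = np.ones(n_loci, dtype=bool)
        for name in config.ascertainment_breeds:
            g = calls[group_rows[name]]
            p = g.mean(axis=0) / 2.0
            maf = np.minimum(p, 1 - p)
            rare_everywhere &= maf < config.ascertainment_min_maf
        keep = ~rare_everywhere
        if not keep.any():
            raise ValueError("ascertainment filter removed every simulated locus")
        loci = [l for l, k in zip(loci, keep) if k]
        calls = calls[:, keep]
        truth = truth.subset_loci(keep)

    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls = calls.copy()
        calls[mask] = MISSING

    panel = GenotypePanel(loci=loci, samples=samples, calls=calls)
    return panel, truth


# ---------------------------------------------------------------------------
# trios
# ---------------------------------------------------------------------------

# offspring genotypes attainable from each (sire, dam) genotype pair
_COMPATIBLE = {
    (0, 0): {0},
    (0, 1): {0, 1},
    (0, 2): {1},
    (1, 1): {0, 1, 2},
    (1, 2): {1, 2},
    (2, 2): {2},
}


def compatible_offspring(g_sire: int, g_dam: int) -> set[int]:
    """Offspring genotypes consistent with Mendelian transmission."""
    return _COMPATIBLE[tuple(sorted((g_sire, g_dam)))]


def simulate_trios(
    panel: GenotypePanel,
    n_trios: int,
    mendelian_error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypePanel, list[tuple[str, str, str]]]:
    """Append simulated offspring of within-breed parent pairs.

    Each offspring receives one transmitted allele per parent per locus.
    At ``mendelian_error_rate`` per locus the offspring call is replaced
    by a genotype *incompatible* with its parents when one exists (for
    het x het matings every genotype is compatible, so no error can be
    planted there); a locus with a missing parent call is left missing.

    Returns the extended panel and the ``(offspring, sire, dam)`` id
    triples.
    """
    rng = np.random.default_rng(seed)
    per_group: list[list[tuple[int, int]]] = []
    for g, idx in panel.group_indices().items():
        idx = list(idx)
        lst = []
        while len(idx) >= 2:
            lst.append((idx.pop(0), idx.pop(0)))
        per_group.append(lst)
    # round-robin over groups, spreading trios across breeds
    pairs: list[tuple[int, int]] = []
    while any(per_group):
        for lst in per_group:
            if lst:
                pairs.append(lst.pop(0))
    if n_trios > len(pairs):
        raise ValueError(f"requested {n_trios} trios but only {len(pairs)} disjoint parent pairs available")
    pairs = pairs[:n_trios]

    kids = np.full((n_trios, panel.n_loci), MISSING, dtype=np.int8)
    kid_samples: list[Sample] = []
    trios: list[tuple[str, str, str]] = []
    for t, (si, di) in enumerate(pairs):
        gs, gd = panel.calls[si], panel.calls[di]
        ok = (gs != MISSING) & (gd != MISSING)
        # transmitted allele: genotype/2 rounds to the hom allele; het transmits coin flip
        a_s = np.where(gs == HET, rng.integers(0, 2, panel.n_loci), gs // 2)
        a_d = np.where(gd == HET, rng.integers(0, 2, panel.n_loci), gd // 2)
        kid = (a_s + a_d).astype(np.int8)
        if mendelian_error_rate > 0:
            hit = ok & (rng.random(panel.n_loci) < mendelian_error_rate)
            for j in np.flatnonzero(hit):
                bad = sorted({0, 1, 2} - compatible_offspring(int(gs[j]), int(gd[j])))
                if bad:
                    kid[j] = bad[rng.integers(0, len(bad))]
        kids[t] = np.where(ok, kid, MISSING)
        sire, dam = panel.samples[si], panel.samples[di]
        kid_id = f"{sire.group}_kid{t}"
        kid_samples.append(
            Sample(id=kid_id, group=sire.group, sex="unknown", sire_id=sire.id, dam_id=dam.id)
        )
        trios.append((kid_id, sire.id, dam.id))

    out = GenotypePanel(
        loci=list(panel.loci),
        samples=list(panel.samples) + kid_samples,
        calls=np.vstack([panel.calls, kids]),
        color_genotypes=panel.color_genotypes,
    )
    return out, trios


# ---------------------------------------------------------------------------
# degraded cross-species panels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaxonDivergence:
    """Assay degradation for one non-focal taxon.

    ``assay_failure_frac``: fraction of loci that fail entirely (missing
    in all individuals of the taxon).  ``monomorphic_frac``: fraction of
    loci fixed for one allele.  ``low_intensity_frac``: fraction of the
    remaining calls whose fluorescence is drawn from the unreliable
    (low-mean) distribution.
    """

    assay_failure_frac: float = 0.0
    monomorphic_frac: float = 0.0
    low_intensity_frac: float = 0.0

    def validate(self) -> None:
        for f in (self.assay_failure_frac, self.monomorphic_frac, self.low_intensity_frac):
            if not 0 <= f <= 1:
                raise ValueError(f"divergence fractions must lie in [0, 1], got {f}")


@dataclass(frozen=True)
class IntensitySpec:
    """Two-component fluorescence model: reliable vs unreliable calls."""

    good_mean: float = 3000.0
    good_sd: float = 500.0
    low_mean: float = 500.0
    low_sd: float = 200.0


def simulate_species_panel(
    config: SimulationConfig,
    divergence: Mapping[str, TaxonDivergence],
    intensity_noise: IntensitySpec = IntensitySpec(),
) -> tuple[GenotypePanel, IntensityTable]:
    """Simulate a degraded multi-taxon panel with per-call intensities.

    ``divergence`` maps taxon names onto the simulated breeds in order;
    distant taxa get higher missingness, more fixed loci and a
    left-shifted intensity distribution, emulating a genotyping array
    applied outside its design species.
    """
    taxa = list(divergence)
    if len(taxa) != config.n_breeds:
        config = replace(config, n_breeds=len(taxa))
    for spec in divergence.values():
        spec.validate()
    panel, _truth = simulate_panel(config)
    rng = np.random.default_rng(config.seed + 1)

    # rename breeds to taxon labels
    name_map = dict(zip([f"breed{i+1}" for i in range(len(taxa))], taxa))
    samples = [replace(s, group=name_map[s.group], id=s.id.replace(s.group, name_map[s.group]))
               for s in panel.samples]
    calls = panel.calls.copy()

    unreliable = np.zeros(calls.shape, dtype=bool)
    for taxon, spec in divergence.items():
        rows = np.array([i for i, s in enumerate(samples) if s.group == taxon])
        fail = rng.random(panel.n_loci) < spec.assay_failure_frac
        mono = rng.random(panel.n_loci) < spec.monomorphic_frac
        calls[np.ix_(rows, np.flatnonzero(mono))] = HOM_A
        calls[np.ix_(rows, np.flatnonzero(fail))] = MISSING
        called = calls[rows] != MISSING
        unreliable[rows] = called & (rng.random(called.shape) < spec.low_intensity_frac)

    called = calls != MISSING
    vals = np.full(calls.shape, np.nan)
    good = called & ~unreliable
    vals[good] = np.clip(
        rng.normal(intensity_noise.good_mean, intensity_noise.good_sd, int(good.sum())), 0, None
    )
    vals[unreliable] = np.clip(
        rng.normal(intensity_noise.low_mean, intensity_noise.low_sd, int(unreliable.sum())), 0, None
    )
    out = GenotypePanel(loci=list(panel.loci), samples=samples, calls=calls)
    return out, IntensityTable(vals)


# ---------------------------------------------------------------------------
# coat-color spiking
# ---------------------------------------------------------------------------


def spike_color_loci(
    panel: GenotypePanel,
    truth: TruthRecord,
    allele_freqs: Mapping[str, float],
    seed: int = 0,
    target_locus: str = "mc1r",
    chromosome: str | None = None,
    center_position: int | None = None,
    founder_length: int = 1_000_000,
) -> tuple[GenotypePanel, TruthRecord]:
    """Embed Mendelian coat-color genotypes linked to an array region.

    The mutant allele of ``target_locus`` rides a single founder
    haplotype: every carrier haplotype has its array SNPs inside the
    ``founder_length`` window around ``center_position`` overwritten with
    one fixed founder pattern, so a conserved homozygous block exists by
    construction and the causal allele is in complete LD with the
    region.  The other color loci are drawn independently under
    Hardy-Weinberg at the given mutant-allele frequencies.

    Returns a new panel (with ``color_genotypes`` populated) and an
    updated truth record carrying the embedded region coordinates and
    per-haplotype carrier status.
    """
    from .colors import COLOR_LOCI, ColorGenotypes, MUTANT_ALLELE, WILD_ALLELE

    if target_locus not in COLOR_LOCI:
        raise ValueError(f"unknown color locus {target_locus!r}; expected one of {COLOR_LOCI}")
    rng = np.random.default_rng(seed)
    chroms = panel.chromosomes
    if chromosome is None:
        chromosome = str(chroms[0])
    on_chrom = np.flatnonzero(chroms == chromosome)
    if on_chrom.size == 0:
        raise ValueError(f"no array loci on chromosome {chromosome!r}")
    positions = panel.positions
    if center_position is None:
        center_position = int(np.median(positions[on_chrom]))
    lo = center_position - founder_length // 2
    hi = lo + founder_length
    chrom_max = positions[on_chrom].max()
    if center_position < 1 or center_position > chrom_max:
        raise ValueError(
            f"requested region center {center_position} lies off chromosome {chromosome!r} "
            f"(last locus at {chrom_max})"
        )
    region = on_chrom[(positions[on_chrom] >= lo) & (positions[on_chrom] < hi)]
    if region.size == 0:
        raise ValueError("founder region contains no array loci")

    q = float(allele_freqs.get(target_locus, 0.0))
    carriers = rng.random((panel.n_samples, 2)) < q
    pattern = (rng.random(region.size) < 0.5).astype(np.int8)

    haplotypes = truth.haplotypes.copy()
    for h in range(2):
        rows = np.flatnonzero(carriers[:, h])
        if rows.size:
            haplotypes[np.ix_(rows, [h], region)] = pattern[None, None, :]

    calls = panel.calls.copy()
    new_geno = (haplotypes[:, 0, :] + haplotypes[:, 1, :]).astype(np.int8)
    was_missing = calls == MISSING
    calls[:, region] = new_geno[:, region]
    calls[was_missing] = MISSING

    wild, mut = WILD_ALLELE, MUTANT_ALLELE
    color: dict[str, ColorGenotypes] = {}
    for i, s in enumerate(panel.samples):
        geno: dict[str, tuple[str, str]] = {}
        for name in COLOR_LOCI:
            if name == target_locus:
                pair = tuple(mut[name] if carriers[i, h] else wild[name] for h in range(2))
            else:
                f = float(allele_freqs.get(name, 0.0))
                pair = tuple(mut[name] if rng.random() < f else wild[name] for _ in range(2))
            geno[name] = pair
        color[s.id] = ColorGenotypes(**geno)

    out = GenotypePanel(
        loci=list(panel.loci), samples=list(panel.samples), calls=calls, color_genotypes=color
    )
    new_truth = TruthRecord(
        breed_names=truth.breed_names,
        breed_freqs=truth.breed_freqs,
        true_f=truth.true_f,
        admixture=truth.admixture,
        haplotypes=haplotypes,
        causal_locus=target_locus,
        causal_region=(chromosome, int(max(lo, 1)), int(hi - 1)),
        carrier_haplotypes=carriers,
    )
    return out, new_truth
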