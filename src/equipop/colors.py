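"""Coat-color phenotype inference, case-control association, and
conserved-haplotype delimitation.

Phenotype engine
----------------
Nine classical coat-color loci are modelled, each biallelic
(wild-type / mutant): MC1R (chestnut, recessive), ASIP (black/bay,
recessive among non-chestnut), STX17 (gray, dominant and epistatic over
everything), SLC36A1 (champagne), MATP (cream), PMEL17 (silver), KIT
exon-skipping (sabino), EDNRB (overo) and a KIT inversion (tobiano).
Inference applies the rules in fixed order: base color from MC1R; black
vs bay from ASIP among non-chestnut horses; named dilution/patterning
phenotypes (palomino, buckskin, cremello, smoky black, white
patterning); gray overriding all; and an optional breed-level dun
override for populations fixed for dun.  Modifier combinations without
a conventional single name are labelled ``"modified"``.

Association tests
-----------------
Allelic association is the 1-df chi-square on the 2x2 allele x status
table without continuity correction; the stratified analog is the
Cochran-Mantel-Haenszel (CMH) 2x2xK statistic.  Family-wise correction
uses label-swapping max-T permutations with the (1 + k) / (B + 1)
estimator; stratified tests permute labels within strata.  The genomic
inflation factor is the median observed chi-square divided by the 1-df
null median (~0.4549).

Haplotype blocks
----------------
The conserved haplotype around a recessive locus is delimited from
mutant homozygotes directly: extend from the anchor SNP while every
carrier is homozygous and all carriers share the same homozygous
genotype.  For groups without homozygotes a shared-allele relaxation
(every carrier keeps at least one copy of a common allele) substitutes
for haplotype phasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import HET, MISSING, GenotypePanel
from .structure import ibs_distance_matrix

__all__ = [
    "COLOR_LOCI",
    "WILD_ALLELE",
    "MUTANT_ALLELE",
    "ColorGenotypes",
    "PhenotypeCall",
    "AssociationResult",
    "HaplotypeBlock",
    "infer_coat_phenotype",
    "phenotype_cases",
    "association_qc_filter",
    "QCFilterResult",
    "hwe_exact_p",
    "allelic_association",
    "cluster_samples",
    "cmh_association",
    "maxT_correction",
    "genomic_inflation",
    "conserved_haplotype",
    "intersect_blocks",
    "block_to_bed",
]

COLOR_LOCI = (
    "mc1r",
    "asip",
    "stx17",
    "slc36a1",
    "matp",
    "pmel17",
    "kit_exon_skip",
    "ednrb",
    "kit_inversion",
)

WILD_ALLELE = {l: {"mc1r": "E", "asip": "A"}.get(l, "n") for l in COLOR_LOCI}
MUTANT_ALLELE = {
    "mc1r": "M",
    "asip": "a",
    "stx17": "G",
    "slc36a1": "Ch",
    "matp": "Cr",
    "pmel17": "Z",
    "kit_exon_skip": "SB1",
    "ednrb": "O",
    "kit_inversion": "TO",
}

#: loci whose mutant allele acts dominantly in single-locus mode
_DOMINANT = {"stx17", "slc36a1", "matp", "pmel17", "kit_exon_skip", "ednrb", "kit_inversion"}


@dataclass(frozen=True)
class ColorGenotypes:
    """Per-sample genotypes at the nine color loci (None = untyped)."""

    mc1r: tuple[str, str] | None = None
    asip: tuple[str, str] | None = None
    stx17: tuple[str, str] | None = None
    slc36a1: tuple[str, str] | None = None
    matp: tuple[str, str] | None = None
    pmel17: tuple[str, str] | None = None
    kit_exon_skip: tuple[str, str] | None = None
    ednrb: tuple[str, str] | None = None
    kit_inversion: tuple[str, str] | None = None

    def mutant_count(self, locus: str) -> int | None:
        pair = getattr(self, locus)
        if pair is None:
            return None
        return sum(a == MUTANT_ALLELE[locus] for a in pair)


@dataclass(frozen=True)
class PhenotypeCall:
    base_color: str | None  # chestnut / black / bay
    final_color: str | None
    case: bool | None  # status for the designated target locus
    mode: str  # multilocus / single_locus
    reason: str = ""


def infer_coat_phenotype(
    cg: ColorGenotypes,
    mode: str = "multilocus",
    target: str = "mc1r",
    dun_override: bool = False,
) -> PhenotypeCall:
    """Infer coat color, and case/control status for ``target``.

    ``multilocus`` applies the full rule cascade; gray horses are
    uninformative for base-color targets (status ``None``) because gray
    masks every other phenotype.  ``single_locus`` ignores epistasis and
    calls status from the target genotype alone (chestnut and black
    recessive, gray dominant).  ``dun_override`` labels the final color
    dun (breeds fixed for dun) unless the horse is gray.
    """
    if target not in COLOR_LOCI:
        raise ValueError(f"unknown target locus {target!r}")

    if mode == "single_locus":
        k = cg.mutant_count(target)
        if k is None:
            return PhenotypeCall(None, None, None, mode, f"{target} untyped")
        case = (k >= 1) if target in _DOMINANT else (k == 2)
        return PhenotypeCall(None, None, case, mode)
    if mode != "multilocus":
        raise ValueError(f"unknown inference mode {mode!r}")

    k_mc1r = cg.mutant_count("mc1r")
    if k_mc1r is None:
        return PhenotypeCall(None, None, None, mode, "mc1r untyped")
    if k_mc1r == 2:
        base = "chestnut"
    else:
        k_asip = cg.mutant_count("asip")
        if k_asip is None:
            return PhenotypeCall(None, None, None, mode, "asip untyped")
        base = "black" if k_asip == 2 else "bay"

    cream = cg.mutant_count("matp") or 0
    champagne = cg.mutant_count("slc36a1") or 0
    silver = cg.mutant_count("pmel17") or 0
    patterned = any(
        (cg.mutant_count(l) or 0) >= 1 for l in ("kit_exon_skip", "ednrb", "kit_inversion")
    )
    n_modifier_kinds = (cream > 0) + (champagne > 0) + (silver > 0) + patterned

    final = base
    if n_modifier_kinds == 1:
        if cream:
            named = {
                ("chestnut", 1): "palomino",
                ("chestnut", 2): "cremello",
                ("bay", 1): "buckskin",
                ("black", 1): "smoky black",
            }
            final = named.get((base, cream), "modified")
        elif champagne or silver:
            final = "modified"  # no single conventional name guaranteed
        elif patterned:
            final = "white_patterned"
    elif n_modifier_kinds > 1:
        final = "modified"

    k_gray = cg.mutant_count("stx17")
    is_gray = (k_gray or 0) >= 1
    if is_gray:
        final = "gray"  # epistatic dominance over everything
    elif dun_override:
        final = "dun"

    if target == "stx17":
        case = is_gray if k_gray is not None else None
    elif target == "mc1r":
        case = None if is_gray else (base == "chestnut")
    elif target == "asip":
        if is_gray or base == "chestnut":
            case = None  # masked: gray hides color, chestnut hides ASIP
        else:
            case = base == "black"
    else:
        k = cg.mutant_count(target)
        if k is None or is_gray:
            case = None
        else:
            case = (k >= 1) if target in _DOMINANT else (k == 2)
    return PhenotypeCall(base, final, case, mode)


def phenotype_cases(
    panel: GenotypePanel,
    target: str = "mc1r",
    mode: str = "multilocus",
    dun_groups: tuple[str, ...] = (),
) -> tuple[list[str], list[str]]:
    """Case/control sample-id lists for ``target`` from the panel's
    color genotypes.

    Samples with undefined status are dropped; members of ``dun_groups``
    (breeds fixed for dun) are excluded from case/control sets for
    dilution-locus targets.
    """
    if panel.color_genotypes is None:
        raise ValueError("panel carries no color genotypes")
    dilution = {"matp", "slc36a1", "pmel17"}
    cases, controls = [], []
    for s in panel.samples:
        cg = panel.color_genotypes.get(s.id)
        if cg is None:
            continue
        dun = s.group in dun_groups
        if dun and target in dilution:
            continue
        call = infer_coat_phenotype(cg, mode=mode, target=target, dun_override=dun)
        if call.case is None:
            continue
        (cases if call.case else controls).append(s.id)
    return cases, controls


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value (full enumeration of
    heterozygote counts conditional on allele counts), two-sided by
    probability mass, no mid-p."""
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het
    if rare == 0:
        return 1.0
    # unnormalized probabilities over all feasible het counts (same parity)
    het_min = rare % 2
    hets = list(range(het_min, min(rare, 2 * n - rare) + 1, 2))
    probs = {}
    h = hets[0]
    probs[h] = 1.0
    for h in hets[:-1]:
        hom_r = (rare - h) / 2
        hom_c = (n - h - hom_r)
        # ratio P(h+2)/P(h)
        ratio = 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        probs[h + 2] = probs[h] * ratio
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    return min(1.0, sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total)


@dataclass
class QCFilterResult:
    panel: GenotypePanel  # filtered samples x filtered loci
    locus_mask: np.ndarray  # over the input panel's loci
    cases: list[str]
    controls: list[str]
    removed: dict[str, int] = field(default_factory=dict)


def association_qc_filter(
    panel: GenotypePanel,
    cases: list[str],
    controls: list[str],
    min_sample_rate: float = 0.9,
    min_locus_rate: float = 0.9,
    min_maf: float = 0.01,
    hwe_p: float = 0.001,
    missing_p: float = 0.01,
    hwe_in: str = "controls",
) -> QCFilterResult:
    """Sequential pre-association QC.

    Order: individuals with call rate < ``min_sample_rate`` out; then
    loci with call rate < ``min_locus_rate``; MAF < ``min_maf``; exact
    Hardy-Weinberg p < ``hwe_p`` (in controls by default, set
    ``hwe_in="all"`` for everyone); differential case/control
    missingness chi-square p < ``missing_p``.  All rates/frequencies are
    computed on the case+control samples.
    """
    sidx = {s: i for i, s in enumerate(panel.sample_ids)}
    rows = np.array([sidx[s] for s in cases + controls], dtype=np.intp)
    status = np.array([True] * len(cases) + [False] * len(controls))

    sub = panel.calls[rows]
    s_rate = (sub != MISSING).mean(axis=1)
    keep_s = s_rate >= min_sample_rate
    rows, status = rows[keep_s], status[keep_s]
    sub = panel.calls[rows]
    removed = {"samples_low_rate": int((~keep_s).sum())}

    called = sub != MISSING
    n_called = called.sum(axis=0)
    rate = called.mean(axis=0)
    mask = rate >= min_locus_rate
    removed["loci_low_rate"] = int((~mask).sum())

    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, np.where(called, sub, 0).sum(axis=0) / (2.0 * n_called), 0.0)
    maf = np.minimum(p, 1 - p)
    hit = mask & (maf < min_maf)
    removed["loci_low_maf"] = int(hit.sum())
    mask &= maf >= min_maf

    hwe_rows = np.ones(rows.size, dtype=bool) if hwe_in == "all" else ~status
    gh = sub[hwe_rows]
    n_hwe_removed = 0
    for j in np.flatnonzero(mask):
        col = gh[:, j]
        col = col[col != MISSING]
        ph = hwe_exact_p(int((col == HET).sum()), int((col == 0).sum()), int((col == 2).sum()))
        if ph < hwe_p:
            mask[j] = False
            n_hwe_removed += 1
    removed["loci_hwe"] = n_hwe_removed

    n_case, n_ctrl = int(status.sum()), int((~status).sum())
    n_diff_removed = 0
    if n_case and n_ctrl:
        miss_case = (~called[status]).sum(axis=0)
        miss_ctrl = (~called[~status]).sum(axis=0)
        for j in np.flatnonzero(mask):
            table = np.array(
                [
                    [n_case - miss_case[j], miss_case[j]],
                    [n_ctrl - miss_ctrl[j], miss_ctrl[j]],
                ],
                dtype=float,
            )
            if table[:, 1].sum() == 0:
                continue
            chi2 = _chi2_2x2(table)
            if np.isfinite(chi2) and stats.chi2.sf(chi2, 1) < missing_p:
                mask[j] = False
                n_diff_removed += 1
    removed["loci_diff_missing"] = n_diff_removed

    if not mask.any():
        raise ValueError("association QC removed every locus")

    kept_ids = [panel.sample_ids[i] for i in rows]
    out = panel.subset(samples=rows, loci=mask)
    return QCFilterResult(
        panel=out,
        locus_mask=mask,
        cases=[s for s, st in zip(kept_ids, status) if st],
        controls=[s for s, st in zip(kept_ids, status) if not st],
        removed=removed,
    )


def _chi2_2x2(table: np.ndarray) -> float:
    """Pearson chi-square on a 2x2 table, no continuity correction."""
    n = table.sum()
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    if n == 0 or (r == 0).any() or (c == 0).any():
        return float("nan")
    det = table[0, 0] * table[1, 1] - table[0, 1] * table[1, 0]
    return float(n * det * det / (r[0] * r[1] * c[0] * c[1]))


# ---------------------------------------------------------------------------
# association statistics
# ---------------------------------------------------------------------------


@dataclass
class AssociationResult:
    frame: pd.DataFrame  # locus_id, chromosome, position, chi2, df, p_raw[, p_corrected]
    test: str
    clusters: np.ndarray | None = None
    lambda_gc: float | None = None

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.frame.nsmallest(n, "p_raw")


def _allele_counts(calls: np.ndarray, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (allele-B count, total allele count) over given rows."""
    sub = calls[rows]
    called = sub != MISSING
    b = np.where(called, sub, 0).sum(axis=0).astype(float)
    tot = 2.0 * called.sum(axis=0)
    return b, tot


def _chi2_allelic(b1, t1, b2, t2) -> np.ndarray:
    """Vectorized 2x2 allele-count chi-square (rows status, cols allele)."""
    a1, a2 = t1 - b1, t2 - b2
    n = t1 + t2
    colB, colA = b1 + b2, a1 + a2
    with np.errstate(invalid="ignore", divide="ignore"):
        det = b1 * a2 - b2 * a1
        chi2 = n * det * det / (t1 * t2 * colB * colA)
    chi2[(t1 == 0) | (t2 == 0) | (colB == 0) | (colA == 0)] = np.nan
    return chi2


def allelic_association(
    panel: GenotypePanel, cases: list[str], controls: list[str]
) -> AssociationResult:
    """Per-locus 1-df chi-square for allelic association.

    Builds the 2x2 allele x status count table per locus and applies the
    Pearson chi-square without continuity correction.  Loci with a zero
    margin get NaN statistics.
    """
    if not cases or not controls:
        raise ValueError("need at least one case and one control")
    sidx = {s: i for i, s in enumerate(panel.sample_ids)}
    r_case = np.array([sidx[s] for s in cases], dtype=np.intp)
    r_ctrl = np.array([sidx[s] for s in controls], dtype=np.intp)
    b1, t1 = _allele_counts(panel.calls, r_case)
    b2, t2 = _allele_counts(panel.calls, r_ctrl)
    chi2 = _chi2_allelic(b1, t1, b2, t2)
    frame = pd.DataFrame(
        {
            "locus_id": panel.locus_ids,
            "chromosome": panel.chromosomes,
            "position": panel.positions,
            "chi2": chi2,
            "df": 1,
            "p_raw": stats.chi2.sf(chi2, 1),
        }
    )
    res = AssociationResult(frame=frame, test="allelic")
    if np.isfinite(chi2).sum() >= 100:
        res.lambda_gc = genomic_inflation(chi2)
    return res


def _cmh_components(
    calls: np.ndarray,
    rows_by_stratum: list[np.ndarray],
    status_by_stratum: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Return (sum of a - E[a], sum of Var[a]) per locus over strata,
    where ``a`` is the case allele-B count of each stratum's 2x2 table."""
    n_loci = calls.shape[1]
    num = np.zeros(n_loci)
    var = np.zeros(n_loci)
    for rows, status in zip(rows_by_stratum, status_by_stratum):
        if rows.size == 0 or status.all() or (~status).all():
            continue  # stratum without both statuses contributes nothing
        b_case, t_case = _allele_counts(calls, rows[status])
        b_ctrl, t_ctrl = _allele_counts(calls, rows[~status])
        n = t_case + t_ctrl
        colB = b_case + b_ctrl
        colA = n - colB
        ok = (n > 1) & (t_case > 0) & (t_ctrl > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            e = t_case * colB / n
            v = t_case * t_ctrl * colB * colA / (n * n * (n - 1))
        num += np.where(ok, b_case - e, 0.0)
        var += np.where(ok, v, 0.0)
    return num, var


def cmh_association(
    panel: GenotypePanel,
    cases: list[str],
    controls: list[str],
    clusters: np.ndarray | dict[str, int],
) -> AssociationResult:
    """Cochran-Mantel-Haenszel 2x2xK allele-count test, 1 df.

    ``clusters`` assigns each sample to a stratum (array aligned to the
    panel's samples, or a sample-id -> label mapping).  Strata lacking
    both cases and controls, or lacking allelic variation, contribute
    zero to numerator and variance.
    """
    sidx = {s: i for i, s in enumerate(panel.sample_ids)}
    if isinstance(clusters, dict):
        cl = np.array([clusters.get(s, -1) for s in panel.sample_ids])
    else:
        cl = np.asarray(clusters)
    rows_by, status_by = [], []
    for k in pd.unique(cl):
        members = np.flatnonzero(cl == k)
        in_study = [
            (i, True) for i in members if panel.sample_ids[i] in set(cases)
        ] + [(i, False) for i in members if panel.sample_ids[i] in set(controls)]
        if not in_study:
            continue
        rows_by.append(np.array([i for i, _ in in_study], dtype=np.intp))
        status_by.append(np.array([st for _, st in in_study]))
    if not any((s.any() and (~s).any()) for s in status_by):
        raise ValueError("no stratum contains both cases and controls")

    num, var = _cmh_components(panel.calls, rows_by, status_by)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(var > 0, num * num / var, np.nan)
    frame = pd.DataFrame(
        {
            "locus_id": panel.locus_ids,
            "chromosome": panel.chromosomes,
            "position": panel.positions,
            "chi2": chi2,
            "df": 1,
            "p_raw": stats.chi2.sf(chi2, 1),
        }
    )
    res = AssociationResult(frame=frame, test="cmh", clusters=cl)
    if np.isfinite(chi2).sum() >= 100:
        res.lambda_gc = genomic_inflation(chi2)
    return res


def cluster_samples(
    panel: GenotypePanel,
    merge_p: float = 0.01,
    n_perm: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Concordance-constrained complete-linkage clustering on IBS distance.

    Clusters are agglomerated greedily by complete linkage on an IBS
    distance matrix computed from the even-indexed loci.  Before each
    merge, a permutation homogeneity test asks whether the two candidate
    clusters look like one population: the statistic is the mean
    between-cluster minus mean within-cluster IBS distance, evaluated on
    a *second* distance matrix from the odd-indexed loci, with cluster
    memberships permuted.  Splitting the loci decouples the test from
    cluster selection (clusters picked on one half of the genome would
    otherwise always look significantly tight on the same data), so the
    test is calibrated under homogeneity.  A merge is forbidden when the
    permutation p-value falls below ``merge_p``; ``merge_p >= 1``
    disables the test so everything merges.  Returns integer cluster
    labels per sample.
    """
    rng = np.random.default_rng(seed)
    n = panel.n_samples
    if merge_p >= 1.0:
        return np.zeros(n, dtype=np.int64)
    even = np.arange(panel.n_loci) % 2 == 0
    dist_sel = ibs_distance_matrix(panel.subset(loci=even)).values
    dist_test = ibs_distance_matrix(panel.subset(loci=~even)).values
    clusters: list[list[int]] = [[i] for i in range(n)]

    def complete_link(a: list[int], b: list[int]) -> float:
        return float(dist_sel[np.ix_(a, b)].max())

    def merge_allowed(a: list[int], b: list[int]) -> bool:
        pooled = a + b
        if len(pooled) < 3:
            return True  # nothing to permute against
        labels = np.array([0] * len(a) + [1] * len(b))

        def statistic(lab: np.ndarray) -> float:
            ga = [pooled[i] for i in np.flatnonzero(lab == 0)]
            gb = [pooled[i] for i in np.flatnonzero(lab == 1)]
            between = dist_test[np.ix_(ga, gb)].mean()
            within_vals = []
            for g in (ga, gb):
                if len(g) >= 2:
                    m = dist_test[np.ix_(g, g)]
                    within_vals.append(m[np.triu_indices(len(g), 1)].mean())
            if not within_vals:
                return 0.0
            return float(between - np.mean(within_vals))

        t_obs = statistic(labels)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            if statistic(perm) >= t_obs:
                hits += 1
        p = (1 + hits) / (n_perm + 1)
        return p >= merge_p

    while len(clusters) > 1:
        pairs = sorted(
            (
                (complete_link(clusters[i], clusters[j]), i, j)
                for i in range(len(clusters))
                for j in range(i + 1, len(clusters))
            )
        )
        merged = False
        for _, i, j in pairs:
            if merge_allowed(clusters[i], clusters[j]):
                clusters[i] = clusters[i] + clusters[j]
                del clusters[j]
                merged = True
                break
        if not merged:
            break

    labels = np.empty(n, dtype=np.int64)
    for k, members in enumerate(clusters):
        labels[members] = k
    return labels


def maxT_correction(
    panel: GenotypePanel,
    cases: list[str],
    controls: list[str],
    statistic: str = "allelic",
    clusters: np.ndarray | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> AssociationResult:
    """Label-swapping max-T family-wise corrected p-values.

    Case/control labels are permuted (within strata for the CMH
    statistic), the chosen statistic is recomputed genome-wide per
    permutation, and each SNP's corrected p is
    ``(1 + #{permutation max >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; corrected p-values will be coarse")
    rng = np.random.default_rng(seed)
    if statistic == "allelic":
        base = allelic_association(panel, cases, controls)
        strata = [np.arange(panel.n_samples)]
    elif statistic == "cmh":
        if clusters is None:
            raise ValueError("cmh max-T needs cluster assignments")
        base = cmh_association(panel, cases, controls, clusters)
        strata = [np.flatnonzero(np.asarray(clusters) == k) for k in pd.unique(np.asarray(clusters))]
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    sidx = {s: i for i, s in enumerate(panel.sample_ids)}
    case_set = set(cases)
    study_rows = np.array([sidx[s] for s in cases + controls], dtype=np.intp)
    obs = base.frame["chi2"].to_numpy()
    obs_f = np.where(np.isfinite(obs), obs, -np.inf)
    exceed = np.zeros(panel.n_loci, dtype=np.int64)

    status = np.array([panel.sample_ids[i] in case_set for i in study_rows])
    strata_of_study = [
        np.flatnonzero(np.isin(study_rows, s)) for s in strata
    ]
    for _ in range(n_perm):
        perm_status = status.copy()
        for members in strata_of_study:
            perm_status[members] = perm_status[members][rng.permutation(members.size)]
        if statistic == "allelic":
            b1, t1 = _allele_counts(panel.calls, study_rows[perm_status])
            b2, t2 = _allele_counts(panel.calls, study_rows[~perm_status])
            chi2 = _chi2_allelic(b1, t1, b2, t2)
        else:
            rows_by = [study_rows[m] for m in strata_of_study]
            status_by = [perm_status[m] for m in strata_of_study]
            num, var = _cmh_components(panel.calls, rows_by, status_by)
            with np.errstate(invalid="ignore", divide="ignore"):
                chi2 = np.where(var > 0, num * num / var, np.nan)
        m = np.nanmax(chi2) if np.isfinite(chi2).any() else -np.inf
        exceed += m >= obs_f
    frame = base.frame.copy()
    frame["p_corrected"] = np.where(
        np.isfinite(obs), (1.0 + exceed) / (n_perm + 1.0), np.nan
    )
    return AssociationResult(frame=frame, test=base.test, clusters=base.clusters, lambda_gc=base.lambda_gc)


def genomic_inflation(chi2: np.ndarray | AssociationResult) -> float:
    """Genomic inflation factor: median observed 1-df chi-square over
    the null median (chi2.ppf(0.5, 1) ~ 0.4549)."""
    if isinstance(chi2, AssociationResult):
        chi2 = chi2.frame["chi2"].to_numpy()
    vals = np.asarray(chi2, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite statistics for inflation factor")
    return float(np.median(vals) / stats.chi2.ppf(0.5, 1))


# ---------------------------------------------------------------------------
# conserved haplotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HaplotypeBlock:
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    n_chromosomes: int
    n_snps: int
    group: str = "all"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("block start must not exceed end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def conserved_haplotype(
    panel: GenotypePanel,
    chromosome: str,
    position: int,
    carriers: list[str],
    group: str = "all",
    mode: str = "homozygote",
) -> HaplotypeBlock:
    """Maximal conserved block around a position shared by all carriers.

    ``homozygote`` mode (carriers homozygous for the risk allele):
    starting from the array SNP nearest ``position``, extend left and
    right while every called carrier is homozygous and all called
    carriers share the same homozygous genotype.  ``shared_allele`` mode
    (for groups with heterozygous carriers only) extends while one
    common allele is present in every called carrier's genotype — a
    phasing-free stand-in for haplotype reconstruction.  Missing calls
    are ignored rather than breaking the block.
    """
    if not carriers:
        raise ValueError("no carrier samples supplied")
    if len(carriers) == 1:
        warnings.warn("single carrier: block is low-confidence")
    rows = np.array([panel.sample_index(s) for s in carriers], dtype=np.intp)
    chroms = panel.chromosomes
    on = np.flatnonzero(chroms == chromosome)
    if on.size == 0:
        raise ValueError(f"no loci on chromosome {chromosome!r}")
    on = on[np.argsort(panel.positions[on])]
    pos = panel.positions[on]
    anchor = int(np.argmin(np.abs(pos - position)))

    def qualifies(j_col: int) -> bool:
        g = panel.calls[rows, j_col]
        g = g[g != MISSING]
        if g.size == 0:
            return True  # uninformative SNP, tolerated
        if mode == "homozygote":
            return bool((g != HET).all() and np.unique(g).size == 1)
        if mode == "shared_allele":
            # allele sets: 0 -> {A}, 1 -> {A,B}, 2 -> {B}
            has_a = (g != 2).all()
            has_b = (g != 0).all()
            return bool(has_a or has_b)
        raise ValueError(f"unknown mode {mode!r}")

    if not qualifies(on[anchor]):
        raise ValueError("anchor SNP is not conserved among carriers; no block")
    left = anchor
    while left > 0 and qualifies(on[left - 1]):
        left -= 1
    right = anchor
    while right < on.size - 1 and qualifies(on[right + 1]):
        right += 1
    n_chrom = 2 * len(carriers) if mode == "homozygote" else len(carriers)
    return HaplotypeBlock(
        chromosome=chromosome,
        start=int(pos[left]),
        end=int(pos[right]),
        n_chromosomes=n_chrom,
        n_snps=int(right - left + 1),
        group=group,
    )


def intersect_blocks(blocks: list[HaplotypeBlock], panel: GenotypePanel | None = None) -> HaplotypeBlock:
    """Across-group minimal block: the intersection of per-group blocks."""
    if not blocks:
        raise ValueError("no blocks to intersect")
    chrom = blocks[0].chromosome
    if any(b.chromosome != chrom for b in blocks):
        raise ValueError("blocks lie on different chromosomes")
    start = max(b.start for b in blocks)
    end = min(b.end for b in blocks)
    if start > end:
        raise ValueError("blocks do not overlap")
    n_snps = min(b.n_snps for b in blocks)
    if panel is not None:
        sel = (panel.chromosomes == chrom) & (panel.positions >= start) & (panel.positions <= end)
        n_snps = int(sel.sum())
    return HaplotypeBlock(
        chromosome=chrom,
        start=start,
        end=end,
        n_chromosomes=sum(b.n_chromosomes for b in blocks),
        n_snps=n_snps,
        group="across-breeds",
    )


def block_to_bed(block: HaplotypeBlock) -> tuple[str, int, int]:
    """Convert a 1-based inclusive block to 0-based half-open BED."""
    return (block.chromosome, block.start - 1, block.end)
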