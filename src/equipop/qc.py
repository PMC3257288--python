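"""Array and panel summary statistics.

Definitions follow standard SNP-array reporting practice:

* **conversion rate** = loci producing any genotype call / loci assayed;
* **validation rate** = converted loci with at least one heterozygous
  call / converted loci;
* **polymorphic** locus (per group): MAF >= 0.01; **informative**:
  MAF > 0.05;
* **Mendelian agreement** = 1 - errors / loci genotyped in all three
  trio members;
* **replication frequency** = concordant / jointly-called genotypes over
  duplicate sample pairs.

Expected heterozygosity H_E is the mean of ``2 p (1 - p)`` over loci
validated panel-wide, with group-specific allele frequencies and no
small-sample correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import HET, MISSING, GenotypePanel
from .simulate import compatible_offspring

__all__ = [
    "AssaySummary",
    "GroupStats",
    "summarize_assay",
    "allele_frequencies",
    "mendelian_agreement",
    "replication_frequency",
]


@dataclass(frozen=True)
class GroupStats:
    group: str
    n_samples: int
    n_polymorphic: int  # MAF >= 0.01
    n_informative: int  # MAF > 0.05
    mean_maf: float
    median_maf: float
    expected_heterozygosity: float


@dataclass
class AssaySummary:
    n_assayed: int
    n_converted: int
    n_validated: int
    per_group: dict[str, GroupStats]
    sample_call_rate: np.ndarray
    locus_call_rate: np.ndarray

    @property
    def conversion_rate(self) -> float:
        return self.n_converted / self.n_assayed

    @property
    def validation_rate(self) -> float:
        return self.n_validated / self.n_converted if self.n_converted else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": g.group,
                "n_samples": g.n_samples,
                "n_polymorphic": g.n_polymorphic,
                "n_informative": g.n_informative,
                "mean_maf": g.mean_maf,
                "median_maf": g.median_maf,
                "expected_heterozygosity": g.expected_heterozygosity,
            }
            for g in self.per_group.values()
        ]
        return pd.DataFrame(rows)


def allele_frequencies(
    panel: GenotypePanel, group: str | None = None
) -> pd.DataFrame:
    """Per-locus MAF, allele-B frequency, call rate and H_E contribution.

    Frequencies are computed over non-missing calls, restricted to the
    samples of ``group`` when given.  Loci with no non-missing calls in
    the group get NaN frequencies and ``undefined=True``.
    """
    if group is None:
        calls = panel.calls
    else:
        idx = panel.group_indices().get(group)
        if idx is None or idx.size == 0:
            raise ValueError(f"group {group!r} is empty or absent")
        calls = panel.calls[idx]
    called = calls != MISSING
    n_called = called.sum(axis=0)
    b_count = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_b = np.where(n_called > 0, b_count / (2.0 * n_called), np.nan)
    maf = np.minimum(p_b, 1 - p_b)
    he = 2 * p_b * (1 - p_b)
    return pd.DataFrame(
        {
            "locus_id": panel.locus_ids,
            "chromosome": panel.chromosomes,
            "position": panel.positions,
            "freq_b": p_b,
            "maf": maf,
            "call_rate": n_called / calls.shape[0],
            "het_exp": he,
            "undefined": n_called == 0,
        }
    )


def summarize_assay(
    panel: GenotypePanel,
    n_assayed: int | None = None,
    groups: dict[str, list[str]] | None = None,
) -> AssaySummary:
    """Panel-wide conversion/validation counts plus per-group diversity.

    ``n_assayed`` is the number of markers on the assay (>= loci present
    in the panel); it defaults to the panel's locus count.  ``groups``
    maps labels to sample-id lists; by default the samples' own group
    labels are used.  Converted = at least one non-missing call;
    validated = converted with at least one heterozygous call.  Per-group
    mean/median MAF are over converted loci (monomorphic loci included at
    MAF 0); H_E is the mean of 2p(1-p) over panel-wide validated loci.
    """
    if n_assayed is None:
        n_assayed = panel.n_loci
    if n_assayed < panel.n_loci:
        raise ValueError(f"n_assayed={n_assayed} < {panel.n_loci} loci present in panel")
    converted = (panel.calls != MISSING).any(axis=0)
    validated = converted & (panel.calls == HET).any(axis=0)

    if groups is None:
        group_rows = panel.group_indices()
    else:
        sidx = {s: i for i, s in enumerate(panel.sample_ids)}
        group_rows = {g: np.array([sidx[s] for s in ids], dtype=np.intp) for g, ids in groups.items()}

    per_group: dict[str, GroupStats] = {}
    for g, rows in group_rows.items():
        if rows.size == 0:
            warnings.warn(f"group {g!r} has no samples; omitted from summary")
            continue
        calls = panel.calls[rows]
        called = calls != MISSING
        n_called = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_called > 0, np.where(called, calls, 0).sum(axis=0) / (2.0 * n_called), np.nan)
        maf = np.minimum(p, 1 - p)
        conv_maf = maf[converted & (n_called > 0)]
        he = 2 * p * (1 - p)
        per_group[g] = GroupStats(
            group=g,
            n_samples=int(rows.size),
            n_polymorphic=int(np.nansum(maf >= 0.01)),
            n_informative=int(np.nansum(maf > 0.05)),
            mean_maf=float(np.nanmean(conv_maf)) if conv_maf.size else float("nan"),
            median_maf=float(np.nanmedian(conv_maf)) if conv_maf.size else float("nan"),
            expected_heterozygosity=float(np.nanmean(he[validated])) if validated.any() else float("nan"),
        )

    return AssaySummary(
        n_assayed=int(n_assayed),
        n_converted=int(converted.sum()),
        n_validated=int(validated.sum()),
        per_group=per_group,
        sample_call_rate=panel.sample_call_rates(),
        locus_call_rate=panel.locus_call_rates(),
    )


def mendelian_agreement(
    panel: GenotypePanel, trios: list[tuple[str, str, str]]
) -> pd.DataFrame:
    """Per-trio Mendelian agreement: 1 - errors / loci typed in all three.

    A locus counts as an error when the offspring genotype cannot arise
    from any transmission of the parental genotypes under biallelic
    Mendelian rules.  Loci missing in any trio member are excluded from
    the denominator.
    """
    rows = []
    for kid, sire, dam in trios:
        if kid in (sire, dam) or sire == dam:
            raise ValueError(f"degenerate trio {(kid, sire, dam)}: members must be distinct")
        gk = panel.calls[panel.sample_index(kid)]
        gs = panel.calls[panel.sample_index(sire)]
        gd = panel.calls[panel.sample_index(dam)]
        ok = (gk != MISSING) & (gs != MISSING) & (gd != MISSING)
        errors = 0
        for j in np.flatnonzero(ok):
            if int(gk[j]) not in compatible_offspring(int(gs[j]), int(gd[j])):
                errors += 1
        n = int(ok.sum())
        rows.append(
            {
                "offspring": kid,
                "sire": sire,
                "dam": dam,
                "n_loci": n,
                "n_errors": errors,
                "agreement": 1.0 - errors / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def replication_frequency(
    panel: GenotypePanel, pairs: list[tuple[str, str]]
) -> tuple[float, int]:
    """Concordance over duplicate genotyping pairs.

    Returns ``(fraction concordant, n jointly-called genotypes)`` pooled
    over all pairs.
    """
    concordant = total = 0
    for a, b in pairs:
        ga = panel.calls[panel.sample_index(a)]
        gb = panel.calls[panel.sample_index(b)]
        joint = (ga != MISSING) & (gb != MISSING)
        total += int(joint.sum())
        concordant += int((ga[joint] == gb[joint]).sum())
    return (concordant / total if total else float("nan"), total)
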