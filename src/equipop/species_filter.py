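"""Three-stage filtering cascade for degraded cross-species panels.

When a genotyping array designed for one species is applied to related
taxa, a large share of calls is unreliable.  The cascade removes them in
a fixed order:

1. :func:`filter_by_intensity` — calls whose summed raw fluorescence is
   below a threshold (default 1000) become missing;
2. :func:`filter_individuals_by_rate` — within each suborder-level
   group, individuals whose post-intensity call rate falls more than two
   standard deviations below the group mean are excluded (single pass);
3. :func:`filter_markers_by_rate` — markers called in strictly more than
   ``min_rate`` (default 90%) of the remaining individuals are kept.

:func:`run_species_filter` applies the stages in order and returns the
filtered panel plus a :class:`SpeciesFilterReport`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import HET, MISSING, GenotypePanel, IntensityTable

__all__ = [
    "SpeciesFilterReport",
    "filter_by_intensity",
    "filter_individuals_by_rate",
    "filter_markers_by_rate",
    "run_species_filter",
]


@dataclass
class SpeciesFilterReport:
    """What the cascade removed and the per-taxon statistics afterwards."""

    n_calls_removed_by_intensity: int = 0
    intensity_threshold: float = float("nan")
    call_rate_before: dict[str, float] = field(default_factory=dict)  # per sample id
    call_rate_after: dict[str, float] = field(default_factory=dict)
    excluded_samples: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)
    group_thresholds: dict[str, float] = field(default_factory=dict)  # mean - 2 SD per group
    n_markers_before: int = 0
    n_markers_retained: int = 0
    per_taxon: pd.DataFrame | None = None

    def taxon_table(self, panel: GenotypePanel, n_assayed: int | None = None) -> pd.DataFrame:
        """Per-taxon conversion/validation rates and observed
        heterozygosity on the retained data."""
        n_assayed = n_assayed or panel.n_loci
        rows = []
        for taxon, idx in panel.group_indices().items():
            calls = panel.calls[idx]
            converted = (calls != MISSING).any(axis=0)
            validated = converted & (calls == HET).any(axis=0)
            called = calls != MISSING
            het_obs = float((calls == HET).sum() / called.sum()) if called.any() else float("nan")
            rows.append(
                {
                    "taxon": taxon,
                    "n_samples": int(idx.size),
                    "n_converted": int(converted.sum()),
                    "n_validated": int(validated.sum()),
                    "conversion_rate": converted.sum() / n_assayed,
                    "validation_rate": (validated.sum() / converted.sum()) if converted.any() else float("nan"),
                    "observed_heterozygosity": het_obs,
                }
            )
        self.per_taxon = pd.DataFrame(rows)
        return self.per_taxon


def filter_by_intensity(
    panel: GenotypePanel,
    intensities: IntensityTable,
    threshold: float = 1000.0,
    report: SpeciesFilterReport | None = None,
) -> GenotypePanel:
    """Set calls with summed intensity strictly below ``threshold`` to missing.

    Ties at exactly the threshold are retained.  Every non-missing call
    must have an intensity value.
    """
    vals = intensities.values
    if vals.shape != panel.calls.shape:
        raise ValueError(f"intensity table shape {vals.shape} does not match panel {panel.calls.shape}")
    called = panel.calls != MISSING
    orphan = called & np.isnan(vals)
    if orphan.any():
        i, j = map(int, np.argwhere(orphan)[0])
        raise ValueError(
            f"missing intensity for non-missing call, e.g. sample "
            f"{panel.sample_ids[i]!r} x locus {panel.locus_ids[j]!r}"
        )
    drop = called & (vals < threshold)
    calls = panel.calls.copy()
    calls[drop] = MISSING
    if report is not None:
        report.n_calls_removed_by_intensity = int(drop.sum())
        report.intensity_threshold = threshold
    return GenotypePanel(loci=list(panel.loci), samples=list(panel.samples), calls=calls,
                         color_genotypes=panel.color_genotypes)


def filter_individuals_by_rate(
    panel: GenotypePanel,
    suborder_groups: dict[str, list[str]] | None = None,
    n_sd: float = 2.0,
    report: SpeciesFilterReport | None = None,
) -> GenotypePanel:
    """Drop individuals with call rate below ``mean - n_sd * SD`` of their group.

    The mean and (population) SD are taken within each suborder-level
    group; the rule is applied once, not iterated.  ``suborder_groups``
    maps group labels to sample ids; by default each sample's own group
    label defines its stratum.  Groups of fewer than two samples are
    passed through with a warning (SD undefined).
    """
    rates = panel.sample_call_rates()
    if suborder_groups is None:
        group_rows = panel.group_indices()
    else:
        sidx = {s: i for i, s in enumerate(panel.sample_ids)}
        group_rows = {g: np.array([sidx[s] for s in ids], dtype=np.intp) for g, ids in suborder_groups.items()}

    keep = np.ones(panel.n_samples, dtype=bool)
    if report is not None:
        report.call_rate_before = dict(zip(panel.sample_ids, rates))
    for g, rows in group_rows.items():
        if rows.size < 2:
            warnings.warn(f"group {g!r} has <2 samples; 2-SD exclusion skipped")
            continue
        mu, sd = float(rates[rows].mean()), float(rates[rows].std())
        cut = mu - n_sd * sd
        if report is not None:
            report.group_thresholds[g] = cut
        for i in rows[rates[rows] < cut]:
            keep[i] = False
            if report is not None:
                report.excluded_samples.append(
                    (panel.sample_ids[i], f"call rate {rates[i]:.4f} < {cut:.4f} ({g})")
                )
    return panel.subset(samples=keep)


def filter_markers_by_rate(
    panel: GenotypePanel,
    min_rate: float = 0.9,
    report: SpeciesFilterReport | None = None,
) -> GenotypePanel:
    """Keep markers called in strictly more than ``min_rate`` of samples.

    The boundary is removed: a marker called in exactly 90% of
    individuals does not pass the default threshold.
    """
    rates = panel.locus_call_rates()
    keep = rates > min_rate
    if report is not None:
        report.n_markers_before = panel.n_loci
        report.n_markers_retained = int(keep.sum())
    return panel.subset(loci=keep)


def run_species_filter(
    panel: GenotypePanel,
    intensities: IntensityTable,
    suborder_groups: dict[str, list[str]] | None = None,
    intensity_threshold: float = 1000.0,
    min_marker_rate: float = 0.9,
) -> tuple[GenotypePanel, SpeciesFilterReport]:
    """Full cascade: intensity -> individuals (2 SD) -> markers (>90%)."""
    report = SpeciesFilterReport()
    p = filter_by_intensity(panel, intensities, intensity_threshold, report)
    p = filter_individuals_by_rate(p, suborder_groups, report=report)
    p = filter_markers_by_rate(p, min_marker_rate, report)
    report.call_rate_after = dict(zip(p.sample_ids, p.sample_call_rates()))
    report.taxon_table(p)
    return p, report
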