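"""Haplotypic r-squared, binned LD-decay profiles, and extent of LD.

r² between two loci is computed on *haplotype* frequencies estimated by
expectation-maximization over the double-heterozygote phase ambiguity
(the convention of standard LD-plotting tools), not on genotypic dosage
correlation — the latter is reserved for LD pruning in
:mod:`equipop.structure`.

For a pair of biallelic loci with allele-B frequencies p and q and
estimated B/B-haplotype frequency f_bb,

    D = f_bb - p q,    r² = D² / (p (1-p) q (1-q)).

EM runs at most 50 iterations from linkage-equilibrium product
frequencies and stops when the largest haplotype-frequency change falls
below 1e-8.  When no double heterozygote is present the haplotype
counts are fully determined and EM reduces to direct counting.

The decay profile bins all intra-chromosomal pairs closer than 4 Mb into
50 kb half-open bins ``[start, end)`` and averages r² per bin.  The
extent of LD is where the profile falls below twice the long-range
background (the mean of the 2-4 Mb bins) and never rises above it again
before the background window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel

__all__ = ["LDProfile", "pairwise_r2", "ld_decay_profile", "ld_extent", "em_r2_pairs"]

_EM_MAX_ITER = 50
_EM_TOL = 1e-8


@dataclass
class LDProfile:
    group: str
    bin_width: int
    max_dist: int
    bins: pd.DataFrame  # columns bin_start, bin_end, n_pairs, mean_r2

    def to_frame(self) -> pd.DataFrame:
        return self.bins.copy()


def em_r2_pairs(
    calls: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    min_samples: int = 10,
    return_freqs: bool = False,
):
    """EM haplotypic r² for many locus pairs at once.

    ``calls`` is a samples x loci dosage matrix with -1 missing;
    ``idx_a`` / ``idx_b`` are parallel column-index arrays.  Returns an
    array of r² values with ``NaN`` where a pair is undefined
    (monomorphic locus or fewer than ``min_samples`` jointly-called
    samples).
    """
    idx_a = np.asarray(idx_a, dtype=np.intp)
    idx_b = np.asarray(idx_b, dtype=np.intp)
    ga = calls[:, idx_a]
    gb = calls[:, idx_b]
    ok = (ga != MISSING) & (gb != MISSING)
    nj = ok.sum(axis=0).astype(float)

    # 3x3 joint genotype counts per pair
    cnt = np.empty((3, 3, idx_a.size), dtype=np.float64)
    for a in range(3):
        for b in range(3):
            cnt[a, b] = ((ga == a) & (gb == b) & ok).sum(axis=0)

    two_n = 2.0 * nj
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (cnt[1].sum(axis=0) + 2 * cnt[2].sum(axis=0)) / two_n  # B freq at locus A
        q = (cnt[:, 1].sum(axis=0) + 2 * cnt[:, 2].sum(axis=0)) / two_n

    # determined haplotype counts; c11 double heterozygotes are ambiguous
    k00 = 2 * cnt[0, 0] + cnt[0, 1] + cnt[1, 0]
    k01 = 2 * cnt[0, 2] + cnt[0, 1] + cnt[1, 2]
    k10 = 2 * cnt[2, 0] + cnt[1, 0] + cnt[2, 1]
    k11 = 2 * cnt[2, 2] + cnt[2, 1] + cnt[1, 2]
    c11 = cnt[1, 1]

    with np.errstate(invalid="ignore", divide="ignore"):
        f00 = (1 - p) * (1 - q)
        f01 = (1 - p) * q
        f10 = p * (1 - q)
        f11 = p * q
        for _ in range(_EM_MAX_ITER):
            num = f00 * f11
            den = num + f01 * f10
            w = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)
            n00 = (k00 + c11 * w) / two_n
            n01 = (k01 + c11 * (1 - w)) / two_n
            n10 = (k10 + c11 * (1 - w)) / two_n
            n11 = (k11 + c11 * w) / two_n
            delta = np.nanmax(
                np.abs(np.stack([n00 - f00, n01 - f01, n10 - f10, n11 - f11]))
            ) if idx_a.size else 0.0
            f00, f01, f10, f11 = n00, n01, n10, n11
            if delta < _EM_TOL:
                break
        d = f11 - p * q
        denom = p * (1 - p) * q * (1 - q)
        r2 = np.where(denom > 0, d * d / np.where(denom > 0, denom, 1.0), np.nan)
    r2[(nj < min_samples)] = np.nan
    r2 = np.clip(r2, 0.0, 1.0)
    if return_freqs:
        return r2, np.stack([f00, f01, f10, f11]), p, q
    return r2


def pairwise_r2(
    panel: GenotypePanel,
    locus_a: str | int,
    locus_b: str | int,
    group: str | None = None,
    min_samples: int = 10,
) -> float:
    """EM haplotypic r² for one locus pair (NaN if undefined)."""
    ja = locus_a if isinstance(locus_a, (int, np.integer)) else panel.locus_index(locus_a)
    jb = locus_b if isinstance(locus_b, (int, np.integer)) else panel.locus_index(locus_b)
    if group is None:
        calls = panel.calls
    else:
        calls = panel.calls[panel.group_indices()[group]]
    return float(em_r2_pairs(calls, [ja], [jb], min_samples=min_samples)[0])


def _intra_chromosome_pairs(
    panel: GenotypePanel, max_dist: int, include_x: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All locus-index pairs on a shared chromosome closer than max_dist."""
    positions = panel.positions
    chroms = panel.chromosomes
    auto = panel.autosomal_mask()
    ia, ib, dist = [], [], []
    for c in pd.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        if not include_x and not auto[idx[0]]:
            continue
        idx = idx[np.argsort(positions[idx])]
        pos = positions[idx]
        for a_i in range(idx.size):
            upper = np.searchsorted(pos, pos[a_i] + max_dist, side="left")
            for b_i in range(a_i + 1, upper):
                ia.append(idx[a_i])
                ib.append(idx[b_i])
                dist.append(pos[b_i] - pos[a_i])
    return (
        np.array(ia, dtype=np.intp),
        np.array(ib, dtype=np.intp),
        np.array(dist, dtype=np.int64),
    )


def ld_decay_profile(
    panel: GenotypePanel,
    group: str | None = None,
    max_dist: int = 4_000_000,
    bin_width: int = 50_000,
    min_group_size: int = 18,
    min_samples: int = 10,
    include_x: bool = False,
    chunk: int = 20_000,
) -> LDProfile:
    """Binned mean haplotypic r² versus physical distance.

    All intra-chromosomal pairs closer than ``max_dist`` are assigned to
    half-open ``bin_width`` bins by inter-SNP distance; undefined pairs
    are dropped.  ``group=None`` pools all samples.  Empty bins are
    reported with ``n_pairs`` 0 and ``mean_r2`` NaN.
    """
    if group is None:
        calls = panel.calls
        label = "all"
    else:
        rows = panel.group_indices().get(group)
        if rows is None:
            raise KeyError(f"group {group!r} not in panel")
        if rows.size < min_group_size:
            raise ValueError(
                f"group {group!r} has {rows.size} samples; minimum is {min_group_size}"
            )
        calls = panel.calls[rows]
        label = group

    ia, ib, dist = _intra_chromosome_pairs(panel, max_dist, include_x)
    r2 = np.empty(ia.size)
    for s in range(0, ia.size, chunk):
        e = s + chunk
        r2[s:e] = em_r2_pairs(calls, ia[s:e], ib[s:e], min_samples=min_samples)

    edges = np.arange(0, max_dist + bin_width, bin_width)
    which = np.digitize(dist, edges) - 1  # [start, end)
    rows = []
    for b in range(len(edges) - 1):
        sel = (which == b) & ~np.isnan(r2)
        rows.append(
            {
                "bin_start": int(edges[b]),
                "bin_end": int(edges[b + 1]),
                "n_pairs": int(sel.sum()),
                "mean_r2": float(r2[sel].mean()) if sel.any() else float("nan"),
            }
        )
    return LDProfile(group=label, bin_width=bin_width, max_dist=max_dist, bins=pd.DataFrame(rows))


def ld_extent(
    profile: LDProfile, background_window: tuple[int, int] = (2_000_000, 4_000_000)
) -> tuple[int, float]:
    """Extent of LD: persistence until falling below two-fold background.

    Background r² is the mean of populated bin means inside
    ``background_window``.  The extent is the left edge of the first bin
    whose mean r² is below twice background and that is never re-exceeded
    by any later populated bin before the background window (guards
    against noisy dips).  A profile that is below the threshold from the
    start returns 0; one that never falls below it returns the window
    start, with a warning.

    Returns ``(extent_bp, background_r2)``.
    """
    bins = profile.bins
    lo, hi = background_window
    in_bg = (bins["bin_start"] >= lo) & (bins["bin_end"] <= hi) & bins["mean_r2"].notna()
    if not in_bg.any():
        raise ValueError("no populated bins inside the background window")
    background = float(bins.loc[in_bg, "mean_r2"].mean())
    threshold = 2.0 * background

    fore = bins[(bins["bin_end"] <= lo) & bins["mean_r2"].notna()].reset_index(drop=True)
    means = fore["mean_r2"].to_numpy()
    below = means < threshold
    # suffix scan: bin qualifies if it and every later foreground bin are below
    stays_below = np.logical_and.accumulate(below[::-1])[::-1]
    hits = np.flatnonzero(stays_below)
    if hits.size == 0:
        warnings.warn("profile never falls below two-fold background before the window; extent set to window start")
        return int(lo), background
    extent = int(fore.loc[hits[0], "bin_start"])
    if extent == 0 and bool(below.all()):
        warnings.warn("profile entirely below two-fold background; extent 0")
    return extent, background
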