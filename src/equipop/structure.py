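"""Pairwise IBS distance, metric MDS, LD pruning and inbreeding.

The genetic distance between two individuals is

    D = 1 - (IBS2 + 0.5 * IBS1) / N

where IBS2 / IBS1 count jointly-called loci sharing two / one allele
identical by state and N is the number of jointly-called loci.  With
dosage coding this is ``mean(|g_i - g_j|) / 2``.

Inbreeding uses the method-of-moments estimator

    F = (O_hom - E_hom) / (L - E_hom)

with the expected homozygous count from reference allele frequencies
(panel-wide by default, optionally within-group) over the sample's
non-missing pruned autosomal loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import HET, MISSING, GenotypePanel

__all__ = [
    "DistanceMatrix",
    "MDSResult",
    "InbreedingResult",
    "ibs_distance_matrix",
    "classical_mds",
    "ld_prune",
    "inbreeding_coefficients",
]


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray  # (n, n) symmetric, NaN where undefined
    n_joint: np.ndarray  # (n, n) jointly-called locus counts

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class MDSResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing

    def to_frame(self) -> pd.DataFrame:
        cols = {f"dim{j+1}": self.coordinates[:, j] for j in range(self.coordinates.shape[1])}
        return pd.DataFrame({"sample_id": self.sample_ids, **cols})


@dataclass
class InbreedingResult:
    sample_ids: list[str]
    f: np.ndarray
    n_loci_used: np.ndarray
    flagged: np.ndarray  # True where too few usable loci

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "F": self.f, "n_loci": self.n_loci_used, "flagged": self.flagged}
        )


def ibs_distance_matrix(panel: GenotypePanel, min_joint_loci: int = 1) -> DistanceMatrix:
    """All-pairs IBS genetic distance D = 1 - (IBS2 + 0.5 IBS1)/N.

    Pairs with fewer than ``min_joint_loci`` jointly-called loci get
    ``NaN``.  The diagonal is exactly 0.
    """
    if panel.n_samples < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    g = panel.calls.astype(np.int16)
    called = g != MISSING
    n = panel.n_samples
    d = np.zeros((n, n))
    joint_counts = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        joint = called[i] & called[i + 1:]
        diff = np.abs(g[i] - g[i + 1:]) * joint
        nj = joint.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(nj > 0, diff.sum(axis=1) / (2.0 * nj), np.nan)
        d[i, i + 1:] = d[i + 1:, i] = row
        joint_counts[i, i + 1:] = joint_counts[i + 1:, i] = nj
    np.fill_diagonal(joint_counts, called.sum(axis=1))
    low = (joint_counts < min_joint_loci) & ~np.eye(n, dtype=bool)
    if low.any():
        warnings.warn(f"{int(low.sum() // 2)} pairs below min_joint_loci={min_joint_loci}; set to NaN")
        d[low] = np.nan
    return DistanceMatrix(sample_ids=panel.sample_ids, values=d, n_joint=joint_counts)


def classical_mds(dist: DistanceMatrix, k: int = 6) -> MDSResult:
    """Metric (classical/Torgerson) MDS of a distance matrix.

    Double-centers ``-0.5 * D**2``, eigendecomposes, and returns the top
    ``k`` positive-eigenvalue coordinates scaled by the root eigenvalue.
    Dimensions with non-positive eigenvalues are dropped with a warning.
    Sign convention: the first nonzero loading of each axis is positive.
    """
    d = dist.values
    if np.isnan(d).any():
        raise ValueError("distance matrix has undefined entries; cannot embed")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int((evals > 1e-10).sum())
    if n_pos < k:
        warnings.warn(f"only {n_pos} positive eigenvalues; returning {n_pos} dimensions instead of {k}")
    k_eff = min(k, n_pos)
    coords = evecs[:, :k_eff] * np.sqrt(evals[:k_eff])
    for col in range(k_eff):
        nz = np.flatnonzero(np.abs(coords[:, col]) > 1e-12)
        if nz.size and coords[nz[0], col] < 0:
            coords[:, col] = -coords[:, col]
    coords = coords - coords.mean(axis=0, keepdims=True)
    return MDSResult(sample_ids=dist.sample_ids, coordinates=coords, eigenvalues=evals)


def pairwise_dosage_r2(calls: np.ndarray, j1: int, j2: int) -> float:
    """Squared Pearson correlation of two dosage columns over jointly
    non-missing samples (the genotypic correlation used for pruning)."""
    a, b = calls[:, j1], calls[:, j2]
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    x = a[ok].astype(float)
    y = b[ok].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return float(r * r)


def _window_r2_matrix(calls: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Pairwise-complete squared dosage correlation for a column window.

    Uses mask/moment matrix products so the window is one linear-algebra
    pass rather than a per-pair loop; pairs with fewer than 2 joint
    samples or a constant column get r² = 0.
    """
    g = calls[:, cols].astype(np.float64)
    m = (g != MISSING).astype(np.float64)
    x = np.where(m > 0, g, 0.0)
    x2 = x * x
    n = m.T @ m
    sx = x.T @ m  # sum of x over jointly-called samples, per (j, k)
    sy = sx.T
    sxy = x.T @ x
    sxx = x2.T @ m
    syy = sxx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        r2 = cov * cov / (varx * vary)
    r2[(n < 2) | (varx <= 0) | (vary <= 0)] = 0.0
    return r2


def ld_prune(
    panel: GenotypePanel,
    window: int = 100,
    step: int = 25,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Sliding-window LD pruning on genotypic correlation.

    Within each ``window``-SNP window (slid by ``step`` SNPs along each
    chromosome in map order), one SNP of every pair with squared dosage
    correlation above ``r2_max`` is greedily removed: the member with the
    lower panel-wide MAF goes (ties: the later map position).  Returns a
    boolean keep-mask over the panel's loci.
    """
    calls = panel.calls
    called = calls != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, np.where(called, calls, 0).sum(axis=0) / (2.0 * n_called), 0.0)
    maf = np.minimum(p, 1 - p)
    positions = panel.positions

    keep = np.ones(panel.n_loci, dtype=bool)
    chroms = panel.chromosomes
    order = np.lexsort((panel.positions, chroms.astype(str)))
    for c in pd.unique(chroms[order]):
        idx = order[chroms[order] == c]
        start = 0
        while True:
            win = idx[start : start + window]
            if win.size >= 2:
                r2 = _window_r2_matrix(calls, win)
                for a_i in range(win.size):
                    ja = win[a_i]
                    if not keep[ja]:
                        continue
                    for b_i in range(a_i + 1, win.size):
                        jb = win[b_i]
                        if not keep[jb] or not keep[ja]:
                            continue
                        if r2[a_i, b_i] > r2_max:
                            if maf[ja] < maf[jb]:
                                keep[ja] = False
                            elif maf[jb] < maf[ja]:
                                keep[jb] = False
                            else:  # tie: drop the later map position
                                keep[max(ja, jb, key=lambda j: positions[j])] = False
            if start + window >= idx.size:
                break
            start += step
    return keep


def inbreeding_coefficients(
    panel: GenotypePanel,
    pruned: np.ndarray | None = None,
    frequencies: str = "panel",
    min_loci: int = 100,
) -> InbreedingResult:
    """Method-of-moments F per sample from excess homozygosity.

    ``pruned`` is a boolean mask or index array of loci to use (e.g.
    from :func:`ld_prune`); X-chromosome loci are always excluded.
    ``frequencies`` selects the reference allele-frequency pool:
    ``"panel"`` (default) or ``"group"`` (each sample's own breed).
    The expected heterozygosity term carries the small-sample
    ``2n/(2n-1)`` correction (with n the per-locus non-missing count in
    the frequency pool), so F is unbiased near zero even at modest
    sample sizes.  Samples with fewer than ``min_loci`` usable loci are
    flagged.
    """
    if frequencies not in ("panel", "group"):
        raise ValueError("frequencies must be 'panel' or 'group'")
    mask = panel.autosomal_mask()
    if pruned is not None:
        pruned = np.asarray(pruned)
        sel = pruned if pruned.dtype == bool else np.isin(np.arange(panel.n_loci), pruned)
        mask &= sel
    cols = np.flatnonzero(mask)
    calls = panel.calls[:, cols]
    called = calls != MISSING

    def freq_pool(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sub = calls[rows]
        ok = sub != MISSING
        nc = ok.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(nc > 0, np.where(ok, sub, 0).sum(axis=0) / (2.0 * nc), np.nan)
        return p, 2 * nc  # frequency and allele count per locus

    if frequencies == "panel":
        pools = {None: freq_pool(np.arange(panel.n_samples))}
        pool_of = lambda i: pools[None]
    else:
        gi = panel.group_indices()
        pools = {g: freq_pool(rows) for g, rows in gi.items()}
        pool_of = lambda i: pools[panel.samples[i].group]

    n = panel.n_samples
    f = np.full(n, np.nan)
    used = np.zeros(n, dtype=np.int64)
    flagged = np.zeros(n, dtype=bool)
    for i in range(n):
        p, n_alleles = pool_of(i)
        ok = called[i] & ~np.isnan(p) & (p > 0) & (p < 1)
        li = int(ok.sum())
        used[i] = li
        if li < min_loci:
            flagged[i] = True
        if li == 0:
            continue
        na = n_alleles[ok].astype(float)
        het_exp = 2.0 * p[ok] * (1.0 - p[ok]) * na / (na - 1.0)
        o_hom = float((calls[i, ok] != HET).sum())
        e_hom = float((1.0 - het_exp).sum())
        denom = li - e_hom
        f[i] = (o_hom - e_hom) / denom if denom != 0 else np.nan
    return InbreedingResult(sample_ids=panel.sample_ids, f=f, n_loci_used=used, flagged=flagged)
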