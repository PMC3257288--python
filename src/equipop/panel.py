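"""Core genotype-panel data model and linkage-format (PED/MAP) text I/O.

A :class:`GenotypePanel` is the universal currency of the toolkit: a
samples x loci matrix of biallelic genotype calls together with a locus
map and per-sample metadata.  Calls are stored as a compact ``int8``
matrix using the dosage-style coding

    ``0`` = homozygous for allele A, ``1`` = heterozygous,
    ``2`` = homozygous for allele B, ``-1`` = missing.

Allele A / allele B orientation is fixed at panel construction (first
allele seen in the input file, or the simulator's reference/alternate
assignment) and never re-oriented afterwards; minor/major status is
recomputed per analysis because the minor allele can differ between
subpopulations.

Coordinates are 1-based inclusive base pairs, following the MAP-file
convention.  Half-missing calls (one allele ``0``) are treated as fully
missing on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "HOM_A",
    "HET",
    "HOM_B",
    "Locus",
    "Sample",
    "GenotypePanel",
    "IntensityTable",
    "PanelFormatError",
    "read_pedmap",
    "write_pedmap",
    "to_dosage",
]

MISSING: int = -1
HOM_A: int = 0
HET: int = 1
HOM_B: int = 2

#: chromosome labels treated as the X chromosome
X_LABELS = frozenset({"X", "x", "chrX", "39"})


class PanelFormatError(ValueError):
    """Raised for malformed PED/MAP input or inconsistent panel pieces."""


@dataclass(frozen=True)
class Locus:
    """A biallelic marker with map position and fixed allele orientation."""

    id: str
    chromosome: str
    position: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"locus {self.id}: position must be >= 1, got {self.position}")
        if self.allele_a == self.allele_b:
            raise ValueError(f"locus {self.id}: alleles must differ, got {self.allele_a!r} twice")

    @property
    def is_x(self) -> bool:
        return self.chromosome in X_LABELS


@dataclass(frozen=True)
class Sample:
    """A genotyped individual with breed/species label and pedigree links.

    ``sire_id`` / ``dam_id`` of ``None`` mean unknown ("0" in PED files).
    ``replicate_of`` marks duplicate genotyping controls.
    """

    id: str
    group: str = "0"
    sex: str = "unknown"  # {male, female, unknown}
    sire_id: str | None = None
    dam_id: str | None = None
    replicate_of: str | None = None


@dataclass
class GenotypePanel:
    """Samples x loci biallelic call matrix with metadata.

    Parameters
    ----------
    loci
        Ordered loci; ids must be unique.
    samples
        Ordered samples; ids must be unique.
    calls
        ``int8`` array of shape ``(n_samples, n_loci)`` over
        ``{-1, 0, 1, 2}``.
    """

    loci: list[Locus]
    samples: list[Sample]
    calls: np.ndarray
    color_genotypes: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise PanelFormatError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.calls, (MISSING, HOM_A, HET, HOM_B))
        if bad.any():
            raise PanelFormatError(f"invalid genotype codes present: {np.unique(self.calls[bad])}")
        ids = [l.id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise PanelFormatError("duplicate locus ids in panel")
        sids = [s.id for s in self.samples]
        if len(set(sids)) != len(sids):
            raise PanelFormatError("duplicate sample ids in panel")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    @property
    def locus_ids(self) -> list[str]:
        return [l.id for l in self.loci]

    @property
    def positions(self) -> np.ndarray:
        return np.array([l.position for l in self.loci], dtype=np.int64)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([l.chromosome for l in self.loci], dtype=object)

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.samples], dtype=object)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in panel") from None

    def locus_index(self, locus_id: str) -> int:
        try:
            return self.locus_ids.index(locus_id)
        except ValueError:
            raise KeyError(f"locus {locus_id!r} not in panel") from None

    def autosomal_mask(self) -> np.ndarray:
        """Boolean mask over loci, True for non-X loci."""
        return np.array([not l.is_x for l in self.loci], dtype=bool)

    # -- derived statistics ---------------------------------------------
    def sample_call_rates(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def locus_call_rates(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    # -- subsetting ------------------------------------------------------
    def subset(
        self,
        samples: Sequence[int] | np.ndarray | None = None,
        loci: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypePanel":
        """Return a new panel restricted to the given sample/locus indices.

        Index arrays may be integer positions or boolean masks.
        """
        s_idx = _as_index(samples, self.n_samples)
        l_idx = _as_index(loci, self.n_loci)
        cg = None
        if self.color_genotypes is not None:
            kept = {self.samples[i].id for i in s_idx}
            cg = {k: v for k, v in self.color_genotypes.items() if k in kept}
        return GenotypePanel(
            loci=[self.loci[i] for i in l_idx],
            samples=[self.samples[i] for i in s_idx],
            calls=self.calls[np.ix_(s_idx, l_idx)],
            color_genotypes=cg,
        )

    def group_indices(self) -> dict[str, np.ndarray]:
        """Map group label -> integer sample indices, in first-seen order."""
        out: dict[str, list[int]] = {}
        for i, s in enumerate(self.samples):
            out.setdefault(s.group, []).append(i)
        return {g: np.array(ix, dtype=np.intp) for g, ix in out.items()}

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "group": [s.group for s in self.samples],
                "sex": [s.sex for s in self.samples],
                "sire_id": [s.sire_id for s in self.samples],
                "dam_id": [s.dam_id for s in self.samples],
            }
        )


def _as_index(idx, n: int) -> np.ndarray:
    if idx is None:
        return np.arange(n, dtype=np.intp)
    idx = np.asarray(idx)
    if idx.dtype == bool:
        if idx.shape != (n,):
            raise PanelFormatError(f"boolean index of shape {idx.shape} for axis of length {n}")
        return np.flatnonzero(idx)
    return idx.astype(np.intp)


@dataclass
class IntensityTable:
    """Summed raw fluorescence intensity per (sample, locus) call.

    Stored dense, aligned to a companion panel: shape
    ``(n_samples, n_loci)``; ``NaN`` marks pairs without an intensity
    measurement.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if ((self.values < 0) & ~np.isnan(self.values)).any():
            raise ValueError("intensities must be non-negative")

    @classmethod
    def from_long(
        cls, panel: GenotypePanel, records: Iterable[tuple[str, str, float]]
    ) -> "IntensityTable":
        """Build from (sample_id, locus_id, summed_intensity) triples."""
        vals = np.full((panel.n_samples, panel.n_loci), np.nan)
        srow = {s: i for i, s in enumerate(panel.sample_ids)}
        lcol = {l: j for j, l in enumerate(panel.locus_ids)}
        for sid, lid, v in records:
            vals[srow[sid], lcol[lid]] = float(v)
        return cls(vals)

    def to_long(self, panel: GenotypePanel) -> pd.DataFrame:
        rows, cols = np.nonzero(~np.isnan(self.values))
        return pd.DataFrame(
            {
                "sample_id": [panel.sample_ids[i] for i in rows],
                "locus_id": [panel.locus_ids[j] for j in cols],
                "summed_intensity": self.values[rows, cols],
            }
        )


# ---------------------------------------------------------------------------
# PED/MAP text I/O
# ---------------------------------------------------------------------------

_SEX_IN = {"1": "male", "2": "female"}
_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}


def read_pedmap(
    ped_path: str | Path,
    map_path: str | Path,
    alleles: Mapping[str, tuple[str, str]] | None = None,
) -> GenotypePanel:
    """Read a linkage-format PED/MAP file pair into a panel.

    PED columns: family, individual id, sire id, dam id, sex, phenotype,
    then two allele characters per locus.  ``0 0`` (and any half-missing
    call) becomes MISSING.  Allele A is the first non-zero allele seen at
    each locus, scanning samples in file order; pass ``alleles`` (locus
    id -> (allele_a, allele_b)) to pin the orientation instead, making
    the read the exact inverse of :func:`write_pedmap`.

    Raises
    ------
    PanelFormatError
        If a PED line's genotype-column count disagrees with the MAP, or
        a locus shows more than two distinct alleles.
    """
    map_path, ped_path = Path(map_path), Path(ped_path)
    map_rows: list[tuple[str, str, int]] = []
    for ln, line in enumerate(map_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise PanelFormatError(f"{map_path}:{ln}: expected 4 MAP columns, got {len(parts)}")
        chrom, lid, _gd, pos = parts[:4]
        map_rows.append((chrom, lid, int(pos)))
    n_loci = len(map_rows)

    samples: list[Sample] = []
    raw_alleles: list[list[tuple[str, str]]] = []
    for ln, line in enumerate(ped_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_loci:
            raise PanelFormatError(
                f"{ped_path}:{ln}: expected {6 + 2 * n_loci} columns "
                f"({n_loci} loci), got {len(parts)}"
            )
        fam, iid, sire, dam, sex, _pheno = parts[:6]
        samples.append(
            Sample(
                id=iid,
                group=fam,
                sex=_SEX_IN.get(sex, "unknown"),
                sire_id=None if sire == "0" else sire,
                dam_id=None if dam == "0" else dam,
            )
        )
        raw_alleles.append(list(zip(parts[6::2], parts[7::2])))

    # establish allele orientation per locus, then encode
    loci: list[Locus] = []
    calls = np.full((len(samples), n_loci), MISSING, dtype=np.int8)
    for j, (chrom, lid, pos) in enumerate(map_rows):
        seen: list[str] = []
        for row in raw_alleles:
            for a in row[j]:
                if a != "0" and a not in seen:
                    seen.append(a)
        if len(seen) > 2:
            raise PanelFormatError(f"locus {lid}: more than two alleles seen: {sorted(seen)}")
        if alleles is not None and lid in alleles:
            a_allele, b_allele = alleles[lid]
            stray = set(seen) - {a_allele, b_allele}
            if stray:
                raise PanelFormatError(
                    f"locus {lid}: alleles {sorted(stray)} not in declared pair "
                    f"({a_allele}, {b_allele})"
                )
        else:
            a_allele = seen[0] if seen else "A"
            b_allele = seen[1] if len(seen) > 1 else ("B" if a_allele != "B" else "C")
        loci.append(Locus(id=lid, chromosome=chrom, position=pos, allele_a=a_allele, allele_b=b_allele))
        for i, row in enumerate(raw_alleles):
            a1, a2 = row[j]
            if a1 == "0" or a2 == "0":  # half-missing treated as missing
                continue
            calls[i, j] = (a1 == b_allele) + (a2 == b_allele)
    return GenotypePanel(loci=loci, samples=samples, calls=calls)


def write_pedmap(panel: GenotypePanel, ped_path: str | Path, map_path: str | Path) -> None:
    """Write a panel as linkage-format PED/MAP text; MISSING becomes ``0 0``."""
    with open(map_path, "w") as fh:
        for l in panel.loci:
            fh.write(f"{l.chromosome}\t{l.id}\t0\t{l.position}\n")
    with open(ped_path, "w") as fh:
        for i, s in enumerate(panel.samples):
            fields = [
                s.group,
                s.id,
                s.sire_id or "0",
                s.dam_id or "0",
                _SEX_OUT.get(s.sex, "0"),
                "0",
            ]
            for j, l in enumerate(panel.loci):
                g = panel.calls[i, j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == HOM_A:
                    fields += [l.allele_a, l.allele_a]
                elif g == HET:
                    fields += [l.allele_a, l.allele_b]
                else:
                    fields += [l.allele_b, l.allele_b]
            fh.write(" ".join(fields) + "\n")


def to_dosage(panel: GenotypePanel) -> np.ndarray:
    """Allele-B dosage matrix: AA=0, AB=1, BB=2, missing=-1 (``int8`` copy).

    The coding uses the panel's fixed allele A/B orientation, not
    minor/major status.
    """
    return panel.calls.copy()
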