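"""Shared fixtures: hand-built panels and PED/MAP writers."""

from __future__ import annotations

import numpy as np
import pytest

from equipop.panel import GenotypePanel, Locus, Sample


def build_panel(
    calls,
    groups=None,
    positions=None,
    chromosomes=None,
    sample_ids=None,
):
    """Construct a panel from a call matrix with minimal boilerplate."""
    calls = np.asarray(calls, dtype=np.int8)
    n_s, n_l = calls.shape
    groups = groups or ["g1"] * n_s
    positions = positions if positions is not None else [1000 * (j + 1) for j in range(n_l)]
    chromosomes = chromosomes or ["1"] * n_l
    sample_ids = sample_ids or [f"s{i}" for i in range(n_s)]
    loci = [
        Locus(id=f"L{j}", chromosome=str(chromosomes[j]), position=int(positions[j]),
              allele_a="A", allele_b="B")
        for j in range(n_l)
    ]
    samples = [Sample(id=sample_ids[i], group=groups[i]) for i in range(n_s)]
    return GenotypePanel(loci=loci, samples=samples, calls=calls)


@pytest.fixture
def panel_factory():
    return build_panel


@pytest.fixture
def tiny_pedmap(tmp_path):
    """A 2-sample, 3-locus PED/MAP pair with one missing call."""
    ped = tmp_path / "tiny.ped"
    map_ = tmp_path / "tiny.map"
    map_.write_text("1 rs1 0 1000\n1 rs2 0 2000\n2 rs3 0 500\n")
    ped.write_text(
        "fam1 ind1 0 0 1 0 A A A G 0 0\n"
        "fam1 ind2 0 0 2 0 A T G G C C\n"
    )
    return ped, map_
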