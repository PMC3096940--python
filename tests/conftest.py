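"""Shared fixtures: tiny hand-built datasets and one synthetic study."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from haplostat.seqio import (
    PopulationMap,
    SequenceAlignment,
    collapse_haplotypes,
)
from haplostat.simulate import paper_mimic_fixture


def make_popmap(assignment: dict[str, tuple[str, str]], coords=None) -> PopulationMap:
    """Build a PopulationMap from {sample: (population, group)}."""
    coords = coords or {}
    rows = []
    pops = list(dict.fromkeys(pop for pop, _ in assignment.values()))
    for sid, (pop, group) in assignment.items():
        lat, lon = coords.get(pop, (float(pops.index(pop)), float(pops.index(pop)) * 2.0))
        rows.append(
            {"sample_id": sid, "population": pop, "group": group, "lat_dd": lat, "lon_dd": lon}
        )
    return PopulationMap(pd.DataFrame(rows))


def make_alignment(seqs: dict[str, str], locus: str = "toy") -> SequenceAlignment:
    return SequenceAlignment(
        locus_name=locus, sample_ids=tuple(seqs), sequences=tuple(seqs.values())
    )


def random_alignment(rng: np.random.Generator, n: int, L: int, with_gaps: bool = False):
    """Random alignment over ACGT (optionally with gap/N columns)."""
    alphabet = list("ACGT")
    mat = rng.choice(alphabet, size=(n, L))
    if with_gaps:
        for j in rng.choice(L, size=max(1, L // 10), replace=False):
            mat[rng.integers(n), j] = rng.choice(["-", "N"])
    seqs = {f"s{i}": "".join(row) for i, row in enumerate(mat)}
    return make_alignment(seqs)


@pytest.fixture(scope="session")
def mimic():
    """One synthetic study-design dataset with its collapsed tables."""
    result = paper_mimic_fixture(seed=3)
    tables = {
        name: collapse_haplotypes(aln, result.popmap)
        for name, aln in result.alignments.items()
    }
    return result, tables
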