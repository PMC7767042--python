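"""Shared fixtures: printed genotype tables and small matrix builders."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from immunediv.core_io import GenotypeMatrix, SnpRecord

#: Genotype distributions of the three selection-candidate SNPs among the
#: three taxa, as printed in the study (counts of individuals with
#: ref/ref, ref/alt, alt/alt genotypes).
TABLE2_COUNTS: dict[str, dict[str, tuple[int, int, int]]] = {
    "MAP2K4-164": {
        "coluzzii": (164, 1, 0),
        "bamako": (13, 74, 87),
        "savanna": (58, 27, 1),
    },
    "Raf-784": {
        "coluzzii": (22, 75, 55),
        "bamako": (128, 3, 0),
        "savanna": (82, 0, 0),
    },
    "Raf-851": {
        "coluzzii": (12, 78, 60),
        "bamako": (2, 20, 106),
        "savanna": (69, 2, 3),
    },
}


def matrix_from_counts(
    counts: dict[str, tuple[int, int, int]], name: str = "snp"
) -> GenotypeMatrix:
    """Single-locus matrix realizing the given per-taxon genotype counts."""
    individuals, taxon_of, calls = [], {}, []
    for taxon, (n0, n1, n2) in counts.items():
        for g, n in zip((0, 1, 2), (n0, n1, n2)):
            for i in range(n):
                ind = f"{taxon}_{g}_{i}"
                individuals.append(ind)
                taxon_of[ind] = taxon
                calls.append(g)
    return GenotypeMatrix(
        individuals=individuals,
        taxon_of=taxon_of,
        loci=[SnpRecord(chromosome="un", position=1, ref_allele="A", alt_allele="T", name=name)],
        calls=np.array(calls, dtype=np.int8).reshape(-1, 1),
    )


def two_locus_matrix(ga: list[int], gb: list[int], taxon: str = "pop") -> GenotypeMatrix:
    """Two-locus single-taxon matrix from per-individual dosage lists."""
    inds = [f"{taxon}_{i}" for i in range(len(ga))]
    return GenotypeMatrix(
        individuals=inds,
        taxon_of={i: taxon for i in inds},
        loci=[
            SnpRecord(chromosome="un", position=1, ref_allele="A", alt_allele="T", name="A"),
            SnpRecord(chromosome="un", position=2, ref_allele="C", alt_allele="G", name="B"),
        ],
        calls=np.column_stack([ga, gb]).astype(np.int8),
    )


@pytest.fixture(scope="session")
def table2_matrices() -> dict[str, GenotypeMatrix]:
    return {name: matrix_from_counts(c, name) for name, c in TABLE2_COUNTS.items()}
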