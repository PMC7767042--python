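"""Codon-usage-based classification of SNPs as potentially functional.

A coding SNP is *potentially functional* if it is non-synonymous, or if it
is synonymous but exchanges codons whose usage frequencies differ at least
2-fold (such substitutions can alter translation kinetics and mRNA
folding).  The 2-fold threshold is inclusive and symmetric in ref/alt.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from Bio.Data import CodonTable

from .core_io import FunctionalClass, SnpRecord

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
#: codon -> one-letter amino acid, with '*' for stop codons
GENETIC_CODE: dict[str, str] = {**_STANDARD.forward_table}
for _stop in _STANDARD.stop_codons:
    GENETIC_CODE[_stop] = "*"

ALL_CODONS: tuple[str, ...] = tuple("".join(c) for c in product("TCAG", repeat=3))

#: classes retained by the potentially-functional filter
FUNCTIONAL_CLASSES = frozenset(
    {FunctionalClass.NONSYNONYMOUS, FunctionalClass.SYNONYMOUS_FUNCTIONAL}
)


def _normalize(codon: str) -> str:
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"not a DNA codon: {codon!r}")
    return codon


@dataclass(frozen=True)
class CodonUsageTable:
    """Relative usage frequency for each of the 64 codons.

    Frequencies need not be normalized per amino acid: the classification
    criterion only takes ratios between synonymous codons.
    """

    frequencies: Mapping[str, float]

    def __post_init__(self) -> None:
        freqs = {_normalize(c): float(f) for c, f in self.frequencies.items()}
        missing = set(ALL_CODONS) - set(freqs)
        if missing:
            raise ValueError(f"codon usage table missing {len(missing)} codons: {sorted(missing)[:4]}")
        nonpos = [c for c, f in freqs.items() if not f > 0]
        if nonpos:
            raise ValueError(f"codon usage frequencies must be > 0; bad: {nonpos[:4]}")
        object.__setattr__(self, "frequencies", freqs)

    def __getitem__(self, codon: str) -> float:
        return self.frequencies[_normalize(codon)]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CodonUsageTable":
        """Read a two-column TSV: codon, relative frequency."""
        freqs: dict[str, float] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0].lower() == "codon":
                    continue
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 'codon<TAB>frequency'")
                freqs[parts[0]] = float(parts[1])
        return cls(freqs)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("codon\tfrequency\n")
            for c in ALL_CODONS:
                fh.write(f"{c}\t{self.frequencies[c]:.6g}\n")


def synthetic_usage_table(seed: int = 0) -> CodonUsageTable:
    """A synthetic codon-usage table for tests and demos.

    Frequencies are log-uniform over roughly a 10-fold range so that both
    >= 2-fold and < 2-fold synonymous pairs occur.  This is NOT a claim
    about any real genome's codon usage.
    """
    rng = np.random.default_rng(seed)
    return CodonUsageTable(
        {c: float(10.0 ** rng.uniform(-1.5, -0.5)) for c in ALL_CODONS}
    )


def classify_snp(
    ref_codon: str,
    alt_codon: str,
    codon_position: int,
    usage: CodonUsageTable,
    *,
    fold_threshold: float = 2.0,
) -> FunctionalClass:
    """Classify a coding SNP from its ref/alt codon pair.

    * amino acids differ (stop gain/loss included) -> NONSYNONYMOUS
    * synonymous with usage ratio >= ``fold_threshold`` -> SYNONYMOUS_FUNCTIONAL
    * synonymous otherwise -> SYNONYMOUS_NEUTRAL

    ``codon_position`` is 1..3 and must be the single position at which the
    codons differ.
    """
    ref, alt = _normalize(ref_codon), _normalize(alt_codon)
    if not 1 <= codon_position <= 3:
        raise ValueError(f"codon_position must be in 1..3, got {codon_position}")
    diffs = [i for i in range(3) if ref[i] != alt[i]]
    if diffs != [codon_position - 1]:
        raise ValueError(
            f"codons {ref}->{alt} must differ exactly at position {codon_position}; "
            f"differ at {[i + 1 for i in diffs]}"
        )
    aa_ref, aa_alt = GENETIC_CODE[ref], GENETIC_CODE[alt]
    if aa_ref != aa_alt or "*" in (aa_ref, aa_alt):
        return FunctionalClass.NONSYNONYMOUS
    f_ref, f_alt = usage[ref], usage[alt]
    ratio = max(f_ref / f_alt, f_alt / f_ref)
    if ratio >= fold_threshold:
        return FunctionalClass.SYNONYMOUS_FUNCTIONAL
    return FunctionalClass.SYNONYMOUS_NEUTRAL


def classify_snps(
    snps: Sequence[SnpRecord], usage: CodonUsageTable
) -> list[SnpRecord]:
    """Return SNPs with ``functional_class`` filled in from codon context.

    SNPs without codon context keep their existing class (NONCODING or
    UNKNOWN as supplied).
    """
    from dataclasses import replace

    out = []
    for snp in snps:
        if snp.ref_codon and snp.alt_codon and snp.codon_position:
            cls = classify_snp(snp.ref_codon, snp.alt_codon, snp.codon_position, usage)
            out.append(replace(snp, functional_class=cls))
        else:
            out.append(snp)
    return out


def potentially_functional_mask(
    snps: Sequence[SnpRecord], usage: CodonUsageTable | None = None
) -> np.ndarray:
    """Boolean mask of SNPs that pass the potentially-functional filter."""
    if usage is not None:
        snps = classify_snps(snps, usage)
    return np.array([s.functional_class in FUNCTIONAL_CLASSES for s in snps], dtype=bool)


def filter_potentially_functional(
    snps: Sequence[SnpRecord], usage: CodonUsageTable | None = None
) -> list[SnpRecord]:
    """Keep NONSYNONYMOUS and SYNONYMOUS_FUNCTIONAL SNPs, preserving order.

    If ``usage`` is given, SNPs carrying codon context are (re)classified
    first; otherwise the stored ``functional_class`` is trusted.
    """
    if usage is not None:
        snps = classify_snps(snps, usage)
    return [s for s in snps if s.functional_class in FUNCTIONAL_CLASSES]
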