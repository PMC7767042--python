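"""Data model and readers/writers for genotypes, annotations and results.

Conventions
-----------
* Genotypes are stored as alternate-allele dosages ``{0, 1, 2}`` with
  :data:`MISSING` (``-1``) as a distinguished sentinel, never a dosage.
* SNP positions follow the VCF convention (1-based); gene and inversion
  intervals follow the BED convention (0-based, half-open).  The single
  place where the two conventions meet is :func:`assign_snps_to_genes`.
* Taxon labels are free strings.  The trio ``coluzzii / bamako / savanna``
  is only a convention of the bundled synthetic configurations.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger("immunediv")

#: Sentinel for a missing genotype call.
MISSING: int = -1


class FunctionalClass(enum.Enum):
    """Functional category of a SNP with respect to the coding sequence."""

    NONSYNONYMOUS = "nonsynonymous"
    SYNONYMOUS_FUNCTIONAL = "synonymous_functional"
    SYNONYMOUS_NEUTRAL = "synonymous_neutral"
    NONCODING = "noncoding"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP.

    ``position`` is 1-based (VCF).  ``gene_ids`` holds every gene whose
    interval contains the SNP (overlapping genes are all recorded; per-gene
    statistics then count the SNP once per gene).  Codon context
    (``ref_codon``/``alt_codon``/``codon_position``) is optional and is
    supplied by the caller, not derived from a transcript model.
    """

    chromosome: str
    position: int
    ref_allele: str | None = None
    alt_allele: str | None = None
    name: str | None = None
    gene_ids: tuple[str, ...] = ()
    functional_class: FunctionalClass = FunctionalClass.UNKNOWN
    ref_codon: str | None = None
    alt_codon: str | None = None
    codon_position: int | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"SNP position must be >= 1, got {self.position}")
        if (
            self.ref_allele is not None
            and self.alt_allele is not None
            and self.ref_allele == self.alt_allele
        ):
            raise ValueError(
                f"ref and alt allele identical ({self.ref_allele}) at "
                f"{self.chromosome}:{self.position}"
            )

    @property
    def gene_id(self) -> str | None:
        """First assigned gene id, or ``None``."""
        return self.gene_ids[0] if self.gene_ids else None

    @property
    def label(self) -> str:
        return self.name or f"{self.chromosome}:{self.position}"


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval in BED convention (0-based, half-open)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    immune: bool = False

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )


@dataclass(frozen=True)
class InversionRegion:
    """A paracentric inversion interval in BED convention."""

    name: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"inversion {self.name}: start ({self.start}) must be < end ({self.end})"
            )


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci dosage matrix with taxon labels.

    ``calls`` has shape ``(n_individuals, n_loci)``; entries are 0/1/2
    alternate-allele dosages or :data:`MISSING`.
    """

    individuals: list[str]
    taxon_of: dict[str, str]
    loci: list[SnpRecord]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        if self.calls.shape != (len(self.individuals), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls contain values outside {0,1,2,MISSING}")
        missing_taxon = [i for i in self.individuals if i not in self.taxon_of]
        if missing_taxon:
            raise ValueError(f"individuals without taxon label: {missing_taxon[:5]}")

    # -- convenience ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def taxa(self) -> list[str]:
        """Taxon labels in order of first appearance."""
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(self.taxon_of[ind], None)
        return list(seen)

    def taxon_rows(self, taxon: str) -> np.ndarray:
        """Row indices of the individuals belonging to ``taxon``."""
        rows = np.array(
            [i for i, ind in enumerate(self.individuals) if self.taxon_of[ind] == taxon],
            dtype=np.intp,
        )
        if rows.size == 0:
            raise KeyError(f"unknown taxon {taxon!r}")
        return rows

    def taxon_calls(self, taxon: str, loci: Sequence[int] | None = None) -> np.ndarray:
        sub = self.calls[self.taxon_rows(taxon)]
        return sub if loci is None else sub[:, np.asarray(loci, dtype=np.intp)]

    def subset_loci(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=np.intp)
        return GenotypeMatrix(
            individuals=list(self.individuals),
            taxon_of=dict(self.taxon_of),
            loci=[self.loci[i] for i in idx],
            calls=self.calls[:, idx].copy(),
        )

    def locus_index(self, label: str) -> int:
        for i, s in enumerate(self.loci):
            if s.label == label or s.name == label:
                return i
        raise KeyError(f"no locus labelled {label!r}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_taxon_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping individual id to taxon label."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            if lineno == 1 and parts[0].lower() in ("individual", "sample", "id"):
                continue
            mapping[parts[0]] = parts[1]
    return mapping


def read_vcf(
    path: str | Path,
    taxon_table_path: str | Path,
    *,
    split_multiallelic: bool = False,
) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF v4.x file.

    Dosages are computed from the GT field; missing genotypes become
    :data:`MISSING`.  Multi-allelic rows are skipped with a warning unless
    ``split_multiallelic`` is set, in which case each alternate allele
    becomes its own biallelic row (all other alternates treated as
    reference).
    """
    from cyvcf2 import VCF

    taxon_of = read_taxon_table(taxon_table_path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - htslib error path
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in taxon_of]
    if absent:
        raise ValueError(
            f"VCF samples missing from taxon table: {absent[:5]}"
            + ("..." if len(absent) > 5 else "")
        )

    loci: list[SnpRecord] = []
    rows: list[np.ndarray] = []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    dosage_of_gt_type = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for variant in vcf:
        alts = variant.ALT
        if len(alts) != 1:
            if not split_multiallelic:
                logger.warning(
                    "skipping multi-allelic site %s:%d (ALT=%s)",
                    variant.CHROM,
                    variant.POS,
                    ",".join(alts),
                )
                continue
            # split: one biallelic row per alternate allele
            gts = np.array(variant.genotypes, dtype=object)
            for ai, alt in enumerate(alts, start=1):
                row = np.empty(len(samples), dtype=np.int8)
                for si, gt in enumerate(gts):
                    a, b = gt[0], gt[1]
                    if a < 0 or b < 0:
                        row[si] = MISSING
                    else:
                        row[si] = int(a == ai) + int(b == ai)
                loci.append(
                    SnpRecord(
                        chromosome=variant.CHROM,
                        position=variant.POS,
                        ref_allele=variant.REF,
                        alt_allele=alt,
                        name=variant.ID,
                    )
                )
                rows.append(row)
            continue
        loci.append(
            SnpRecord(
                chromosome=variant.CHROM,
                position=variant.POS,
                ref_allele=variant.REF,
                alt_allele=alts[0],
                name=variant.ID,
            )
        )
        rows.append(dosage_of_gt_type[variant.gt_types])

    calls = (
        np.vstack(rows).T if rows else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        individuals=samples,
        taxon_of={s: taxon_of[s] for s in samples},
        loci=loci,
        calls=calls,
    )


def read_genotype_table(
    path: str | Path,
    taxon_table_path: str | Path,
    loci: Sequence[SnpRecord] | None = None,
) -> GenotypeMatrix:
    """Read an individuals x loci dosage table (TSV, '.' for missing).

    The header row names the loci; the first column holds individual ids.
    If ``loci`` is not supplied, placeholder :class:`SnpRecord` objects are
    created with sequential positions on an unnamed chromosome.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    taxon_of = read_taxon_table(taxon_table_path)
    absent = [s for s in df.index if s not in taxon_of]
    if absent:
        raise ValueError(f"individuals missing from taxon table: {absent[:5]}")
    calls = df.replace(".", str(MISSING)).astype(np.int8).to_numpy()
    if loci is None:
        loci = [
            SnpRecord(chromosome="un", position=i + 1, name=str(col))
            for i, col in enumerate(df.columns)
        ]
    elif len(loci) != df.shape[1]:
        raise ValueError("loci list does not match table width")
    return GenotypeMatrix(
        individuals=list(df.index),
        taxon_of={s: taxon_of[s] for s in df.index},
        loci=list(loci),
        calls=calls,
    )


def _read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: BED4 requires >= 4 columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            out.append((chrom, start, end, name))
    return out


def read_annotations(
    genes_bed: str | Path,
    inversions_bed: str | Path | None = None,
    immune_list_path: str | Path | None = None,
) -> tuple[list[GeneAnnotation], list[InversionRegion]]:
    """Read gene and inversion BED4 files plus an immune-gene id list."""
    immune: set[str] = set()
    if immune_list_path is not None:
        with open(immune_list_path) as fh:
            immune = {line.strip() for line in fh if line.strip()}
    genes = [
        GeneAnnotation(gene_id=name, chromosome=c, start=s, end=e, immune=name in immune)
        for c, s, e, name in _read_bed(genes_bed)
    ]
    known = {g.gene_id for g in genes}
    unknown = immune - known
    if unknown:
        logger.warning(
            "immune list names %d gene id(s) absent from the gene BED: %s",
            len(unknown),
            sorted(unknown)[:5],
        )
    inversions: list[InversionRegion] = []
    if inversions_bed is not None:
        inversions = [
            InversionRegion(name=name, chromosome=c, start=s, end=e)
            for c, s, e, name in _read_bed(inversions_bed)
        ]
    return genes, inversions


def assign_snps_to_genes(
    snps: Sequence[SnpRecord], genes: Sequence[GeneAnnotation]
) -> list[SnpRecord]:
    """Assign each SNP to every gene whose interval contains it.

    A 1-based SNP position ``p`` lies inside the 0-based half-open gene
    interval ``[start, end)`` iff ``start < p <= end``.  SNPs in no gene get
    an empty ``gene_ids``; SNPs in overlapping genes get all of them.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chromosome, IntervalTree()).addi(g.start, g.end, g.gene_id)
    out: list[SnpRecord] = []
    for snp in snps:
        tree = trees.get(snp.chromosome)
        hits = sorted(iv.data for iv in tree[snp.position - 1]) if tree else []
        out.append(replace(snp, gene_ids=tuple(hits)))
    return out


def gene_locus_map(loci: Sequence[SnpRecord]) -> dict[str, list[int]]:
    """Map gene id -> indices of the loci assigned to it."""
    out: dict[str, list[int]] = {}
    for i, snp in enumerate(loci):
        for g in snp.gene_ids:
            out.setdefault(g, []).append(i)
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write one TSV per analysis stage ('.' for missing values).

    Column order and row order are taken from the DataFrames as given, so
    a deterministic pipeline produces byte-identical files on rerun.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, na_rep=".")
        paths.append(p)
    return paths


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as a minimal VCF v4.2 (GT only)."""
    gt_of_dosage = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.individuals)
            + "\n"
        )
        order = sorted(
            range(matrix.n_loci),
            key=lambda i: (matrix.loci[i].chromosome, matrix.loci[i].position),
        )
        for j in order:
            snp = matrix.loci[j]
            gts = "\t".join(gt_of_dosage[int(d)] for d in matrix.calls[:, j])
            fh.write(
                f"{snp.chromosome}\t{snp.position}\t{snp.name or '.'}\t"
                f"{snp.ref_allele or 'A'}\t{snp.alt_allele or 'T'}\t.\t.\t.\tGT\t{gts}\n"
            )


def write_taxon_table(taxon_of: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("individual\ttaxon\n")
        for ind, tax in taxon_of.items():
            fh.write(f"{ind}\t{tax}\n")


def write_bed(
    intervals: Iterable[GeneAnnotation | InversionRegion], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = getattr(iv, "gene_id", None) or getattr(iv, "name")
            fh.write(f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{name}\n")


def write_immune_list(gene_ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in gene_ids:
            fh.write(f"{g}\n")
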