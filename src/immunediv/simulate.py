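"""Synthetic-data generators with the statistical structure the analysis assumes.

The divergence model is Balding-Nichols: per locus an ancestral frequency
p is drawn, then each taxon's allele frequency from
``Beta(p(1-F)/F, (1-p)(1-F)/F)`` and genotypes as ``Binomial(2, freq)``
(Hardy-Weinberg within taxon).  The generator's ``F`` is the estimand of
the Weir-Cockerham theta estimator, so parameter-recovery tests close the
loop between simulation and inference.

The study-mimic bundle emulates a three-taxon mosquito dataset: a genome
of ~12,519 genes of which 231 form an "immune" subset generated at
elevated divergence (F = 0.13 vs a 0.035 background), WGS-scale sample
sizes (12/11/13 diploids), five paracentric inversions on chromosome arm
2R, and optional within-gene LD blocks.  Inversion coordinates and gene
placement are stylized, not real genome annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .core_io import (
    MISSING,
    FunctionalClass,
    GeneAnnotation,
    GenotypeMatrix,
    InversionRegion,
    SnpRecord,
    assign_snps_to_genes,
    write_bed,
    write_immune_list,
    write_taxon_table,
    write_vcf,
)

logger = logging.getLogger("immunediv")

__all__ = [
    "StudyMimicConfig",
    "StudyMimicBundle",
    "gen_balding_nichols",
    "gen_ld_block",
    "gen_annotation",
    "gen_study_mimic",
    "max_feasible_r2",
]

#: stylized 2R paracentric inversion intervals (synthetic; loosely inspired
#: by the cytogenetic map, NOT real breakpoint coordinates)
DEFAULT_INVERSIONS: tuple[InversionRegion, ...] = (
    InversionRegion("2Rj", "2R", 3_200_000, 15_200_000),
    InversionRegion("2Rb", "2R", 19_000_000, 26_700_000),
    InversionRegion("2Rc", "2R", 26_800_000, 31_400_000),
    InversionRegion("2Rd", "2R", 32_000_000, 42_000_000),
    InversionRegion("2Ru", "2R", 43_000_000, 46_500_000),
)

DEFAULT_CHROM_LENGTHS: Mapping[str, int] = {
    "2L": 49_364_325,
    "2R": 61_545_105,
    "3L": 41_963_435,
    "3R": 53_200_684,
    "X": 24_393_108,
}


def _uniform_ancestral(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.uniform(0.05, 0.95, size=n)


# ---------------------------------------------------------------------------
# Balding-Nichols genotypes
# ---------------------------------------------------------------------------

def gen_balding_nichols(
    n_per_taxon: Sequence[int],
    locus_F_values: Sequence[float] | float,
    n_loci: int | None = None,
    ancestral_freq_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int = 0,
    taxa: Sequence[str] | None = None,
    loci: Sequence[SnpRecord] | None = None,
) -> GenotypeMatrix:
    """Simulate Hardy-Weinberg genotypes under the Balding-Nichols model.

    ``locus_F_values`` is a scalar (with ``n_loci``) or a per-locus array
    of divergence parameters in (0, 1).  Monomorphic draws (all taxon
    frequencies rounding to fixation) are retained; downstream estimators
    must handle them.
    """
    rng = np.random.default_rng(seed)
    if np.isscalar(locus_F_values):
        if n_loci is None:
            raise ValueError("n_loci required with a scalar F")
        F = np.full(n_loci, float(locus_F_values))
    else:
        F = np.asarray(locus_F_values, dtype=float)
        if n_loci is not None and n_loci != F.size:
            raise ValueError("n_loci disagrees with locus_F_values length")
    if np.any((F <= 0) | (F >= 1)):
        raise ValueError("all F values must lie in (0, 1)")
    L = F.size

    sampler = ancestral_freq_sampler or _uniform_ancestral
    p_anc = np.asarray(sampler(rng, L), dtype=float)

    taxa = list(taxa) if taxa is not None else [f"taxon{i+1}" for i in range(len(n_per_taxon))]
    individuals: list[str] = []
    taxon_of: dict[str, str] = {}
    blocks = []
    alpha = p_anc * (1 - F) / F
    beta = (1 - p_anc) * (1 - F) / F
    for t, n in zip(taxa, n_per_taxon):
        freqs = rng.beta(alpha, beta)
        blocks.append(rng.binomial(2, freqs, size=(n, L)).astype(np.int8))
        for j in range(n):
            ind = f"{t}_{j:03d}"
            individuals.append(ind)
            taxon_of[ind] = t
    calls = np.vstack(blocks)
    if loci is None:
        loci = [
            SnpRecord(chromosome="un", position=i + 1, ref_allele="A", alt_allele="T", name=f"snp{i}")
            for i in range(L)
        ]
    return GenotypeMatrix(
        individuals=individuals, taxon_of=taxon_of, loci=list(loci), calls=calls
    )


# ---------------------------------------------------------------------------
# LD blocks
# ---------------------------------------------------------------------------

def max_feasible_r2(p_a: float, p_b: float) -> float:
    """Largest r^2 attainable (with positive D) at the given allele freqs."""
    d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    return d_max**2 / (p_a * (1 - p_a) * p_b * (1 - p_b))


def _haplotype_freqs(p_a: float, p_b: float, r2: float) -> np.ndarray:
    """Four haplotype frequencies [AB, Ab, aB, ab] achieving target r^2 (D > 0)."""
    feasible = max_feasible_r2(p_a, p_b)
    if r2 > feasible + 1e-12:
        raise ValueError(
            f"target r2={r2:.4g} infeasible at freqs ({p_a:.3g}, {p_b:.3g}); "
            f"feasible maximum is {feasible:.4g}"
        )
    d = np.sqrt(r2 * p_a * (1 - p_a) * p_b * (1 - p_b))
    return np.array(
        [
            p_a * p_b + d,
            p_a * (1 - p_b) - d,
            (1 - p_a) * p_b - d,
            (1 - p_a) * (1 - p_b) + d,
        ]
    ).clip(0, 1)


def gen_ld_block(
    allele_freqs: Sequence[float],
    block_r2_target: float,
    n_individuals: int,
    seed: int = 0,
) -> np.ndarray:
    """Unphased genotype columns for a block of loci in mutual LD.

    Haplotypes are drawn as a Markov chain along the block: consecutive
    locus pairs attain ``block_r2_target`` exactly in expectation (positive
    D), so LD between non-adjacent loci decays multiplicatively.  Each
    individual is the union of two independent haplotype draws.  Raises if
    the target is infeasible at the requested allele frequencies, naming
    the feasible maximum.
    """
    if not 0 <= block_r2_target <= 1:
        raise ValueError("r2 target must be in [0, 1]")
    freqs = [float(p) for p in allele_freqs]
    if len(freqs) < 2:
        raise ValueError("an LD block needs at least 2 loci")
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_individuals
    haps = np.empty((n_hap, len(freqs)), dtype=np.int8)
    haps[:, 0] = rng.random(n_hap) < freqs[0]
    for j in range(1, len(freqs)):
        pa, pb = freqs[j - 1], freqs[j]
        hap4 = _haplotype_freqs(pa, pb, block_r2_target)
        # conditional P(B allele | allele at previous locus)
        p_b_given_a = hap4[0] / pa if pa > 0 else 0.0
        p_b_given_not_a = hap4[2] / (1 - pa) if pa < 1 else 0.0
        u = rng.random(n_hap)
        prev = haps[:, j - 1] == 1
        haps[:, j] = np.where(prev, u < p_b_given_a, u < p_b_given_not_a)
    return (haps[0::2] + haps[1::2]).astype(np.int8)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def gen_annotation(
    n_genes: int,
    chromosome_lengths: Mapping[str, int] = DEFAULT_CHROM_LENGTHS,
    inversions: Sequence[InversionRegion] = DEFAULT_INVERSIONS,
    immune_count: int = 231,
    immune_placement_bias: float = 0.0,
    gene_length: int = 2_000,
    near_distance: int = 0,
    seed: int = 0,
) -> tuple[list[GeneAnnotation], list[InversionRegion], list[str]]:
    """Place non-overlapping genes and pick an immune subset.

    Genes occupy disjoint slots allocated to chromosomes proportionally to
    length.  With ``immune_placement_bias = 0`` the immune subset is a
    uniform draw; with bias ``b`` each immune pick comes from the genes
    overlapping an inversion (expanded by ``near_distance``) with
    probability ``b`` while that pool lasts, so ``b = 1`` puts every
    immune gene near an inversion when capacity allows.
    """
    if immune_count > n_genes:
        raise ValueError("immune_count exceeds n_genes")
    rng = np.random.default_rng(seed)
    chroms = list(chromosome_lengths)
    lengths = np.array([chromosome_lengths[c] for c in chroms], dtype=float)
    spacing = 2 * gene_length
    capacity = (lengths // spacing).astype(int)
    if capacity.sum() < n_genes:
        raise ValueError(
            f"cannot pack {n_genes} genes of length {gene_length} into the genome"
        )
    # proportional allocation, remainders to the largest chromosomes
    share = lengths / lengths.sum() * n_genes
    counts = np.floor(share).astype(int)
    for i in np.argsort(-(share - counts)):
        if counts.sum() >= n_genes:
            break
        counts[i] += 1
    counts = np.minimum(counts, capacity)
    while counts.sum() < n_genes:  # spill over if a chromosome saturated
        for i in np.argsort(-(capacity - counts)):
            if counts[i] < capacity[i]:
                counts[i] += 1
                break

    genes: list[GeneAnnotation] = []
    gid = 0
    for ci, chrom in enumerate(chroms):
        slots = rng.choice(capacity[ci], size=counts[ci], replace=False)
        for slot in np.sort(slots):
            start = int(slot) * spacing
            genes.append(
                GeneAnnotation(
                    gene_id=f"gene{gid:05d}",
                    chromosome=chrom,
                    start=start,
                    end=start + gene_length,
                )
            )
            gid += 1

    def hits(g: GeneAnnotation) -> bool:
        return any(
            inv.chromosome == g.chromosome
            and g.start < inv.end + near_distance
            and inv.start - near_distance < g.end
            for inv in inversions
        )

    hit_ids = [g.gene_id for g in genes if hits(g)]
    all_ids = [g.gene_id for g in genes]
    remaining_hit = set(hit_ids)
    remaining_all = set(all_ids)
    immune_ids: list[str] = []
    for _ in range(immune_count):
        if remaining_hit and rng.random() < immune_placement_bias:
            pick = sorted(remaining_hit)[rng.integers(len(remaining_hit))]
        else:
            pick = sorted(remaining_all)[rng.integers(len(remaining_all))]
        immune_ids.append(pick)
        remaining_all.discard(pick)
        remaining_hit.discard(pick)
    immune_set = set(immune_ids)
    genes = [replace(g, immune=g.gene_id in immune_set) for g in genes]
    return genes, list(inversions), sorted(immune_ids)


# ---------------------------------------------------------------------------
# Study-mimic bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyMimicConfig:
    """Conditions of the emulated field study.

    WGS-scale defaults: three sympatric taxa of 12/11/13 diploids, a
    12,519-gene genome with a 231-gene immune subset diverged at
    F = 0.13 against an F = 0.035 background.  ``genotyping_scale()``
    switches to the SNP-panel sample sizes (194/167/87).
    """

    taxa: tuple[str, ...] = ("coluzzii", "bamako", "savanna")
    sample_sizes: tuple[int, ...] = (12, 11, 13)
    n_genes: int = 12_519
    immune_count: int = 231
    snps_per_gene: int = 1
    fst_immune: float = 0.13
    fst_background: float = 0.035
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    ld_block_r2: float | None = None
    chromosome_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    inversions: tuple[InversionRegion, ...] = DEFAULT_INVERSIONS
    immune_placement_bias: float = 0.0
    gene_length: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sample_sizes):
            raise ValueError("taxa and sample_sizes lengths differ")
        if any(n < 2 for n in self.sample_sizes):
            raise ValueError("sample sizes must be >= 2")
        for F in (self.fst_immune, self.fst_background):
            if not 0 < F < 1:
                raise ValueError("F levels must be in (0, 1)")
        if self.immune_count > self.n_genes:
            raise ValueError("immune_count exceeds n_genes")
        if self.snps_per_gene < 1:
            raise ValueError("snps_per_gene must be >= 1")

    @classmethod
    def genotyping_scale(cls, **kw) -> "StudyMimicConfig":
        return cls(sample_sizes=(194, 167, 87), **kw)


@dataclass
class StudyMimicBundle:
    matrix: GenotypeMatrix
    genes: list[GeneAnnotation]
    inversions: list[InversionRegion]
    immune_gene_ids: list[str]
    config: StudyMimicConfig
    paths: dict[str, Path] | None = None


def gen_study_mimic(
    config: StudyMimicConfig | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> StudyMimicBundle:
    """Generate the full synthetic dataset bundle.

    Immune-gene SNPs are drawn at the immune F level, the rest at the
    background level.  With ``snps_per_gene > 1`` and ``ld_block_r2`` set,
    within-gene SNPs are coupled into an LD block per taxon (capped at the
    feasible r^2 for the drawn frequencies).  If ``out_dir`` is given the
    bundle is also written as VCF + taxon TSV + BED4 + immune list.
    """
    config = config or StudyMimicConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    s_ann, s_geno, s_ld = (int(x) for x in rng.integers(0, 2**31, size=3))

    genes, inversions, immune_ids = gen_annotation(
        n_genes=config.n_genes,
        chromosome_lengths=config.chromosome_lengths,
        inversions=config.inversions,
        immune_count=config.immune_count,
        immune_placement_bias=config.immune_placement_bias,
        gene_length=config.gene_length,
        seed=s_ann,
    )
    immune_set = set(immune_ids)

    # SNP coordinates: evenly spread inside each gene
    loci: list[SnpRecord] = []
    F = np.empty(config.n_genes * config.snps_per_gene)
    k = config.snps_per_gene
    for gi, g in enumerate(genes):
        step = max((g.end - g.start) // (k + 1), 1)
        for j in range(k):
            pos = min(g.start + (j + 1) * step, g.end)  # 1-based pos in (start, end]
            loci.append(
                SnpRecord(
                    chromosome=g.chromosome,
                    position=pos,
                    ref_allele="A",
                    alt_allele="T",
                    name=f"{g.gene_id}-{j}",
                    functional_class=FunctionalClass.NONSYNONYMOUS,
                )
            )
            F[gi * k + j] = (
                config.fst_immune if g.gene_id in immune_set else config.fst_background
            )

    def sampler(r: np.random.Generator, n: int) -> np.ndarray:
        return r.uniform(config.ancestral_low, config.ancestral_high, size=n)

    matrix = gen_balding_nichols(
        n_per_taxon=config.sample_sizes,
        locus_F_values=F,
        ancestral_freq_sampler=sampler,
        seed=s_geno,
        taxa=config.taxa,
        loci=loci,
    )

    # Optional within-gene LD: a tight block shares one haplotype
    # background, so all of a gene's SNPs get the same taxon frequency
    # (one Balding-Nichols draw per gene and taxon) and haplotypes are
    # coupled at the target r^2, which is always feasible at equal freqs.
    if config.ld_block_r2 is not None and k > 1:
        ld_rng = np.random.default_rng(s_ld)
        for gi, g in enumerate(genes):
            F_g = (
                config.fst_immune if g.gene_id in immune_set else config.fst_background
            )
            p_anc = ld_rng.uniform(config.ancestral_low, config.ancestral_high)
            cols = slice(gi * k, (gi + 1) * k)
            row0 = 0
            for t, n in zip(config.taxa, config.sample_sizes):
                f = float(ld_rng.beta(p_anc * (1 - F_g) / F_g, (1 - p_anc) * (1 - F_g) / F_g))
                if 0 < f < 1:
                    matrix.calls[row0 : row0 + n, cols] = gen_ld_block(
                        [f] * k, config.ld_block_r2, n,
                        seed=int(ld_rng.integers(2**31)),
                    )
                row0 += n

    matrix.loci = assign_snps_to_genes(matrix.loci, genes)

    paths = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out_dir / "genotypes.vcf",
            "taxa": out_dir / "taxa.tsv",
            "genes": out_dir / "genes.bed",
            "inversions": out_dir / "inversions.bed",
            "immune": out_dir / "immune_genes.txt",
        }
        write_vcf(matrix, paths["vcf"])
        write_taxon_table(matrix.taxon_of, paths["taxa"])
        write_bed(genes, paths["genes"])
        write_bed(inversions, paths["inversions"])
        write_immune_list(immune_ids, paths["immune"])

    return StudyMimicBundle(
        matrix=matrix,
        genes=genes,
        inversions=inversions,
        immune_gene_ids=immune_ids,
        config=config,
        paths=paths,
    )
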