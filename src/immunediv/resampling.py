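"""Gene-set resampling tests and the inversion-overlap permutation test.

Genes (not SNPs) are the resampling unit: redrawing whole genes preserves
within-gene linkage when a gene carries several SNPs.  Sampled null sets
are drawn without replacement within a replicate and independently across
replicates.  Empirical p-values use the add-one convention
``p = (1 + #{null >= observed}) / (B + 1)`` and can therefore never be 0.

Each test also supports ``exhaustive=True``, which enumerates every
equal-sized subset of the full gene pool (the observed set included) and
reports the exact fraction of subsets with a statistic >= the observed
one.  This exact mode is what the sampled p-value converges to.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import GeneAnnotation, GenotypeMatrix, InversionRegion, gene_locus_map
from .popstats import wc_components, wc_fst_set

__all__ = [
    "ResamplingResult",
    "geneset_fst_test",
    "geneset_snpcount_test",
    "inversion_overlap_test",
]

_MAX_EXHAUSTIVE = 500_000


@dataclass(frozen=True)
class ResamplingResult:
    observed: float
    null_values: np.ndarray
    p_value: float
    B: int
    seed: int | None
    exhaustive: bool = False

    @property
    def null_mean(self) -> float:
        return float(self.null_values.mean())

    @property
    def null_sd(self) -> float:
        return float(self.null_values.std(ddof=1)) if self.null_values.size > 1 else float("nan")

    @property
    def null_sem(self) -> float:
        """Standard error of the null mean, SD / sqrt(B)."""
        return self.null_sd / math.sqrt(self.B)


def _empirical_p(observed: float, null_values: np.ndarray) -> float:
    B = null_values.size
    return (1 + int((null_values >= observed).sum())) / (B + 1)


def _filter_exclusions(
    genes: Sequence[GeneAnnotation],
    exclusion_regions: Sequence[InversionRegion | GeneAnnotation] | None,
) -> list[GeneAnnotation]:
    """Drop genes overlapping any exclusion region (e.g. speciation islands)."""
    if not exclusion_regions:
        return list(genes)
    kept = []
    for g in genes:
        hit = any(
            r.chromosome == g.chromosome and g.start < r.end and r.start < g.end
            for r in exclusion_regions
        )
        if not hit:
            kept.append(g)
    return kept


def _resample(
    observed: float,
    pool_stats: np.ndarray | None,
    stat_of_subset,
    pool_size: int,
    k: int,
    B: int,
    seed: int | None,
    exhaustive: bool,
    observed_subset: Sequence[int] | None = None,
) -> ResamplingResult:
    """Shared resampling core.

    ``stat_of_subset(indices)`` evaluates the statistic on a subset of pool
    indices.  In exhaustive mode all C(pool_size, k) subsets are
    enumerated and p is the exact upper-tail fraction; in sampled mode B
    subsets are drawn and the add-one p is returned.
    """
    if exhaustive:
        n_subsets = math.comb(pool_size, k)
        if n_subsets > _MAX_EXHAUSTIVE:
            raise ValueError(
                f"exhaustive enumeration of C({pool_size},{k}) = {n_subsets} subsets refused"
            )
        null = np.array(
            [stat_of_subset(list(sub)) for sub in itertools.combinations(range(pool_size), k)]
        )
        p = float((null >= observed).mean())
        return ResamplingResult(
            observed=observed, null_values=null, p_value=p, B=n_subsets, seed=None, exhaustive=True
        )
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    for b in range(B):
        sub = rng.choice(pool_size, size=k, replace=False)
        null[b] = stat_of_subset(sub)
    return ResamplingResult(
        observed=observed,
        null_values=null,
        p_value=_empirical_p(observed, null),
        B=B,
        seed=seed,
    )


def geneset_fst_test(
    matrix: GenotypeMatrix,
    taxa_pair: Sequence[str],
    genes: Sequence[GeneAnnotation],
    immune_gene_ids: Sequence[str],
    B: int = 1000,
    seed: int | None = 0,
    *,
    exclusion_regions: Sequence[InversionRegion | GeneAnnotation] | None = None,
    exhaustive: bool = False,
) -> ResamplingResult:
    """Is set F_ST of the immune genes higher than of random gene sets?

    Observed statistic: ratio-of-sums Weir-Cockerham theta over all SNPs in
    immune genes for the given taxa contrast.  Null: theta of a random
    equal-sized gene set from the non-immune pool (without replacement).
    Genes overlapping ``exclusion_regions`` are removed from both the
    immune set and the pool before anything else.
    """
    genes = _filter_exclusions(genes, exclusion_regions)
    immune = [g for g in genes if g.gene_id in set(immune_gene_ids)]
    if not immune:
        raise ValueError("immune gene set is empty after exclusions")
    gene_map = gene_locus_map(matrix.loci)

    # per-locus W&C components, computed once
    a, b, c = wc_components(matrix, list(taxa_pair))
    denom = a + b + c
    usable = ~np.isnan(denom) & (denom != 0)
    a = np.where(usable, a, 0.0)
    denom = np.where(usable, denom, 0.0)
    per_gene_a = {}
    per_gene_d = {}
    for g in genes:
        idx = gene_map.get(g.gene_id, [])
        per_gene_a[g.gene_id] = a[idx].sum() if idx else 0.0
        per_gene_d[g.gene_id] = denom[idx].sum() if idx else 0.0

    def set_theta(gene_ids: Sequence[str]) -> float:
        sa = sum(per_gene_a[g] for g in gene_ids)
        sd = sum(per_gene_d[g] for g in gene_ids)
        return sa / sd if sd != 0 else float("nan")

    observed = set_theta([g.gene_id for g in immune])
    if exhaustive:
        pool = [g.gene_id for g in genes]
    else:
        pool = [g.gene_id for g in genes if g.gene_id not in set(immune_gene_ids)]
    pool_arr = np.array(pool, dtype=object)

    def stat(sub_idx) -> float:
        return set_theta(pool_arr[np.asarray(sub_idx)])

    return _resample(
        observed, None, stat, len(pool), len(immune), B, seed, exhaustive
    )


def geneset_snpcount_test(
    snps_or_matrix,
    genes: Sequence[GeneAnnotation],
    immune_gene_ids: Sequence[str],
    B: int = 1000,
    seed: int | None = 0,
    *,
    exclusion_regions: Sequence[InversionRegion | GeneAnnotation] | None = None,
    exhaustive: bool = False,
) -> ResamplingResult:
    """Does the immune gene set carry more SNPs than random gene sets?

    Statistic: total number of SNP-to-gene assignments within the set.
    Null replicates and p-value conventions are the same as in
    :func:`geneset_fst_test`; the result's ``null_sem`` reports SD/sqrt(B).
    """
    loci = snps_or_matrix.loci if isinstance(snps_or_matrix, GenotypeMatrix) else snps_or_matrix
    genes = _filter_exclusions(genes, exclusion_regions)
    immune_set = set(immune_gene_ids)
    immune = [g for g in genes if g.gene_id in immune_set]
    if not immune:
        raise ValueError("immune gene set is empty after exclusions")
    gene_map = gene_locus_map(loci)
    count_of = {g.gene_id: len(gene_map.get(g.gene_id, [])) for g in genes}

    observed = float(sum(count_of[g.gene_id] for g in immune))
    if exhaustive:
        pool = [g.gene_id for g in genes]
    else:
        pool = [g.gene_id for g in genes if g.gene_id not in immune_set]
    counts = np.array([count_of[g] for g in pool], dtype=float)

    def stat(sub_idx) -> float:
        return float(counts[np.asarray(sub_idx)].sum())

    return _resample(observed, None, stat, len(pool), len(immune), B, seed, exhaustive)


def inversion_overlap_test(
    genes: Sequence[GeneAnnotation],
    immune_gene_ids: Sequence[str],
    inversions: Sequence[InversionRegion],
    near_distance: int = 1_000_000,
    B: int = 1000,
    seed: int | None = 0,
    *,
    chromosome: str | None = None,
    exhaustive: bool = False,
) -> ResamplingResult:
    """Are immune genes enriched near or within inversions?

    A gene *hits* if its interval overlaps an inversion expanded by
    ``near_distance`` on each side (i.e. it lies within the inversion or
    within that distance of a breakpoint).  Observed = number of immune
    genes hitting; null sets are drawn from ALL genes (the immune genes
    included), matching a positional permutation of gene labels.
    ``chromosome`` restricts both the immune set and the pool to one
    chromosome arm.
    """
    if not inversions:
        raise ValueError("no inversions supplied")
    genes = list(genes)
    if chromosome is not None:
        genes = [g for g in genes if g.chromosome == chromosome]
    immune_set = set(immune_gene_ids)
    immune = [g for g in genes if g.gene_id in immune_set]
    if not immune:
        raise ValueError("immune gene set is empty")

    def hits(g: GeneAnnotation) -> bool:
        return any(
            inv.chromosome == g.chromosome
            and g.start < inv.end + near_distance
            and inv.start - near_distance < g.end
            for inv in inversions
        )

    hit_flags = np.array([hits(g) for g in genes], dtype=float)
    observed = float(sum(hits(g) for g in immune))

    def stat(sub_idx) -> float:
        return float(hit_flags[np.asarray(sub_idx)].sum())

    return _resample(observed, None, stat, len(genes), len(immune), B, seed, exhaustive)
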