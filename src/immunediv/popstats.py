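"""Allele frequencies, heterozygosity, association tests and Weir-Cockerham F_ST.

The F_ST estimator is the Weir & Cockerham (1984) variance-component
estimator theta-hat for diploid data: per locus the among-population (a),
among-individual-within-population (b) and within-individual (c) components
are computed from per-population sample sizes, allele frequencies and
observed heterozygote proportions, and theta = a / (a + b + c).  Multilocus
values use the ratio-of-sums ("weighted") convention, sum(a) / sum(a+b+c),
which matches the weighted F_ST reported by VCFtools.

Missing data are handled per locus by complete-case analysis within each
population.  Negative per-locus theta estimates are reported as computed,
never clamped; the ratio-of-sums set estimator lets them average properly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import MISSING, GenotypeMatrix

__all__ = [
    "FstResult",
    "SetFstResult",
    "AssociationResult",
    "HetResult",
    "allele_frequency",
    "observed_heterozygosity",
    "genotype_association",
    "bonferroni_adjust",
    "wc_components",
    "wc_fst_locus",
    "wc_fst_set",
    "chisq_power",
]


@dataclass(frozen=True)
class FstResult:
    locus: int
    a: float
    b: float
    c: float
    theta: float
    n_pops: int
    sample_sizes: tuple[int, ...]


@dataclass(frozen=True)
class SetFstResult:
    theta: float
    sum_a: float
    sum_abc: float
    n_loci_used: int
    n_excluded: int


@dataclass(frozen=True)
class AssociationResult:
    locus: int
    chi2: float
    df: int
    p_value: float
    significant: bool | None = None


@dataclass(frozen=True)
class HetResult:
    per_locus: np.ndarray
    mean: float
    sd: float


# ---------------------------------------------------------------------------
# Frequencies and heterozygosity
# ---------------------------------------------------------------------------

def allele_frequency(
    matrix: GenotypeMatrix, taxon: str, locus: int
) -> tuple[float, int]:
    """Alternate-allele frequency and allele count within a taxon.

    Returns ``(freq, n_alleles)`` where ``n_alleles = 2 x`` the number of
    non-missing individuals.  All-missing loci give ``(nan, 0)``.
    """
    calls = matrix.taxon_calls(taxon, [locus])[:, 0]
    ok = calls != MISSING
    n = int(ok.sum())
    if n == 0:
        import logging

        logging.getLogger("immunediv").warning(
            "all calls missing for taxon %s at locus %d", taxon, locus
        )
        return float("nan"), 0
    return float(calls[ok].sum()) / (2 * n), 2 * n


def observed_heterozygosity(matrix: GenotypeMatrix, taxon: str) -> HetResult:
    """Per-locus observed heterozygosity and its mean/SD over loci.

    H_obs at a locus is the fraction of non-missing individuals with a
    heterozygous call.  The mean and SD are over loci with at least one
    call.
    """
    calls = matrix.taxon_calls(taxon)
    ok = calls != MISSING
    n = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(n > 0, (calls == 1).sum(axis=0) / np.maximum(n, 1), np.nan)
    valid = h[~np.isnan(h)]
    return HetResult(
        per_locus=h,
        mean=float(valid.mean()) if valid.size else float("nan"),
        sd=float(valid.std(ddof=1)) if valid.size > 1 else float("nan"),
    )


def expected_heterozygosity(
    matrix: GenotypeMatrix, taxa: Sequence[str] | None = None
) -> np.ndarray:
    """Per-locus mean (over taxa) unbiased expected heterozygosity.

    Within each taxon, H_exp = 2n/(2n-1) * 2p(1-p) from the complete-case
    allele frequency; the per-locus value averages over the taxa.  Used to
    condition the outlier scan on diversity.
    """
    taxa = list(taxa) if taxa is not None else matrix.taxa
    hs = []
    for t in taxa:
        calls = matrix.taxon_calls(t)
        ok = calls != MISSING
        n = ok.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(ok, calls, 0).sum(axis=0) / np.maximum(2 * n, 1)
            h = np.where(n > 0, 2 * n / np.maximum(2 * n - 1, 1) * 2 * p * (1 - p), np.nan)
        hs.append(h)
    return np.nanmean(np.vstack(hs), axis=0)


# ---------------------------------------------------------------------------
# Association
# ---------------------------------------------------------------------------

def genotype_table(
    matrix: GenotypeMatrix, locus: int, taxa: Sequence[str] | None = None
) -> np.ndarray:
    """Taxa x genotype-class (0/1/2) contingency table of non-missing counts."""
    taxa = list(taxa) if taxa is not None else matrix.taxa
    table = np.zeros((len(taxa), 3), dtype=np.int64)
    for i, t in enumerate(taxa):
        calls = matrix.taxon_calls(t, [locus])[:, 0]
        for g in (0, 1, 2):
            table[i, g] = int((calls == g).sum())
    return table


def genotype_association(
    matrix: GenotypeMatrix,
    locus: int,
    taxa: Sequence[str] | None = None,
    *,
    allelic: bool = False,
) -> AssociationResult:
    """Pearson chi-square test of genotype (or allele) counts across taxa.

    The contingency table is taxa x genotype classes (columns with zero
    total dropped, likewise empty taxa rows); no continuity correction.
    ``allelic=True`` collapses genotypes to a taxa x 2 allele-count table.
    Monomorphic loci (df = 0) give NaN statistics.
    """
    table = genotype_table(matrix, locus, taxa)
    if allelic:
        alt = table[:, 1] + 2 * table[:, 2]
        ref = 2 * table[:, 0] + table[:, 1]
        table = np.stack([ref, alt], axis=1)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    r, c = table.shape
    if r < 2 or c < 2:
        return AssociationResult(locus=locus, chi2=float("nan"), df=0, p_value=float("nan"))
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return AssociationResult(locus=locus, chi2=float(chi2), df=int(df), p_value=float(p))


def bonferroni_adjust(
    p_values: Sequence[float], m: int | None = None, alpha: float = 0.05
) -> tuple[np.ndarray, float]:
    """Bonferroni flags: significant iff p < alpha/m.

    ``m`` defaults to the number of tests supplied; it may be larger (e.g.
    the full panel size when only a subset is examined).
    """
    p = np.asarray(p_values, dtype=float)
    m = m if m is not None else p.size
    if m < p.size:
        raise ValueError(f"m ({m}) must be >= number of tests ({p.size})")
    threshold = alpha / m
    with np.errstate(invalid="ignore"):
        flags = p < threshold
    return flags, threshold


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def wc_components(
    matrix: GenotypeMatrix,
    taxa: Sequence[str] | None = None,
    loci: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham variance components (a, b, c), vectorized.

    Loci where any population has no usable call, or with fewer than 2
    populations, get NaN components.  Monomorphic loci get a = b = c = 0
    (their theta is NaN by the 0/0 convention).
    """
    taxa = list(taxa) if taxa is not None else matrix.taxa
    r = len(taxa)
    if r < 2:
        raise ValueError("need at least 2 taxa for F_ST")
    idx = np.asarray(loci, dtype=np.intp) if loci is not None else None

    n_it, p_it, h_it = [], [], []
    for t in taxa:
        calls = matrix.taxon_calls(t, idx)
        ok = calls != MISSING
        n = ok.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(ok, calls, 0).sum(axis=0) / np.maximum(2 * n, 1)
            h = (calls == 1).sum(axis=0) / np.maximum(n, 1)
        n_it.append(n)
        p_it.append(p)
        h_it.append(h)
    n_i = np.vstack(n_it)  # (r, L)
    p_i = np.vstack(p_it)
    h_i = np.vstack(h_it)

    bad = (n_i < 1).any(axis=0)
    n_i = np.where(n_i < 1, np.nan, n_i)

    nbar = n_i.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)

        inner = pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4
        a = (nbar / n_c) * (s2 - inner / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2

    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def wc_fst_locus(
    matrix: GenotypeMatrix, taxa: Sequence[str], locus: int
) -> FstResult:
    """Single-locus Weir-Cockerham theta with its variance components.

    theta is NaN when a + b + c = 0 (monomorphic locus).
    """
    taxa = list(taxa)
    a, b, c = wc_components(matrix, taxa, [locus])
    a, b, c = float(a[0]), float(b[0]), float(c[0])
    denom = a + b + c
    theta = a / denom if denom != 0 else float("nan")
    sizes = tuple(
        int((matrix.taxon_calls(t, [locus])[:, 0] != MISSING).sum()) for t in taxa
    )
    return FstResult(
        locus=locus, a=a, b=b, c=c, theta=theta, n_pops=len(taxa), sample_sizes=sizes
    )


def wc_fst_set(
    matrix: GenotypeMatrix,
    taxa: Sequence[str],
    loci: Sequence[int] | None = None,
) -> SetFstResult:
    """Multilocus ratio-of-sums ("weighted") theta over a set of loci.

    Loci with NaN components (monomorphic-with-missing edge cases, absent
    populations) are excluded from both sums; monomorphic loci contribute
    zero to both sums and are counted as excluded.
    """
    a, b, c = wc_components(matrix, taxa, loci)
    denom = a + b + c
    usable = ~np.isnan(denom) & (denom != 0)
    n_excluded = int((~usable).sum())
    sum_a = float(a[usable].sum())
    sum_abc = float(denom[usable].sum())
    theta = sum_a / sum_abc if sum_abc != 0 else float("nan")
    return SetFstResult(
        theta=theta,
        sum_a=sum_a,
        sum_abc=sum_abc,
        n_loci_used=int(usable.sum()),
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# Power
# ---------------------------------------------------------------------------

def chisq_power(effect_size_w: float, df: int, n: int, alpha: float = 0.05) -> float:
    """Power of a chi-square test at effect size w and total sample size n.

    The test statistic under the alternative is noncentral chi-square with
    noncentrality lambda = n * w^2; power = P(X > chi2_crit(alpha, df)).
    With w = 0 this reduces to alpha.
    """
    if effect_size_w < 0:
        raise ValueError("effect size w must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    crit = stats.chi2.ppf(1 - alpha, df)
    lam = n * effect_size_w**2
    if lam == 0:
        return float(alpha)
    return float(stats.ncx2.sf(crit, df, lam))
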