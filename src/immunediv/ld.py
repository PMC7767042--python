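"""Two-locus EM haplotype-frequency estimation and r^2 LD summaries.

For unphased diploid genotypes at two biallelic loci, only the
double-heterozygote class is phase-ambiguous.  The EM algorithm assigns it
fractionally each E-step by the relative probabilities of the coupling
(AB/ab) and repulsion (Ab/aB) phase, and re-estimates the four haplotype
frequencies in the M-step; the maximized likelihood gives the
maximum-likelihood r^2 = D^2 / (p_A(1-p_A) p_B(1-p_B)).

Uppercase alleles denote the alternate allele at each locus, so ``p_AB``
is the frequency of the alt-alt haplotype.

The all-double-heterozygote dataset has two symmetric likelihood maxima
(full coupling and full repulsion) separated by a saddle at linkage
equilibrium; equilibrium initialization alone stalls on the saddle, hence
the random restarts.  Symmetric ties are reported with the higher-|D|
solution (r^2 is identical by symmetry) and a multimodality flag.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import MISSING, GenotypeMatrix, SnpRecord

logger = logging.getLogger("immunediv")

__all__ = ["LdEstimate", "em_haplotype_frequencies", "em_from_table", "ld_summary"]

#: minimum complete-case individuals for a defined pairwise estimate
MIN_PAIR_N = 5


@dataclass(frozen=True)
class LdEstimate:
    locus_a: int
    locus_b: int
    p_AB: float
    p_Ab: float
    p_aB: float
    p_ab: float
    D: float
    r2: float
    loglik: float
    n_iter: int
    converged: bool
    multimodal: bool
    n_used: int

    @property
    def d_prime(self) -> float:
        pA, pB = self.p_AB + self.p_Ab, self.p_AB + self.p_aB
        if self.D >= 0:
            dmax = min(pA * (1 - pB), (1 - pA) * pB)
        else:
            dmax = min(pA * pB, (1 - pA) * (1 - pB))
        return self.D / dmax if dmax > 0 else float("nan")


def _nan_estimate(la: int, lb: int, n_used: int) -> LdEstimate:
    nan = float("nan")
    return LdEstimate(la, lb, nan, nan, nan, nan, nan, nan, nan, 0, False, False, n_used)


def genotype_pair_table(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """3x3 table of joint genotype counts; rows = dosage at A, cols = at B.

    Complete-case: individuals missing at either locus are dropped.
    """
    ok = (ga != MISSING) & (gb != MISSING)
    table = np.zeros((3, 3), dtype=np.int64)
    for i, j in zip(ga[ok], gb[ok]):
        table[i, j] += 1
    return table


def _class_probs(p: np.ndarray) -> np.ndarray:
    """P(joint genotype class) under random union of haplotypes.

    ``p = [p_AB, p_Ab, p_aB, p_ab]``; returns a 3x3 array indexed by
    (dosage at A, dosage at B).
    """
    pAB, pAb, paB, pab = p
    out = np.empty((3, 3))
    out[2, 2] = pAB**2
    out[2, 1] = 2 * pAB * pAb
    out[2, 0] = pAb**2
    out[1, 2] = 2 * pAB * paB
    out[1, 1] = 2 * pAB * pab + 2 * pAb * paB
    out[1, 0] = 2 * pAb * pab
    out[0, 2] = paB**2
    out[0, 1] = 2 * paB * pab
    out[0, 0] = pab**2
    return out


def loglik_from_table(table: np.ndarray, p: np.ndarray) -> float:
    """Multinomial log-likelihood of a 3x3 genotype table given haplotype freqs."""
    probs = _class_probs(np.asarray(p, dtype=float))
    with np.errstate(divide="ignore"):
        lp = np.log(probs)
    mask = table > 0
    if np.any(np.isneginf(lp[mask])):
        return float("-inf")
    return float((table[mask] * lp[mask]).sum())


def r2_from_haplotypes(p: np.ndarray) -> tuple[float, float]:
    """(D, r2) from haplotype frequencies ``[p_AB, p_Ab, p_aB, p_ab]``."""
    pAB, pAb, paB, pab = p
    pA, pB = pAB + pAb, pAB + paB
    D = pAB - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        return float(D), float("nan")
    return float(D), float(min(D * D / denom, 1.0))


def _em_single(
    table: np.ndarray, p0: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, float, int, bool]:
    """Run EM from one starting point; returns (p, loglik, iters, converged)."""
    n2 = 2 * table.sum()
    # fixed (phase-unambiguous) haplotype counts contributed by each class
    base = np.zeros(4)
    base[0] = 2 * table[2, 2] + table[2, 1] + table[1, 2]  # AB
    base[1] = 2 * table[2, 0] + table[2, 1] + table[1, 0]  # Ab
    base[2] = 2 * table[0, 2] + table[1, 2] + table[0, 1]  # aB
    base[3] = 2 * table[0, 0] + table[0, 1] + table[1, 0]  # ab
    n_dh = table[1, 1]

    p = p0.copy()
    ll = loglik_from_table(table, p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: split double heterozygotes between coupling and repulsion
        coup = p[0] * p[3]
        rep = p[1] * p[2]
        w = coup / (coup + rep) if (coup + rep) > 0 else 0.5
        counts = base.copy()
        counts[0] += n_dh * w
        counts[3] += n_dh * w
        counts[1] += n_dh * (1 - w)
        counts[2] += n_dh * (1 - w)
        # M-step
        p = counts / n2
        new_ll = loglik_from_table(table, p)
        if new_ll < ll - 1e-9:
            raise AssertionError(
                f"EM log-likelihood decreased ({ll} -> {new_ll}); this is a bug"
            )
        if new_ll - ll < tol:
            ll = new_ll
            converged = True
            break
        ll = new_ll
    return p, ll, it, converged


def em_from_table(
    table: np.ndarray,
    *,
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_restarts: int = 5,
    seed: int = 0,
    locus_a: int = 0,
    locus_b: int = 1,
) -> LdEstimate:
    """EM haplotype frequencies from a 3x3 joint genotype table.

    The first restart starts at linkage equilibrium (product of marginal
    allele frequencies); the remainder start at random Dirichlet points.
    The best log-likelihood wins; near-ties between distinct solutions are
    flagged multimodal and resolved toward the higher-|D| solution.
    """
    table = np.asarray(table, dtype=np.int64)
    n = int(table.sum())
    pA = (table * np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2]])).sum() / (2 * n)
    pB = (table * np.array([[0, 1, 2]] * 3)).sum() / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        est = _nan_estimate(locus_a, locus_b, n)
        logger.warning("monomorphic locus in LD pair (%d, %d)", locus_a, locus_b)
        return est

    rng = np.random.default_rng(seed)
    equil = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    starts = [equil]
    for _ in range(max(n_restarts - 1, 0)):
        starts.append(rng.dirichlet(np.ones(4)))
    # Boundary starts: a maximum with a zero haplotype frequency lies on a
    # simplex face that interior EM approaches only sublinearly.  EM keeps
    # an exact zero at zero, so starting on each data-compatible face finds
    # such maxima quickly.  A face is viable only if no phase-unambiguous
    # genotype requires the zeroed haplotype.
    base = np.array(
        [
            2 * table[2, 2] + table[2, 1] + table[1, 2],
            2 * table[2, 0] + table[2, 1] + table[1, 0],
            2 * table[0, 2] + table[1, 2] + table[0, 1],
            2 * table[0, 0] + table[0, 1] + table[1, 0],
        ]
    )
    free = [h for h in range(4) if base[h] == 0]
    for r in range(1, min(len(free), 2) + 1):
        for zeros in itertools.combinations(free, r):
            p0 = equil.copy()
            p0[list(zeros)] = 0.0
            if p0.sum() <= 0:
                continue
            p0 /= p0.sum()
            if np.isfinite(loglik_from_table(table, p0)):
                starts.append(p0)

    solutions = []
    for p0 in starts:
        p, ll, it, conv = _em_single(table, p0, tol, max_iter)
        solutions.append((p, ll, it, conv))

    best_ll = max(s[1] for s in solutions)
    # candidates within numerical tie of the best likelihood
    ties = [s for s in solutions if s[1] >= best_ll - 1e-6]
    multimodal = False
    ref_p = ties[0][0]
    for p, *_ in ties[1:]:
        if np.max(np.abs(p - ref_p)) > 1e-3:
            multimodal = True
            break
    # higher-|D| solution wins among ties
    best = max(ties, key=lambda s: abs(r2_from_haplotypes(s[0])[0]))
    p, ll, it, conv = best
    if multimodal:
        logger.warning(
            "LD likelihood for pair (%d, %d) is multimodal; reporting higher-|D| mode",
            locus_a,
            locus_b,
        )
    if not conv:
        logger.warning("EM did not converge for pair (%d, %d)", locus_a, locus_b)

    D, r2 = r2_from_haplotypes(p)
    return LdEstimate(
        locus_a=locus_a,
        locus_b=locus_b,
        p_AB=float(p[0]),
        p_Ab=float(p[1]),
        p_aB=float(p[2]),
        p_ab=float(p[3]),
        D=D,
        r2=r2,
        loglik=ll,
        n_iter=it,
        converged=conv,
        multimodal=multimodal,
        n_used=n,
    )


def em_haplotype_frequencies(
    matrix: GenotypeMatrix,
    taxon: str,
    locus_a: int,
    locus_b: int,
    *,
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_restarts: int = 5,
    seed: int = 0,
) -> LdEstimate:
    """Maximum-likelihood two-locus haplotype frequencies within a taxon.

    Pairwise complete-case; pairs with fewer than ``MIN_PAIR_N`` usable
    individuals, or with either locus monomorphic among them, give NaN.
    """
    calls = matrix.taxon_calls(taxon, [locus_a, locus_b])
    table = genotype_pair_table(calls[:, 0], calls[:, 1])
    n = int(table.sum())
    if n < MIN_PAIR_N:
        logger.warning(
            "only %d usable individuals for LD pair (%d, %d); need %d",
            n,
            locus_a,
            locus_b,
            MIN_PAIR_N,
        )
        return _nan_estimate(locus_a, locus_b, n)
    return em_from_table(
        table,
        tol=tol,
        max_iter=max_iter,
        n_restarts=n_restarts,
        seed=seed,
        locus_a=locus_a,
        locus_b=locus_b,
    )


def ld_summary(
    matrix: GenotypeMatrix,
    taxon: str,
    snp_indices: Sequence[int] | None = None,
    thresholds: Sequence[float] = (0.5, 0.8, 0.95),
    *,
    max_between_pairs: int | None = None,
    seed: int = 0,
    return_pairs: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Proportions of SNP pairs exceeding r^2 thresholds, within vs between genes.

    Only SNPs with a gene assignment participate.  A pair is *within-gene*
    if the two SNPs share at least one gene id.  Proportions are taken over
    pairs with a defined r^2 (the NaN-pair count is reported alongside).
    ``max_between_pairs`` caps the between-gene pair count by seeded random
    subsampling, keeping large panels tractable.
    """
    if snp_indices is None:
        snp_indices = [i for i, s in enumerate(matrix.loci) if s.gene_ids]
    snp_indices = list(snp_indices)
    within, between = [], []
    for ia, ib in itertools.combinations(snp_indices, 2):
        ga = set(matrix.loci[ia].gene_ids)
        gb = set(matrix.loci[ib].gene_ids)
        (within if ga & gb else between).append((ia, ib))
    if max_between_pairs is not None and len(between) > max_between_pairs:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(between), size=max_between_pairs, replace=False)
        between = [between[k] for k in sorted(keep)]

    rows = []
    pair_rows = []
    for partition, pairs in (("within_gene", within), ("between_gene", between)):
        r2s = []
        for k, (ia, ib) in enumerate(pairs):
            est = em_haplotype_frequencies(matrix, taxon, ia, ib, seed=seed + k)
            r2s.append(est.r2)
            if return_pairs:
                pair_rows.append(
                    {
                        "taxon": taxon,
                        "locus_a": matrix.loci[ia].label,
                        "locus_b": matrix.loci[ib].label,
                        "same_gene": partition == "within_gene",
                        "p_AB": est.p_AB,
                        "p_Ab": est.p_Ab,
                        "p_aB": est.p_aB,
                        "p_ab": est.p_ab,
                        "D": est.D,
                        "r2": est.r2,
                        "converged": est.converged,
                    }
                )
        r2s = np.array(r2s, dtype=float)
        defined = r2s[~np.isnan(r2s)]
        for thr in thresholds:
            rows.append(
                {
                    "taxon": taxon,
                    "partition": partition,
                    "threshold": thr,
                    "n_pairs": len(pairs),
                    "n_defined": defined.size,
                    "n_nan": int(np.isnan(r2s).sum()),
                    "proportion": float((defined > thr).mean()) if defined.size else float("nan"),
                }
            )
    summary = pd.DataFrame(rows)
    if return_pairs:
        return summary, pd.DataFrame(pair_rows)
    return summary
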