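"""Hierarchical-island-model coalescent null and F_ST outlier detection.

The neutral null is a metapopulation of ``n_groups`` groups of
``demes_per_group`` demes.  Lineages coalesce pairwise within a deme at
rate 1 per pair (time in units of 2N generations per deme) and migrate at
total rate ``(M_w + M_b) / 2`` per lineage, choosing a destination deme
uniformly within the same group with probability ``M_w / (M_w + M_b)``
and uniformly in another group otherwise; ``M_w > M_b`` makes demes
exchange more migrants within than between groups.  Per simulated locus a
single mutation is placed on the genealogy with probability proportional
to branch length, yielding one biallelic SNP that is always polymorphic
in the pooled sample; sampled lineages are paired into diploids within
each deme (lineages are exchangeable, so consecutive pairing is a random
pairing).

Each null point is the pair (mean within-deme unbiased expected
heterozygosity, Weir-Cockerham theta across the sampled demes).  Observed
loci are compared to null points in the same heterozygosity quantile bin
(an FDIST-style conditioning that controls for allele-frequency-dependent
F_ST variance), one-sided toward high F_ST.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .core_io import GenotypeMatrix
from .popstats import expected_heterozygosity, wc_components

__all__ = [
    "HierIslandConfig",
    "OutlierResult",
    "simulate_hier_island_null",
    "outlier_pvalues",
    "flag_outliers",
    "locus_scan_stats",
]


@dataclass(frozen=True)
class HierIslandConfig:
    """Parameters of the hierarchical-island coalescent null.

    Defaults place three sampled demes in three distinct groups, mimicking
    three partially isolated taxa.  Migration rates are scaled (M = 4Nm).
    """

    n_groups: int = 10
    demes_per_group: int = 100
    migration_within: float = 20.0
    migration_between: float = 2.0
    diploids_per_deme: int = 12
    sampled_demes: tuple[tuple[int, int], ...] = ((0, 0), (1, 0), (2, 0))
    n_sims: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.migration_within > self.migration_between > 0:
            raise ValueError("need M_w > M_b > 0")
        if self.n_sims < 100:
            raise ValueError("n_sims must be >= 100")
        if self.n_groups < 1 or self.demes_per_group < 1:
            raise ValueError("need at least one group and one deme")
        if len(self.sampled_demes) > self.n_groups * self.demes_per_group:
            raise ValueError("more sampled demes than demes")
        for g, d in self.sampled_demes:
            if not (0 <= g < self.n_groups and 0 <= d < self.demes_per_group):
                raise ValueError(f"sampled deme ({g},{d}) outside the metapopulation")
        if len(set(self.sampled_demes)) != len(self.sampled_demes):
            raise ValueError("sampled demes must be distinct")
        n_lin = 2 * self.diploids_per_deme * len(self.sampled_demes)
        if n_lin > 512:
            raise ValueError(f"sample of {n_lin} lineages too large")
        if self.diploids_per_deme < 1:
            raise ValueError("diploids_per_deme must be >= 1")


@dataclass(frozen=True)
class OutlierResult:
    locus: int
    theta: float
    heterozygosity: float
    p_value: float
    het_bin: int


@njit(cache=True)
def _sim_kernel(
    n_sims, n_groups, demes_per_group, m_w, m_b, samp_group, samp_deme, n_dip, seed
):  # pragma: no cover - exercised through the wrapper
    np.random.seed(seed)
    G, D = n_groups, demes_per_group
    n_demes = G * D
    n_s = samp_group.size
    n_lin0 = 2 * n_dip * n_s
    n_words = (n_lin0 + 63) // 64

    out_het = np.empty(n_sims)
    out_theta = np.empty(n_sims)
    out_tmrca = np.empty(n_sims)

    occ = np.zeros(n_demes, dtype=np.int64)
    grp = np.empty(n_lin0, dtype=np.int64)
    dem = np.empty(n_lin0, dtype=np.int64)
    birth = np.empty(n_lin0)
    mask = np.zeros((n_lin0, n_words), dtype=np.uint64)
    blen = np.empty(2 * n_lin0)
    bmask = np.zeros((2 * n_lin0, n_words), dtype=np.uint64)
    ps = np.empty(n_s)
    hs = np.empty(n_s)

    mig_per_lin = (m_w + m_b) / 2.0 if n_demes > 1 else 0.0
    p_within = m_w / (m_w + m_b)

    for s in range(n_sims):
        for d in range(n_demes):
            occ[d] = 0
        k = n_lin0
        for i in range(n_lin0):
            si = i // (2 * n_dip)
            grp[i] = samp_group[si]
            dem[i] = samp_group[si] * D + samp_deme[si]
            birth[i] = 0.0
            for w in range(n_words):
                mask[i, w] = np.uint64(0)
            mask[i, i >> 6] = np.uint64(1) << np.uint64(i & 63)
            occ[dem[i]] += 1
        sum_pairs = 0.0
        for d in range(n_demes):
            c = occ[d]
            if c > 1:
                sum_pairs += c * (c - 1) / 2.0

        t = 0.0
        nb = 0
        while k > 1:
            total = sum_pairs + k * mig_per_lin
            t += -np.log(np.random.random()) / total
            if np.random.random() * total < sum_pairs:
                # ---- coalescence: deme weighted by its pair count
                target = np.random.random() * sum_pairs
                acc = 0.0
                cd = -1
                for d in range(n_demes):
                    c = occ[d]
                    if c > 1:
                        acc += c * (c - 1) / 2.0
                        if acc >= target:
                            cd = d
                            break
                if cd < 0:
                    for d in range(n_demes - 1, -1, -1):
                        if occ[d] > 1:
                            cd = d
                            break
                c = occ[cd]
                i1 = np.random.randint(c)
                i2 = np.random.randint(c - 1)
                if i2 >= i1:
                    i2 += 1
                x = -1
                y = -1
                seen = 0
                for i in range(k):
                    if dem[i] == cd:
                        if seen == i1:
                            x = i
                        if seen == i2:
                            y = i
                        seen += 1
                blen[nb] = t - birth[x]
                for w in range(n_words):
                    bmask[nb, w] = mask[x, w]
                nb += 1
                blen[nb] = t - birth[y]
                for w in range(n_words):
                    bmask[nb, w] = mask[y, w]
                nb += 1
                for w in range(n_words):
                    mask[x, w] |= mask[y, w]
                birth[x] = t
                k -= 1
                grp[y] = grp[k]
                dem[y] = dem[k]
                birth[y] = birth[k]
                for w in range(n_words):
                    mask[y, w] = mask[k, w]
                occ[cd] -= 1
                sum_pairs -= c - 1
            else:
                # ---- migration
                i = np.random.randint(k)
                old = dem[i]
                g = grp[i]
                new = old
                if np.random.random() < p_within:
                    if D > 1:
                        dl = np.random.randint(D - 1)
                        if dl >= old - g * D:
                            dl += 1
                        new = g * D + dl
                else:
                    if G > 1:
                        g2 = np.random.randint(G - 1)
                        if g2 >= g:
                            g2 += 1
                        new = g2 * D + np.random.randint(D)
                        grp[i] = g2
                if new != old:
                    occ[old] -= 1
                    sum_pairs -= occ[old]
                    sum_pairs += occ[new]
                    occ[new] += 1
                    dem[i] = new
        out_tmrca[s] = t

        # ---- one mutation, uniform on total branch length
        tot = 0.0
        for bi in range(nb):
            tot += blen[bi]
        target = np.random.random() * tot
        acc = 0.0
        chosen = nb - 1
        for bi in range(nb):
            acc += blen[bi]
            if acc >= target:
                chosen = bi
                break

        # ---- per-deme derived frequency and observed heterozygosity
        het_acc = 0.0
        for si in range(n_s):
            cnt = 0
            hets = 0
            for j in range(n_dip):
                i0 = (si * n_dip + j) * 2
                i1 = i0 + 1
                a0 = (bmask[chosen, i0 >> 6] >> np.uint64(i0 & 63)) & np.uint64(1)
                a1 = (bmask[chosen, i1 >> 6] >> np.uint64(i1 & 63)) & np.uint64(1)
                cnt += int(a0) + int(a1)
                if a0 != a1:
                    hets += 1
            p = cnt / (2.0 * n_dip)
            ps[si] = p
            hs[si] = hets / n_dip
            het_acc += (2.0 * n_dip / (2.0 * n_dip - 1.0)) * 2.0 * p * (1.0 - p)
        out_het[s] = het_acc / n_s

        # ---- Weir-Cockerham theta across sampled demes (equal sizes)
        if n_s >= 2 and n_dip >= 2:
            r = float(n_s)
            nbar = float(n_dip)
            pbar = 0.0
            hbar = 0.0
            for si in range(n_s):
                pbar += ps[si]
                hbar += hs[si]
            pbar /= r
            hbar /= r
            s2 = 0.0
            for si in range(n_s):
                s2 += (ps[si] - pbar) ** 2
            s2 /= r - 1.0
            inner = pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0
            a_ = s2 - inner / (nbar - 1.0)
            b_ = nbar / (nbar - 1.0) * (
                pbar * (1.0 - pbar)
                - (r - 1.0) / r * s2
                - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
            )
            c_ = hbar / 2.0
            denom = a_ + b_ + c_
            out_theta[s] = a_ / denom if denom != 0.0 else np.nan
        else:
            out_theta[s] = np.nan

    return out_het, out_theta, out_tmrca


def _simulate(config: HierIslandConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    samp_group = np.array([g for g, _ in config.sampled_demes], dtype=np.int64)
    samp_deme = np.array([d for _, d in config.sampled_demes], dtype=np.int64)
    return _sim_kernel(
        config.n_sims,
        config.n_groups,
        config.demes_per_group,
        float(config.migration_within),
        float(config.migration_between),
        samp_group,
        samp_deme,
        config.diploids_per_deme,
        config.seed % 2**31,
    )


def simulate_hier_island_null(config: HierIslandConfig) -> np.ndarray:
    """Simulate the neutral joint (heterozygosity, theta) distribution.

    Returns an array of shape ``(n_sims, 2)`` with columns
    (mean within-deme expected heterozygosity, W&C theta).
    """
    het, theta, _ = _simulate(config)
    return np.column_stack([het, theta])


def _merge_bins(bin_counts: np.ndarray, min_per_bin: int) -> np.ndarray:
    """Map original quantile bins to merged bins with >= min_per_bin points."""
    merged = np.empty(bin_counts.size, dtype=np.intp)
    group = 0
    acc = 0
    for b in range(bin_counts.size):
        merged[b] = group
        acc += bin_counts[b]
        if acc >= min_per_bin:
            group += 1
            acc = 0
    if acc > 0 and group > 0:
        # fold the short trailing group into the previous one
        merged[merged == group] = group - 1
    return merged


def outlier_pvalues(
    observed_het: Sequence[float],
    observed_theta: Sequence[float],
    null_points: np.ndarray,
    n_het_bins: int = 20,
    min_per_bin: int = 20,
) -> list[OutlierResult]:
    """Per-locus upper-tail selection p-values conditioned on heterozygosity.

    Null points are binned by heterozygosity quantiles (bins with fewer
    than ``min_per_bin`` points merge rightward into neighbours); each
    observed locus is ranked against the null theta values of its bin:
    ``p = (1 + #{null theta >= observed}) / (n_bin + 1)``.
    """
    null_points = np.asarray(null_points, dtype=float)
    if null_points.size == 0:
        raise ValueError("empty null distribution")
    null_het, null_theta = null_points[:, 0], null_points[:, 1]
    edges = np.quantile(null_het, np.linspace(0, 1, n_het_bins + 1))[1:-1]
    null_bin = np.searchsorted(edges, null_het, side="right")
    counts = np.bincount(null_bin, minlength=n_het_bins)
    merged = _merge_bins(counts, min_per_bin)

    # pre-sort null theta per merged bin for rank lookups
    theta_by_bin: dict[int, np.ndarray] = {}
    null_mbin = merged[null_bin]
    for mb in np.unique(null_mbin):
        theta_by_bin[int(mb)] = np.sort(null_theta[null_mbin == mb])

    results = []
    obs_het = np.asarray(observed_het, dtype=float)
    obs_theta = np.asarray(observed_theta, dtype=float)
    obs_bin = merged[np.searchsorted(edges, obs_het, side="right")]
    for i, (th, mb) in enumerate(zip(obs_theta, obs_bin)):
        pool = theta_by_bin[int(mb)]
        if np.isnan(th):
            p = float("nan")
        else:
            n_ge = pool.size - np.searchsorted(pool, th, side="left")
            p = (1 + int(n_ge)) / (pool.size + 1)
        results.append(
            OutlierResult(
                locus=i,
                theta=float(th),
                heterozygosity=float(obs_het[i]),
                p_value=p,
                het_bin=int(mb),
            )
        )
    return results


def flag_outliers(
    results: Sequence[OutlierResult], alpha: float = 0.05, m: int | None = None
) -> list[OutlierResult]:
    """Bonferroni-flagged outliers: p < alpha / m (m defaults to #loci)."""
    m = m if m is not None else len(results)
    threshold = alpha / m
    return [r for r in results if not np.isnan(r.p_value) and r.p_value < threshold]


def locus_scan_stats(
    matrix: GenotypeMatrix, taxa: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Observed per-locus (heterozygosity, theta) for the outlier scan.

    Heterozygosity is the mean over taxa of the unbiased within-taxon
    expected heterozygosity, matching the null simulator's statistic.
    """
    taxa = list(taxa) if taxa is not None else matrix.taxa
    het = expected_heterozygosity(matrix, taxa)
    a, b, c = wc_components(matrix, taxa)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(a + b + c != 0, a / (a + b + c), np.nan)
    return het, theta
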