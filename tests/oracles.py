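"""Independent reference implementations used only by the tests.

These are deliberately separate, scalar/brute-force codings of the same
statistics the package computes in vectorized form: Weir-Cockerham
variance components transcribed literally from the component formulas, a
textbook Pearson chi-square, and a direct likelihood maximization over
the haplotype simplex for two-locus LD.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats


def wc_oracle(pops: list[np.ndarray]) -> tuple[float, float, float, float]:
    """Literal scalar transcription of the W&C (1984) components.

    ``pops`` holds one dosage array (no missing) per population.
    Returns (a, b, c, theta).
    """
    r = len(pops)
    n = [float(len(p)) for p in pops]
    p = [float(np.sum(x)) / (2 * len(x)) for x in pops]
    h = [float(np.mean(np.asarray(x) == 1)) for x in pops]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni * ni for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    theta = a / denom if denom != 0 else float("nan")
    return a, b, c, theta


def chi2_oracle(table: np.ndarray) -> tuple[float, int, float]:
    """Textbook Pearson chi-square on a contingency table (no correction)."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    chi2 = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / total
            chi2 += (table[i, j] - e) ** 2 / e
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return chi2, df, float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# Two-locus likelihood, derived from first principles (ordered haplotype pairs)
# ---------------------------------------------------------------------------

_HAP_A = np.array([1, 1, 0, 0])  # alt-allele indicator at locus A per haplotype
_HAP_B = np.array([1, 0, 1, 0])


def class_probs_oracle(p4: np.ndarray) -> np.ndarray:
    """Joint genotype probabilities by summing over ordered haplotype pairs."""
    out = np.zeros((3, 3))
    for i in range(4):
        for j in range(4):
            out[_HAP_A[i] + _HAP_A[j], _HAP_B[i] + _HAP_B[j]] += p4[i] * p4[j]
    return out


def loglik_oracle(table: np.ndarray, p4: np.ndarray) -> float:
    probs = class_probs_oracle(np.asarray(p4, dtype=float))
    ll = 0.0
    for i in range(3):
        for j in range(3):
            if table[i, j] > 0:
                if probs[i, j] <= 0:
                    return float("-inf")
                ll += table[i, j] * np.log(probs[i, j])
    return float(ll)


def r2_oracle(p4: np.ndarray) -> float:
    pA = p4[0] + p4[1]
    pB = p4[0] + p4[2]
    D = p4[0] - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    return float(min(D * D / denom, 1.0)) if denom > 0 else float("nan")


def _softmax4(z: np.ndarray) -> np.ndarray:
    e = np.exp(np.concatenate([z, [0.0]]) - max(z.max(initial=0.0), 0.0))
    return e / e.sum()


def bruteforce_ml(table: np.ndarray, seed: int = 0) -> tuple[float, float]:
    """Brute-force ML over the haplotype simplex: grid scan + local polish.

    Returns (max log-likelihood, r2 at the maximizer).
    """
    table = np.asarray(table, dtype=float)
    # coarse simplex grid at resolution 1/20
    pts = []
    n = 20
    for i in range(n + 1):
        for j in range(n + 1 - i):
            for k in range(n + 1 - i - j):
                pts.append((i / n, j / n, k / n, (n - i - j - k) / n))
    pts = np.array(pts)
    pts = np.clip(pts, 1e-9, None)
    pts /= pts.sum(axis=1, keepdims=True)
    lls = np.array([loglik_oracle(table, p) for p in pts])
    order = np.argsort(lls)[::-1][:8]

    best_ll, best_p = -np.inf, None
    for idx in order:
        z0 = np.log(pts[idx][:3] / pts[idx][3])

        def neg(z):
            return -loglik_oracle(table, _softmax4(z))

        res = optimize.minimize(neg, z0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        if -res.fun > best_ll:
            best_ll = -res.fun
            best_p = _softmax4(res.x)
    return float(best_ll), r2_oracle(best_p)
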