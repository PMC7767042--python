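"""Gene-set bootstrap and inversion permutation: exactness and calibration."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats

from immunediv.core_io import GeneAnnotation, GenotypeMatrix, InversionRegion, SnpRecord
from immunediv.popstats import wc_fst_set
from immunediv.resampling import (
    geneset_fst_test,
    geneset_snpcount_test,
    inversion_overlap_test,
)


def _gene(i: int, chrom: str = "2R", start: int | None = None, length: int = 100):
    s = start if start is not None else i * 1000
    return GeneAnnotation(gene_id=f"g{i}", chromosome=chrom, start=s, end=s + length)


def _matrix_with_gene_snps(theta_targets: list[float], seed: int = 0) -> tuple:
    """One SNP per gene; per-gene divergence tuned by fixed genotype blocks.

    theta target 0.5 -> strongly diverged pops; 0.1 -> mildly diverged.
    Returns (matrix, genes).
    """
    rng = np.random.default_rng(seed)
    genes = [_gene(i) for i in range(len(theta_targets))]
    n = 20
    cols = []
    loci = []
    for i, tt in enumerate(theta_targets):
        # population frequencies straddling 0.5 by +-delta; larger delta
        # gives larger theta
        delta = min(0.49, float(np.sqrt(tt)) / 2 + 0.1)
        fa, fb = 0.5 - delta, 0.5 + delta
        col = np.concatenate(
            [rng.binomial(2, fa, n), rng.binomial(2, fb, n)]
        ).astype(np.int8)
        cols.append(col)
        loci.append(
            SnpRecord(chromosome="2R", position=genes[i].start + 50,
                      ref_allele="A", alt_allele="T", name=f"s{i}",
                      gene_ids=(genes[i].gene_id,))
        )
    inds = [f"a{k}" for k in range(n)] + [f"b{k}" for k in range(n)]
    taxon_of = {k: ("A" if k.startswith("a") else "B") for k in inds}
    return GenotypeMatrix(inds, taxon_of, loci, np.column_stack(cols)), genes


class TestExhaustiveEnumeration:
    def test_fst_toy_matches_subset_enumeration(self):
        # 5 single-SNP genes: g0 strongly diverged, g1..g4 identical mild
        # columns; immune = {g0, g1}.  Exhaustive p = fraction of the
        # C(5,2)=10 equal-sized subsets of the full pool whose set F_ST >=
        # the observed immune value: exactly the 4 subsets containing g0.
        genes = [_gene(i) for i in range(5)]
        n = 20
        strong = np.concatenate([np.zeros(n), np.full(n, 2)])
        mild = np.concatenate(
            [np.tile([0, 0, 1, 1], 5), np.tile([0, 1, 1, 2], 5)]
        )
        calls = np.column_stack([strong] + [mild] * 4).astype(np.int8)
        loci = [
            SnpRecord(chromosome="2R", position=g.start + 50, ref_allele="A",
                      alt_allele="T", name=f"s{i}", gene_ids=(g.gene_id,))
            for i, g in enumerate(genes)
        ]
        inds = [f"a{k}" for k in range(n)] + [f"b{k}" for k in range(n)]
        taxon_of = {k: ("A" if k.startswith("a") else "B") for k in inds}
        m = GenotypeMatrix(inds, taxon_of, loci, calls)
        res = geneset_fst_test(m, ("A", "B"), genes, ["g0", "g1"], exhaustive=True)
        # independent enumeration oracle straight from wc_fst_set
        vals = []
        for pair in itertools.combinations(range(5), 2):
            vals.append(wc_fst_set(m, ["A", "B"], list(pair)).theta)
        obs = wc_fst_set(m, ["A", "B"], [0, 1]).theta
        expect = np.mean([v >= obs for v in vals])
        assert res.observed == pytest.approx(obs)
        assert res.p_value == pytest.approx(expect)
        assert res.B == 10
        # the strongly diverged gene drives the tail: subsets containing it
        assert expect == pytest.approx(4 / 10)

    def test_snpcount_toy_enumeration(self):
        # genes carrying (10, 1, 1, 1) SNPs, immune = {g0}: p(count >= 10) = 1/4
        genes = [_gene(i) for i in range(4)]
        loci = []
        for gi, k in enumerate((10, 1, 1, 1)):
            for j in range(k):
                loci.append(
                    SnpRecord(chromosome="2R", position=genes[gi].start + j + 1,
                              ref_allele="A", alt_allele="T",
                              gene_ids=(genes[gi].gene_id,))
                )
        res = geneset_snpcount_test(loci, genes, ["g0"], exhaustive=True)
        assert res.observed == 10
        assert res.p_value == pytest.approx(1 / 4)

    def test_snpcount_equal_genes_degenerate(self):
        genes = [_gene(i) for i in range(4)]
        loci = [
            SnpRecord(chromosome="2R", position=g.start + j + 1,
                      ref_allele="A", alt_allele="T", gene_ids=(g.gene_id,))
            for g in genes for j in range(3)
        ]
        res = geneset_snpcount_test(loci, genes, ["g0", "g1"], exhaustive=True)
        assert res.p_value == 1.0  # every subset ties the observed count

    def test_inversion_toy_enumeration(self):
        # 4 genes, 2 inside the inversion, immune = those 2:
        # null mean over C(4,2)=6 subsets is 1.0 and p(>=2) = 1/6
        inv = InversionRegion("2Rb", "2R", 0, 1500)
        genes = [_gene(i) for i in range(4)]  # g0,g1 inside [0,1500)
        res = inversion_overlap_test(genes, ["g0", "g1"], [inv],
                                     near_distance=0, exhaustive=True)
        assert res.observed == 2
        assert res.null_mean == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 6)

    def test_inversion_covering_everything(self):
        inv = InversionRegion("big", "2R", 0, 10**9)
        genes = [_gene(i) for i in range(6)]
        res = inversion_overlap_test(genes, ["g0", "g1"], [inv],
                                     near_distance=0, exhaustive=True)
        assert res.p_value == 1.0

    def test_sampled_p_converges_to_exact_p(self):
        m, genes = _matrix_with_gene_snps([0.5, 0.3, 0.1, 0.1, 0.1, 0.1, 0.1], seed=4)
        immune = ["g0", "g1"]
        exact = geneset_fst_test(m, ("A", "B"), genes, immune, exhaustive=True)
        # sampled mode draws from the non-immune pool; build the matching
        # exact reference by enumerating non-immune subsets with add-one
        pool = [g for g in genes if g.gene_id not in immune]
        obs = exact.observed
        null = [
            wc_fst_set(m, ["A", "B"], [genes.index(a), genes.index(b)]).theta
            for a, b in itertools.combinations(pool, 2)
        ]
        p_exact = np.mean([v >= obs for v in null])
        B = 2000
        sampled = geneset_fst_test(m, ("A", "B"), genes, immune, B=B, seed=11)
        tol = 2 * np.sqrt(max(p_exact, 1 / B) * (1 - p_exact) / B) + 1 / B
        assert abs(sampled.p_value - p_exact) <= tol + 1e-12


class TestConventionsAndCalibration:
    def test_p_never_zero_and_addone_formula(self):
        m, genes = _matrix_with_gene_snps([0.5] + [0.01] * 9, seed=6)
        res = geneset_fst_test(m, ("A", "B"), genes, ["g0"], B=200, seed=1)
        assert res.p_value >= 1 / 201
        n_ge = int((res.null_values >= res.observed).sum())
        assert res.p_value == pytest.approx((1 + n_ge) / 201)

    def test_b_below_one_rejected_and_empty_immune(self):
        m, genes = _matrix_with_gene_snps([0.1, 0.1], seed=0)
        with pytest.raises(ValueError, match="B must be >= 1"):
            geneset_fst_test(m, ("A", "B"), genes, ["g0"], B=0)
        with pytest.raises(ValueError, match="empty"):
            geneset_fst_test(m, ("A", "B"), genes, ["nope"], B=10)

    def test_same_seed_reproducible_different_seeds_compatible(self):
        m, genes = _matrix_with_gene_snps([0.2] * 30, seed=8)
        immune = ["g0", "g1", "g2"]
        r1 = geneset_fst_test(m, ("A", "B"), genes, immune, B=300, seed=5)
        r2 = geneset_fst_test(m, ("A", "B"), genes, immune, B=300, seed=5)
        np.testing.assert_array_equal(r1.null_values, r2.null_values)
        r3 = geneset_fst_test(m, ("A", "B"), genes, immune, B=300, seed=6)
        assert abs(r1.null_mean - r3.null_mean) < 4 * max(r1.null_sem, r3.null_sem)

    def test_null_immune_sets_give_uniform_p(self):
        # immune set itself random -> p should be uniform on {1/(B+1)..1}
        rng = np.random.default_rng(13)
        m, genes = _matrix_with_gene_snps(
            rng.uniform(0.05, 0.3, 40).tolist(), seed=14
        )
        B = 99
        ps = []
        for rep in range(200):
            immune = [f"g{i}" for i in rng.choice(40, size=5, replace=False)]
            res = geneset_fst_test(m, ("A", "B"), genes, immune, B=B, seed=rep)
            ps.append(res.p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_null_mean_matches_sampling_expectation(self):
        rng = np.random.default_rng(3)
        genes = [_gene(i) for i in range(50)]
        loci = []
        counts = rng.poisson(3, size=50)
        for g, k in zip(genes, counts):
            for j in range(k):
                loci.append(
                    SnpRecord(chromosome="2R", position=g.start + j + 1,
                              ref_allele="A", alt_allele="T", gene_ids=(g.gene_id,))
                )
        immune = [f"g{i}" for i in range(5)]
        res = geneset_snpcount_test(loci, genes, immune, B=1000, seed=9)
        pool_mean = counts[5:].mean()
        assert abs(res.null_mean - 5 * pool_mean) < 3 * res.null_sem * np.sqrt(1000 / 5)

    def test_inversion_null_calibration(self):
        rng = np.random.default_rng(10)
        inv = InversionRegion("2Rb", "2R", 0, 25_000)
        genes = [_gene(i) for i in range(100)]
        within = 0
        for rep in range(200):
            immune = [f"g{i}" for i in rng.choice(100, size=10, replace=False)]
            res = inversion_overlap_test(genes, immune, [inv], near_distance=0,
                                         B=300, seed=rep)
            if abs(res.observed - res.null_mean) <= 3 * res.null_sd:
                within += 1
        assert within >= 198  # >= 99% of random sets inside +-3 SD

    def test_exclusion_regions_remove_genes_from_both_pools(self):
        m, genes = _matrix_with_gene_snps([0.5, 0.1, 0.1, 0.1], seed=1)
        excl = [InversionRegion("island", "2R", 0, 500)]  # covers g0 only
        res = geneset_fst_test(m, ("A", "B"), genes, ["g0", "g1"], B=10,
                               seed=0, exclusion_regions=excl)
        # g0 excluded -> observed is g1's theta alone
        assert res.observed == pytest.approx(wc_fst_set(m, ["A", "B"], [1]).theta)

    def test_no_inversions_is_error(self):
        genes = [_gene(i) for i in range(4)]
        with pytest.raises(ValueError, match="no inversions"):
            inversion_overlap_test(genes, ["g0"], [], B=10)
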