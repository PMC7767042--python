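"""Frequencies, heterozygosity, association, power and Weir-Cockerham F_ST."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from immunediv.core_io import MISSING, GenotypeMatrix, SnpRecord
from immunediv.popstats import (
    allele_frequency,
    bonferroni_adjust,
    chisq_power,
    genotype_association,
    observed_heterozygosity,
    wc_components,
    wc_fst_locus,
    wc_fst_set,
)
from immunediv.simulate import gen_balding_nichols

from conftest import matrix_from_counts
from oracles import chi2_oracle, wc_oracle


def _matrix(rows: dict[str, list[list[int]]]) -> GenotypeMatrix:
    """Build a matrix from per-taxon lists of per-individual dosage rows."""
    inds, taxon_of, calls = [], {}, []
    for taxon, block in rows.items():
        for i, row in enumerate(block):
            ind = f"{taxon}{i}"
            inds.append(ind)
            taxon_of[ind] = taxon
            calls.append(row)
    n_loci = len(calls[0])
    loci = [
        SnpRecord(chromosome="un", position=i + 1, ref_allele="A", alt_allele="T")
        for i in range(n_loci)
    ]
    return GenotypeMatrix(inds, taxon_of, loci, np.array(calls, dtype=np.int8))


class TestAlleleFrequencyAndHet:
    def test_printed_genotype_counts_give_expected_freq(self, table2_matrices):
        # 164 C/C, 1 C/T, 0 T/T -> one T allele among 330
        m = table2_matrices["MAP2K4-164"]
        freq, n = allele_frequency(m, "coluzzii", 0)
        assert n == 330
        assert freq == pytest.approx(1 / 330)

    def test_fixed_alt_and_balanced(self):
        m = _matrix({"a": [[2], [2], [2]]})
        assert allele_frequency(m, "a", 0)[0] == 1.0
        m = _matrix({"a": [[0], [1], [2]]})
        assert allele_frequency(m, "a", 0)[0] == 0.5

    def test_all_missing_gives_nan_and_warning(self, caplog):
        m = _matrix({"a": [[MISSING], [MISSING]]})
        with caplog.at_level("WARNING", logger="immunediv"):
            freq, n = allele_frequency(m, "a", 0)
        assert np.isnan(freq) and n == 0
        assert any("missing" in r.message for r in caplog.records)

    def test_observed_heterozygosity_from_printed_counts(self, table2_matrices):
        m = table2_matrices["MAP2K4-164"]
        res = observed_heterozygosity(m, "coluzzii")
        assert res.per_locus[0] == pytest.approx(1 / 165)

    def test_het_extremes(self):
        assert observed_heterozygosity(_matrix({"a": [[1], [1]]}), "a").per_locus[0] == 1.0
        assert observed_heterozygosity(_matrix({"a": [[2], [2]]}), "a").per_locus[0] == 0.0

    def test_mean_and_sd_over_loci(self):
        m = _matrix({"a": [[0, 1], [1, 1], [2, 1]]})
        res = observed_heterozygosity(m, "a")
        assert res.mean == pytest.approx(np.mean([1 / 3, 1.0]))
        assert res.sd == pytest.approx(np.std([1 / 3, 1.0], ddof=1))


class TestAssociation:
    def test_two_by_two_hand_value(self):
        m = _matrix({"a": [[0]] * 10, "b": [[2]] * 10})
        res = genotype_association(m, 0)
        assert res.chi2 == pytest.approx(20.0)
        assert res.df == 1

    def test_identical_distributions_give_zero(self):
        m = _matrix({"a": [[0], [1], [2]], "b": [[0], [1], [2]]})
        res = genotype_association(m, 0)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_monomorphic_gives_nan_with_zero_df(self):
        m = _matrix({"a": [[0], [0]], "b": [[0], [0]]})
        res = genotype_association(m, 0)
        assert res.df == 0 and np.isnan(res.p_value)

    @pytest.mark.parametrize("snp", ["MAP2K4-164", "Raf-784", "Raf-851"])
    def test_printed_tables_match_textbook_oracle(self, table2_matrices, snp):
        m = table2_matrices[snp]
        res = genotype_association(m, 0)
        from immunediv.popstats import genotype_table

        chi2, df, p = chi2_oracle(genotype_table(m, 0))
        assert res.chi2 == pytest.approx(chi2, abs=1e-9)
        assert res.df == df
        assert res.p_value == pytest.approx(p, abs=1e-9)

    def test_allelic_mode_collapses_to_two_columns(self):
        m = _matrix({"a": [[0], [1]], "b": [[2], [1]]})
        res = genotype_association(m, 0, allelic=True)
        # allele table [[3,1],[1,3]] -> textbook chi2 = 2
        assert res.chi2 == pytest.approx(2.0)

    def test_null_pvalues_uniform(self):
        # no taxon effect: genotypes drawn from one frequency for both taxa
        rng = np.random.default_rng(5)
        n, L = 60, 2000
        freqs = rng.uniform(0.2, 0.8, L)
        calls = rng.binomial(2, freqs, size=(2 * n, L)).astype(np.int8)
        m = GenotypeMatrix(
            [f"i{k}" for k in range(2 * n)],
            {f"i{k}": ("a" if k < n else "b") for k in range(2 * n)},
            [SnpRecord(chromosome="un", position=i + 1) for i in range(L)],
            calls,
        )
        ps = np.array([genotype_association(m, i).p_value for i in range(L)])
        ps = ps[~np.isnan(ps)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBonferroni:
    def test_threshold_and_flags(self):
        flags, thr = bonferroni_adjust([1e-6, 0.01], m=333)
        assert thr == pytest.approx(0.05 / 333)
        assert flags.tolist() == [True, False]

    def test_single_test_reduces_to_alpha(self):
        flags, thr = bonferroni_adjust([0.04], m=1)
        assert thr == 0.05 and flags[0]

    def test_m_smaller_than_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1, 0.2], m=1)


class TestWcFst:
    def test_fixed_opposite_alleles_give_theta_one(self):
        m = _matrix({"a": [[0]] * 10, "b": [[2]] * 10})
        assert wc_fst_locus(m, ["a", "b"], 0).theta == pytest.approx(1.0)

    def test_identical_populations_give_nonpositive_theta(self):
        block = [[0], [1], [2], [1], [0], [2], [1], [1]]
        m = _matrix({"a": block, "b": [r[:] for r in block]})
        assert wc_fst_locus(m, ["a", "b"], 0).theta <= 0

    def test_monomorphic_gives_nan(self):
        m = _matrix({"a": [[0], [0]], "b": [[0], [0]]})
        assert np.isnan(wc_fst_locus(m, ["a", "b"], 0).theta)

    def test_printed_three_taxon_counts_match_oracle(self, table2_matrices):
        m = table2_matrices["Raf-851"]
        res = wc_fst_locus(m, ["coluzzii", "bamako", "savanna"], 0)
        pops = [m.taxon_calls(t)[:, 0] for t in ("coluzzii", "bamako", "savanna")]
        a, b, c, theta = wc_oracle(pops)
        assert res.a == pytest.approx(a, abs=1e-9)
        assert res.b == pytest.approx(b, abs=1e-9)
        assert res.c == pytest.approx(c, abs=1e-9)
        assert res.theta == pytest.approx(theta, abs=1e-9)

    def test_random_configurations_match_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            r = rng.integers(2, 4)
            pops = {}
            for t in range(r):
                n = int(rng.integers(2, 21))
                p = rng.uniform(0.05, 0.95)
                pops[f"t{t}"] = rng.binomial(2, p, size=(n, 1)).astype(int).tolist()
            m = _matrix(pops)
            res = wc_fst_locus(m, list(pops), 0)
            a, b, c, theta = wc_oracle([np.array(v)[:, 0] for v in pops.values()])
            assert res.a == pytest.approx(a, abs=1e-9)
            if not np.isnan(theta):
                assert res.theta == pytest.approx(theta, abs=1e-9)
            else:
                assert np.isnan(res.theta)

    def test_missing_data_complete_case(self):
        m = _matrix({"a": [[0], [2], [MISSING]], "b": [[2], [0], [1]]})
        res = wc_fst_locus(m, ["a", "b"], 0)
        m2 = _matrix({"a": [[0], [2]], "b": [[2], [0], [1]]})
        assert res.theta == pytest.approx(wc_fst_locus(m2, ["a", "b"], 0).theta)
        assert res.sample_sizes == (2, 3)


class TestWcFstSet:
    def test_single_locus_equals_locus_theta(self):
        m = _matrix({"a": [[0], [1], [2]], "b": [[2], [2], [1]]})
        assert wc_fst_set(m, ["a", "b"], [0]).theta == pytest.approx(
            wc_fst_locus(m, ["a", "b"], 0).theta
        )

    def test_duplicating_loci_leaves_set_theta_unchanged(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(12, 6))
        m = _matrix({"a": calls[:6].tolist(), "b": calls[6:].tolist()})
        base = wc_fst_set(m, ["a", "b"]).theta
        dup = m.subset_loci([0, 1, 2, 3, 4, 5, 0, 1, 2, 3, 4, 5])
        assert wc_fst_set(dup, ["a", "b"]).theta == pytest.approx(base)

    def test_pooled_identical_populations_near_zero(self):
        # same underlying frequencies in both pops -> theta ~ 0 over many loci
        rng = np.random.default_rng(9)
        L = 1000
        freqs = rng.uniform(0.1, 0.9, L)
        blocks = {
            t: rng.binomial(2, freqs, size=(30, L)).astype(int).tolist() for t in ("a", "b")
        }
        m = _matrix(blocks)
        assert abs(wc_fst_set(m, ["a", "b"]).theta) < 0.01

    @pytest.mark.parametrize("F", [0.02, 0.05, 0.10, 0.15])
    def test_balding_nichols_parameter_recovery(self, F):
        m = gen_balding_nichols([50, 50, 50], F, n_loci=2000, seed=int(F * 1000))
        assert wc_fst_set(m, m.taxa).theta == pytest.approx(F, abs=0.015)

    def test_monomorphic_loci_counted_as_excluded(self):
        m = _matrix({"a": [[0, 0], [1, 0]], "b": [[2, 0], [2, 0]]})
        res = wc_fst_set(m, ["a", "b"])
        assert res.n_loci_used == 1 and res.n_excluded == 1


class TestChisqPower:
    def test_zero_effect_gives_alpha(self):
        assert chisq_power(0.0, df=2, n=400, alpha=0.05) == pytest.approx(0.05)

    def test_large_effect_near_one_and_matches_simulation(self):
        power = chisq_power(0.5, df=2, n=400)
        assert power >= 0.999
        # Monte-Carlo check of the noncentral statistic at a moderate effect
        w, df, n = 0.15, 2, 400
        rng = np.random.default_rng(21)
        draws = stats.ncx2.rvs(df, n * w * w, size=20000, random_state=rng)
        crit = stats.chi2.ppf(0.95, df)
        assert chisq_power(w, df, n) == pytest.approx((draws > crit).mean(), abs=0.02)

    def test_power_monotone_in_sample_size(self):
        powers = [chisq_power(0.2, 2, n) for n in (50, 100, 200, 400, 800)]
        assert all(a < b for a, b in zip(powers, powers[1:]))
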