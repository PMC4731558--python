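"""Microsatellite statistics: closed forms, enumeration oracles, EM
parameter recovery and the ENA-corrected differentiation estimator."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from seapopgen.io import GenotypeTable
from seapopgen.mtdna import UndefinedStatistic, _amova_two_level
from seapopgen.msat import (
    _geom_param_from_variance,
    _wc_components,
    allelic_richness,
    bottleneck_test,
    hwe_test,
    ld_test,
    locus_pop_stats,
    null_allele_em,
    pairwise_theta,
    theta_fst,
    theta_fst_ena,
    unbiased_he,
)
from tests.conftest import hwe_genotypes


def table_from_calls(calls_by_pop, loci=("L1",)):
    ids, pops, calls = [], [], []
    for pop, rows in calls_by_pop.items():
        for k, row in enumerate(rows):
            ids.append(f"{pop}{k}")
            pops.append(pop)
            calls.append(list(row))
    return GenotypeTable(ids=ids, population=pops, loci=list(loci), calls=calls)


class TestLocusPopStats:
    def test_all_homozygous(self):
        t = table_from_calls({"P": [[(10, 10)]] * 6})
        df = locus_pop_stats(t)
        assert df.iloc[0]["He"] == 0 and df.iloc[0]["Ho"] == 0
        assert math.isnan(df.iloc[0]["F_IS"])

    def test_all_heterozygous_closed_form(self):
        """n=10, two alleles at 0.5: He = (20/19)*0.5 = 0.526, Ho = 1."""
        t = table_from_calls({"P": [[(10, 12)]] * 10})
        row = locus_pop_stats(t).iloc[0]
        assert row["He"] == pytest.approx(20 / 19 * 0.5)
        assert row["Ho"] == 1.0
        assert row["F_IS"] < 0

    def test_mean_fis_near_zero_under_random_mating(self):
        rng = np.random.default_rng(3)
        fis = []
        for rep in range(60):
            t = hwe_genotypes(50, [10, 12, 14], [0.5, 0.3, 0.2], rng)
            fis.append(locus_pop_stats(t).iloc[0]["F_IS"])
        assert abs(np.mean(fis)) < 0.03


class TestHwe:
    def test_monomorphic_p_one(self):
        t = table_from_calls({"P": [[(10, 10)]] * 8})
        res = hwe_test(t, "L1", "P", n_perm=99, seed=1)
        assert res.p_two_sided == 1.0

    def test_smoothed_p_uniform_under_hwe(self):
        """Randomized permutation p is uniform for random-mating data."""
        ps = []
        for rep in range(200):
            rng = np.random.default_rng(rep + 1)
            t = hwe_genotypes(30, [10, 12, 14, 16], [0.4, 0.3, 0.2, 0.1], rng)
            ps.append(hwe_test(t, "L1", "P", n_perm=99, seed=rep).p_two_sided_smoothed)
        assert sstats.kstest(ps, "uniform").pvalue > 0.01

    def test_null_alleles_produce_heterozygote_deficit(self):
        from seapopgen.simulate import apply_null_alleles

        rng = np.random.default_rng(5)
        hits = 0
        for rep in range(20):
            t = hwe_genotypes(60, [10, 12, 14, 16], [0.4, 0.3, 0.2, 0.1], rng)
            masked = apply_null_alleles(t, 0.4, seed=rep)
            res = hwe_test(masked, "L1", "P", n_perm=99, seed=rep)
            hits += res.p_deficit <= 0.05
        assert hits >= 14  # strong deficit detected in the clear majority


class TestLd:
    def test_duplicated_locus_maximal_association(self):
        rng = np.random.default_rng(2)
        base = hwe_genotypes(40, [10, 12, 14], [0.5, 0.3, 0.2], rng)
        dup = GenotypeTable(
            ids=base.ids, population=base.population, loci=["L1", "L2"],
            calls=[[row[0], row[0]] for row in base.calls],
        )
        p = ld_test(dup, ("L1", "L2"), n_perm=99, seed=3)
        assert p == pytest.approx(1 / 100)

    def test_monomorphic_pair_p_one(self):
        t = table_from_calls(
            {"P": [[(10, 10), (20, 20)]] * 8}, loci=("L1", "L2")
        )
        assert ld_test(t, ("L1", "L2"), n_perm=49, seed=1) == 1.0

    def test_smoothed_p_uniform_for_independent_loci(self):
        ps = []
        for rep in range(200):
            rng = np.random.default_rng(rep + 1000)
            t = hwe_genotypes(
                30, [10, 12, 14, 16], [0.4, 0.3, 0.2, 0.1], rng, n_loci=2
            )
            ps.append(ld_test(t, ("L1", "L2"), n_perm=99, seed=rep, smoothed=True))
        assert sstats.kstest(ps, "uniform").pvalue > 0.01


class TestAllelicRichness:
    def test_full_sample_identity(self):
        t = table_from_calls({"P": [[(10, 12)], [(10, 14)], [(12, 14)]]})
        df = allelic_richness(t, g=6)
        assert df.iloc[0]["Ar"] == pytest.approx(3.0)

    def test_single_allele_gives_one(self):
        t = table_from_calls({"P": [[(10, 10)]] * 5})
        assert allelic_richness(t, g=4).iloc[0]["Ar"] == pytest.approx(1.0)

    def test_matches_exhaustive_subsample_enumeration(self):
        """Gene-copy counts (6,2), g=4: average allele count over all
        C(8,4) subsamples."""
        copies = [10] * 6 + [12] * 2
        calls = [[(copies[2 * i], copies[2 * i + 1])] for i in range(4)]
        t = table_from_calls({"P": calls})
        ar = allelic_richness(t, g=4).iloc[0]["Ar"]
        oracle = np.mean([
            len(set(sub)) for sub in itertools.combinations(copies, 4)
        ])
        assert ar == pytest.approx(oracle, abs=1e-12)

    def test_monotone_in_g(self):
        rng = np.random.default_rng(4)
        t = hwe_genotypes(20, [10, 12, 14, 16, 18], [0.3, 0.25, 0.2, 0.15, 0.1], rng)
        ars = [allelic_richness(t, g=g).iloc[0]["Ar"] for g in (4, 10, 20, 40)]
        assert all(b >= a - 1e-12 for a, b in zip(ars, ars[1:]))

    def test_error_names_undersized_population(self):
        t = table_from_calls({"tiny": [[(10, 12)]] * 3})
        with pytest.raises(UndefinedStatistic, match="tiny"):
            allelic_richness(t, g=10)


class TestNullAlleleEm:
    @staticmethod
    def masked_hwe(n, r, rng, freqs=(0.3, 0.25, 0.2, 0.15, 0.1)):
        alleles = [10, 12, 14, 16, 18]
        calls = []
        for _ in range(n):
            copy = []
            for _c in range(2):
                a = alleles[rng.choice(5, p=list(freqs))]
                copy.append(None if rng.random() < r else a)
            a, b = copy
            if a is None and b is None:
                calls.append([None])
            elif a is None:
                calls.append([(b, b)])
            elif b is None:
                calls.append([(a, a)])
            else:
                calls.append([(min(a, b), max(a, b))])
        return GenotypeTable(
            ids=[f"i{k}" for k in range(n)], population=["P"] * n,
            loci=["L1"], calls=calls,
        )

    def test_hwe_without_nulls_estimates_near_zero(self):
        rng = np.random.default_rng(1)
        t = hwe_genotypes(600, [10, 12, 14, 16], [0.4, 0.3, 0.2, 0.1], rng)
        est = null_allele_em(t, "L1", "P")
        assert est.converged and est.r <= 0.02

    def test_recovers_r_030_at_n_500(self):
        rng = np.random.default_rng(7)
        t = self.masked_hwe(500, 0.3, rng)
        est = null_allele_em(t, "L1", "P")
        assert est.converged
        assert 0.25 <= est.r <= 0.35

    def test_rmse_shrinks_with_sample_size(self):
        """Quadrupling n (125 -> 500) roughly halves the RMSE of r-hat."""
        rng = np.random.default_rng(11)
        rmse = {}
        for n in (125, 500):
            errs = [
                null_allele_em(self.masked_hwe(n, 0.3, rng), "L1", "P").r - 0.3
                for _ in range(40)
            ]
            rmse[n] = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse[500] < 0.75 * rmse[125]

    def test_all_missing_population_errors(self):
        t = GenotypeTable(
            ids=["a1", "a2", "b1", "b2", "b3", "b4", "b5"],
            population=["A", "A", "B", "B", "B", "B", "B"],
            loci=["L1"],
            calls=[[None], [None]] + [[(10, 12)]] * 5,
        )
        with pytest.raises(UndefinedStatistic):
            null_allele_em(t, "L1", "A")


class TestTheta:
    def test_fixed_difference_gives_one(self):
        t = table_from_calls({"A": [[(10, 10)]] * 8, "B": [[(20, 20)]] * 8})
        theta, p = theta_fst(t, ("A", "B"), n_perm=99, seed=1)
        assert theta == pytest.approx(1.0)
        assert p <= 0.05

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(9)
        t = hwe_genotypes(200, [10, 12, 14], [0.5, 0.3, 0.2], rng)
        split = GenotypeTable(
            ids=t.ids, population=["A"] * 100 + ["B"] * 100,
            loci=t.loci, calls=t.calls,
        )
        theta, _ = theta_fst(split, ("A", "B"))
        assert abs(theta) < 0.02

    def test_components_match_hand_formulas(self):
        """Two pops, one biallelic locus: a, b, c recomputed from the
        explicit 1984 expressions written out in the test."""
        t = table_from_calls({
            "A": [[(1, 1)], [(1, 2)], [(1, 2)], [(2, 2)]],
            "B": [[(1, 1)], [(1, 1)], [(1, 2)], [(1, 1)]],
        })
        theta, _ = theta_fst(t, ("A", "B"))
        # hand computation for allele 1 (allele 2 is its mirror)
        n = np.array([4.0, 4.0])
        p = np.array([4 / 8, 7 / 8])
        h = np.array([2 / 4, 1 / 4])
        r = 2
        nbar = 4.0
        nc = (r * nbar - (16 + 16) / (r * nbar)) / (r - 1)
        pbar = (4 * p[0] + 4 * p[1]) / 8
        s2 = (4 * (p[0] - pbar) ** 2 + 4 * (p[1] - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (4 * h[0] + 4 * h[1]) / 8
        a1 = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / 3)
        b1 = (4 / 3) * (pbar * (1 - pbar) - s2 / 2 - (7 / 16) * hbar)
        c1 = hbar / 2
        # both alleles contribute symmetrically at a biallelic locus
        assert theta == pytest.approx((2 * a1) / (2 * (a1 + b1 + c1)), abs=1e-12)
        code_a, code_b, code_c = _wc_components(n, p, h)
        assert (code_a, code_b, code_c) == pytest.approx((a1, b1, c1), abs=1e-12)

    def test_theta_and_amova_phi_concordant_on_same_biallelic_data(self):
        """theta and distance-based Phi_ST rank population pairs alike when
        computed from the same biallelic genotypes (21 pairs)."""
        rng = np.random.default_rng(15)
        pops = [f"P{i}" for i in range(7)]
        n, n_loci = 20, 10
        anc = rng.uniform(0.2, 0.8, n_loci)
        div = np.linspace(0.01, 0.25, 7)  # increasing drift per population
        tables = {}
        for k, pop in enumerate(pops):
            rows = []
            for _ in range(n):
                row = []
                for l in range(n_loci):
                    f = np.clip(anc[l] + rng.normal(0, math.sqrt(div[k] * anc[l] * (1 - anc[l]))), 0.02, 0.98)
                    g = rng.random(2) < f
                    row.append((1 + int(g[0]), 1 + int(g[1])))
                    row[-1] = (min(row[-1]), max(row[-1]))
                rows.append(row)
            tables[pop] = rows
        t = table_from_calls(tables, loci=[f"L{l+1}" for l in range(n_loci)])
        theta_m = pairwise_theta(t).values
        # Phi from gene copies with 0/1 distances, summed over loci
        phi_m = np.zeros((7, 7))
        for i in range(7):
            for j in range(i + 1, 7):
                num = den = 0.0
                for locus in t.loci:
                    a = t.alleles(locus, pops[i])
                    b = t.alleles(locus, pops[j])
                    vals = np.array(a + b)
                    uniq = sorted(set(vals))
                    if len(uniq) < 2:
                        continue
                    D2 = 1.0 - np.eye(len(uniq))
                    hap_idx = np.array([uniq.index(v) for v in vals])
                    labels = np.array([0] * len(a) + [1] * len(b))
                    sa, sw, _ = _amova_two_level(D2, hap_idx, labels, 2)
                    num += sa
                    den += sa + sw
                phi_m[i, j] = phi_m[j, i] = num / den
        iu = np.triu_indices(7, 1)
        rho = sstats.spearmanr(theta_m[iu], phi_m[iu]).statistic
        assert rho > 0.8
        assert np.sign(np.median(theta_m[iu])) == np.sign(np.median(phi_m[iu]))


class TestEna:
    def test_zero_null_rates_reproduce_uncorrected(self):
        rng = np.random.default_rng(21)
        t = hwe_genotypes(60, [10, 12, 14], [0.5, 0.3, 0.2], rng)
        split = GenotypeTable(
            ids=t.ids, population=["A"] * 30 + ["B"] * 30, loci=t.loci, calls=t.calls
        )
        nulls = pd.DataFrame(0.0, index=["L1"], columns=["A", "B"])
        theta, _ = theta_fst(split, ("A", "B"))
        assert theta_fst_ena(split, nulls, ("A", "B")) == pytest.approx(theta, abs=1e-12)

    def test_hand_recomputation_with_augmented_allele(self):
        t = table_from_calls({
            "A": [[(1, 1)], [(1, 2)], [(1, 2)], [(2, 2)]],
            "B": [[(1, 1)], [(1, 1)], [(1, 2)], [(1, 1)]],
        })
        r = pd.DataFrame([[0.2, 0.1]], index=["L1"], columns=["A", "B"])
        got = theta_fst_ena(t, r, ("A", "B"))
        n = np.array([4.0, 4.0])
        rvec = np.array([0.2, 0.1])
        comp = np.zeros(3)
        for p, h in [
            (np.array([0.5, 7 / 8]), np.array([0.5, 0.25])),   # allele 1
            (np.array([0.5, 1 / 8]), np.array([0.5, 0.25])),   # allele 2
        ]:
            comp += _wc_components(n, p * (1 - rvec), h)
        comp += _wc_components(n, rvec, np.zeros(2))
        assert got == pytest.approx(comp[0] / comp.sum(), abs=1e-12)

    def test_missing_estimate_falls_back_with_warning(self):
        t = table_from_calls({
            "A": [[(1, 1)], [(1, 2)], [(1, 2)], [(2, 2)]],
            "B": [[(1, 1)], [(1, 1)], [(1, 2)], [(1, 1)]],
        })
        empty = pd.DataFrame()
        theta, _ = theta_fst(t, ("A", "B"))
        with pytest.warns(UserWarning):
            got = theta_fst_ena(t, empty, ("A", "B"))
        assert got == pytest.approx(theta, abs=1e-12)


class TestBottleneck:
    def test_geometric_variance_mapping(self):
        for var in (10.0, 20.0, 30.0):
            q = _geom_param_from_variance(var)
            assert (1 - q) / q**2 == pytest.approx(var, rel=1e-12)

    def test_monomorphic_loci_error(self):
        t = table_from_calls(
            {"P": [[(10, 10), (20, 20)]] * 10}, loci=("L1", "L2")
        )
        with pytest.raises(UndefinedStatistic):
            bottleneck_test(t, "P", n_iter=100, seed=1)

    def test_heterozygosity_excess_flagged_for_overly_even_frequencies(self):
        """Evenly spread alleles (He high for their allele count) mimic a
        post-bottleneck population and yield small excess p."""
        rng = np.random.default_rng(31)
        rows = []
        for _ in range(25):
            row = []
            for _l in range(4):
                a, b = rng.choice([10, 14, 18], 2)  # 3 equifrequent, well-spread
                row.append((min(a, b), max(a, b)))
            rows.append(row)
        t = table_from_calls({"P": rows}, loci=[f"L{l+1}" for l in range(4)])
        res = bottleneck_test(t, "P", n_iter=3000, seed=2, min_keep=80)
        assert res.p_excess < 0.1
        assert all(s > 0 for s in res.standardized)

    def test_equilibrium_data_not_systematically_significant(self):
        from seapopgen.scenarios import single_population
        from seapopgen.simulate import SimParams, simulate_microsatellites

        scen = single_population()
        prm = SimParams(ne=2000, mu_ms=2.5e-4, p_gsm=0.8)
        ps = []
        for rep in range(8):
            g = simulate_microsatellites(scen, prm, {"P0": 25}, 4, seed=rep + 1)
            try:
                ps.append(bottleneck_test(g, "P0", n_iter=2000, seed=rep, min_keep=60).p_excess)
            except UndefinedStatistic:
                continue
        assert len(ps) >= 5
        assert np.mean([p > 0.05 for p in ps]) >= 0.5


def test_unbiased_he_bounds():
    assert 0 <= unbiased_he([1, 1, 2, 2, 3, 3]) <= 1
    with pytest.raises(UndefinedStatistic):
        unbiased_he([1])
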