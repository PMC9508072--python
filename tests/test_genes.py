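import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pairmeta.genes import (
    MHC_REGION,
    gene_statistic_pvalue,
    monte_carlo_gene_pvalue,
    probit_z,
    run_gene_analysis,
)
from pairmeta.io import GeneModel, map_snps_to_genes
from pairmeta.simulate import SimTruth, build_ld_structure, simulate_pair


def ar1(k, rho):
    idx = np.arange(k)
    return rho ** np.abs(idx[:, None] - idx[None, :])


class TestProbit:
    @pytest.mark.parametrize(
        "p, expect",
        [(0.5, 0.0), (0.05, 1.6448536269514722), (2.7e-6, 4.548615512572751)],
    )
    def test_known_quantiles(self, p, expect):
        assert probit_z(p) == pytest.approx(expect, rel=1e-12)

    def test_strictly_decreasing(self):
        ps = np.logspace(-10, -0.05, 40)
        zs = [probit_z(p) for p in ps]
        assert all(a > b for a, b in zip(zs, zs[1:]))

    def test_log_path_handles_sub_denormal_p(self):
        # p = exp(-800) is far below the smallest positive float
        z = probit_z(None, log_p=-800.0)
        assert 39 < z < 41  # Phi^-1(1 - e^-800) ~ 39.9

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_domain_errors(self, p):
        with pytest.raises(ValueError):
            probit_z(p)

    @given(st.floats(min_value=1e-250, max_value=1.0, exclude_max=True,
                     allow_subnormal=False))
    @settings(deadline=None, max_examples=100)
    def test_round_trip_to_one_sided_tail(self, p):
        z = probit_z(p)
        assert stats.norm.sf(z) == pytest.approx(p, rel=1e-12)


class TestBrownGeneTest:
    def test_single_snp_passes_through(self):
        stat, p = gene_statistic_pvalue([0.05], np.eye(1))
        assert p == pytest.approx(0.05, rel=1e-10)

    def test_independent_snps_exact_chi2(self):
        stat, p = gene_statistic_pvalue([0.5] * 5, np.eye(5))
        assert stat == pytest.approx(5 * stats.chi2.isf(0.5, 1), rel=1e-12)
        assert stat == pytest.approx(2.2747, abs=1e-3)
        assert p == pytest.approx(0.810, abs=1e-3)

    @pytest.mark.parametrize("k", [2, 10, 50])
    def test_identity_ld_matches_chi2_tail(self, k):
        rng = np.random.default_rng(k)
        p = rng.uniform(0.001, 0.999, size=k)
        stat, pg = gene_statistic_pvalue(p, np.eye(k))
        assert pg == pytest.approx(stats.chi2.sf(stat, k), rel=1e-10)

    def test_correlated_fixture_within_monte_carlo_ci(self):
        # k=10 AR(1) rho=0.8, fixed p-vector, vs 10^6-draw empirical oracle
        R = ar1(10, 0.8)
        p_vec = np.array([0.02, 0.4, 0.15, 0.6, 0.01, 0.3, 0.8, 0.05, 0.5,
                          0.25])
        stat, p_brown = gene_statistic_pvalue(p_vec, R)
        p_mc = monte_carlo_gene_pvalue(stat, R, n_draws=10**6, seed=0)
        # the two-moment gamma is an approximation: hold it to the
        # |log10 ratio| < 0.15 calibration band, which dwarfs the MC error
        assert abs(math.log10(p_brown / p_mc)) < 0.15

    def test_monotone_in_each_snp_p(self):
        R = ar1(6, 0.5)
        rng = np.random.default_rng(1)
        base = rng.uniform(0.05, 0.95, size=6)
        _, p0 = gene_statistic_pvalue(base, R)
        for j in range(6):
            better = base.copy()
            better[j] /= 10
            _, p1 = gene_statistic_pvalue(better, R)
            assert p1 <= p0

    def test_domain_and_matrix_errors(self):
        with pytest.raises(ValueError):
            gene_statistic_pvalue([0.0, 0.5], np.eye(2))
        with pytest.raises(ValueError):
            gene_statistic_pvalue([0.5, 0.5], np.array([[1.0, 2.0],
                                                        [2.0, 1.0]]))


class TestMonteCarlo:
    def test_stat_zero_gives_p_near_one(self):
        assert monte_carlo_gene_pvalue(0.0, np.eye(3), 10**4, seed=1) > 0.999

    def test_identity_matches_chi2_within_binomial_se(self):
        stat = 11.07  # chi2_5 upper 5% point
        expect = stats.chi2.sf(stat, 5)
        n = 10**5
        p = monte_carlo_gene_pvalue(stat, np.eye(5), n, seed=2)
        se = math.sqrt(expect * (1 - expect) / n)
        assert abs(p - expect) < 3 * se

    def test_deterministic_given_seed(self):
        R = ar1(4, 0.6)
        a = monte_carlo_gene_pvalue(5.0, R, 10**4, seed=9)
        b = monte_carlo_gene_pvalue(5.0, R, 10**4, seed=9)
        assert a == b

    def test_minimum_draws_enforced(self):
        with pytest.raises(ValueError):
            monte_carlo_gene_pvalue(1.0, np.eye(2), 100, seed=0)


class TestRunGeneAnalysis:
    def test_mhc_overlap_excluded_any_overlap_rule(self, small_ld):
        # gene ending inside the MHC start is excluded; same-span gene on
        # another chromosome is kept
        truth = SimTruth(h2_1=0.0, h2_2=0.0, rg=0.0, n1=1000, n2=1000, seed=1)
        ss, _ = simulate_pair(small_ld, truth)
        ss.table["chrom"] = "6"
        ss.table["pos"] = np.linspace(
            27_900_000, 28_600_000, len(ss), dtype=int
        )
        genes = [
            GeneModel("G_edge", "6", 28_000_000, 28_500_000),
            GeneModel("G_out", "6", 27_900_000, 28_400_000),
        ]
        annot = map_snps_to_genes(ss, genes, 0.0)
        run = run_gene_analysis(ss, annot, genes, small_ld)
        ids = {r.gene_id for r in run.results}
        assert "G_edge" not in ids and run.n_excluded_mhc == 1
        assert "G_out" in ids
        assert MHC_REGION[1] == 28_477_797

    def test_bonferroni_threshold_is_alpha_over_tested(self, small_ld):
        truth = SimTruth(h2_1=0.2, h2_2=0.2, rg=0.0, n1=5000, n2=5000, seed=2)
        ss, _ = simulate_pair(small_ld, truth)
        genes = [
            GeneModel(f"G{b}", "1", int(ss.table.pos[b * 20]),
                      int(ss.table.pos[b * 20 + 19]))
            for b in range(10)
        ]
        annot = map_snps_to_genes(ss, genes, 0.0)
        run = run_gene_analysis(ss, annot, genes, small_ld)
        assert run.n_genes_tested == 10
        assert run.bonferroni_threshold == pytest.approx(0.05 / 10)
        for r in run.results:
            assert r.bonferroni_sig == (r.p < run.bonferroni_threshold)
            assert stats.norm.sf(r.z) == pytest.approx(r.p, rel=1e-9)

    def test_null_simulation_type_i_error(self):
        # 500 genes aligned with LD blocks under h2 = 0
        ld = build_ld_structure(500, 10, (0.0, 0.9), seed=11)
        truth = SimTruth(h2_1=0.0, h2_2=0.0, rg=0.0, n1=50_000, n2=50_000,
                         seed=12)
        ss, _ = simulate_pair(ld, truth)
        pos = ss.table["pos"].to_numpy()
        genes = [
            GeneModel(f"G{b}", "1", int(pos[b * 10]), int(pos[b * 10 + 9]))
            for b in range(500)
        ]
        annot = map_snps_to_genes(ss, genes, 0.0)
        run = run_gene_analysis(ss, annot, genes, ld)
        frac = np.mean([r.p < 0.05 for r in run.results])
        # binomial 99% CI around 0.05 at n=500
        half = 2.576 * math.sqrt(0.05 * 0.95 / 500)
        assert abs(frac - 0.05) < half
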