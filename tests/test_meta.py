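import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pairmeta.genes import GeneResult, probit_z
from pairmeta.meta import (
    cauchy_combine,
    count_recurrence,
    method_concordance,
    novel_signal_filter,
    stouffer_combine,
    stouffer_combine_p,
)
from pairmeta.worked_example import TABLE1, TRAIT_N, reproduce_meta


def _gene(gid, p):
    lp = math.log(p)
    return GeneResult(gene_id=gid, n_snps=5, stat=1.0, p=p, log_p=lp,
                      z=probit_z(p))


class TestStouffer:
    def test_reproduces_published_bdnf_row(self):
        z = [probit_z(4.22e-6), probit_z(1.08e-2)]
        _, p_meta = stouffer_combine(z, [TRAIT_N["SZ"], TRAIT_N["AD"]])
        assert p_meta == pytest.approx(2.75e-7, rel=0.05)

    def test_reproduces_published_med27_row(self):
        _, p_meta = stouffer_combine_p(
            [6.47e-5, 1.425e-5], [TRAIT_N["SZ"], TRAIT_N["ND"]]
        )
        assert p_meta == pytest.approx(8.64e-9, rel=0.05)

    def test_equal_studies_scale_by_sqrt2(self):
        z0 = 1.7
        z_meta, _ = stouffer_combine([z0, z0], [5000, 5000])
        assert z_meta == pytest.approx(math.sqrt(2) * z0, rel=1e-12)

    def test_vanishing_weight_recovers_other_study(self):
        z_meta, _ = stouffer_combine([2.5, 0.3], [10**7, 1])
        assert z_meta == pytest.approx(2.5, abs=1e-3)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            stouffer_combine([1.0, 2.0], [100, 0])

    def test_extreme_z_stays_in_unit_interval(self):
        _, p = stouffer_combine([40.0, 40.0], [1000, 1000])
        assert 0 < p < 1e-300
        # the log-space tail is finite and usable for the probit
        assert math.isfinite(stats.norm.logsf(math.sqrt(2) * 40.0))


class TestCauchy:
    def test_two_half_pvalues_give_half(self):
        assert cauchy_combine([0.5, 0.5], [10, 10]) == pytest.approx(0.5)

    def test_equal_inputs_are_a_fixed_point(self):
        for p0 in (0.9, 0.3, 1e-4):
            assert cauchy_combine([p0, p0], [7, 7]) == pytest.approx(
                p0, rel=1e-9
            )

    def test_tiny_p_matches_high_precision_oracle(self):
        # exact-arithmetic oracle via sympy at 50 digits
        import sympy as sp

        p1, p2 = sp.Rational(1, 10**20), sp.Rational(3, 10)
        T = (sp.tan((sp.Rational(1, 2) - p1) * sp.pi) / 2
             + sp.tan((sp.Rational(1, 2) - p2) * sp.pi) / 2)
        exact = float(sp.N(sp.Rational(1, 2) - sp.atan(T) / sp.pi, 50))
        got = cauchy_combine([1e-20, 0.3], [5, 5])
        assert got == pytest.approx(exact, rel=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            cauchy_combine([0.0, 0.5], [1, 1])
        with pytest.raises(ValueError):
            cauchy_combine([0.5, 1.0], [1, 1])


class TestConcordance:
    def test_identical_vectors_perfect_correlation(self):
        p = np.array([0.1, 0.01, 0.5, 0.9])
        r, lo, hi = method_concordance(p, p)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert hi - lo < 1e-10

    def test_fisher_ci_matches_published_scale(self):
        # at r = 0.9744, n = 18,297 the Fisher-z CI half-width on r is ~7e-4
        r0, n = 0.9744, 18_297
        rng = np.random.default_rng(0)
        # construct vectors with exactly this empirical correlation via
        # Gram-Schmidt
        x = rng.standard_normal(n)
        e = rng.standard_normal(n)
        e -= e @ x / (x @ x) * x
        y = r0 * x / x.std() + math.sqrt(1 - r0**2) * e / e.std()
        pa = 10.0 ** (-(x - x.min() + 0.01))
        pb = 10.0 ** (-(y - y.min() + 0.01))
        r, lo, hi = method_concordance(pa, pb)
        assert r == pytest.approx(r0, abs=1e-6)
        assert hi - lo == pytest.approx(
            2 * (1 - r0**2) * 1.96 / math.sqrt(n - 3), rel=0.05
        )
        assert lo == pytest.approx(0.9737, abs=3e-4)
        assert hi == pytest.approx(0.9751, abs=3e-4)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(3)
        r, _, _ = method_concordance(
            rng.uniform(size=1000), rng.uniform(size=1000)
        )
        assert abs(r) < 0.08

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            method_concordance([0.5, 0.5, 0.5, 0.5], [0.1, 0.2, 0.3, 0.4])


class TestNovelSignalFilter:
    def _meta(self, gid, p_meta):
        from pairmeta.meta import MetaResult

        return MetaResult(gene_id=gid, z_meta=probit_z(p_meta), p_meta=p_meta,
                          log_p_meta=math.log(p_meta), method="stouffer",
                          n1=1.0, n2=1.0)

    def test_bdnf_like_gene_retained(self):
        r1 = {"BDNF": _gene("BDNF", 4.22e-6)}
        r2 = {"BDNF": _gene("BDNF", 1.08e-2)}
        rep = novel_signal_filter(r1, r2, [self._meta("BDNF", 2.75e-7)])
        assert bool(rep.loc[0, "retained"])

    def test_not_nominal_in_one_trait_fails(self):
        r1 = {"G": _gene("G", 1e-7)}
        r2 = {"G": _gene("G", 0.2)}
        rep = novel_signal_filter(r1, r2, [self._meta("G", 1e-9)])
        assert not bool(rep.loc[0, "retained"])
        assert not bool(rep.loc[0, "nominal_both"])

    def test_bonferroni_significant_single_trait_fails(self):
        r1 = {"G": _gene("G", 1e-8)}
        r2 = {"G": _gene("G", 0.01)}
        rep = novel_signal_filter(r1, r2, [self._meta("G", 1e-10)])
        assert not bool(rep.loc[0, "retained"])
        assert not bool(rep.loc[0, "sub_bonf_both"])

    def test_missing_gene_is_consistency_error(self):
        with pytest.raises(ValueError, match="Gmissing"):
            novel_signal_filter({}, {}, [self._meta("Gmissing", 0.5)])

    def test_matches_brute_force_predicate(self):
        rng = np.random.default_rng(8)
        alpha, nominal = 2.7e-6, 0.05
        gids = [f"G{i}" for i in range(300)]
        p1 = 10 ** rng.uniform(-8, 0, 300)
        p2 = 10 ** rng.uniform(-8, 0, 300)
        pm = 10 ** rng.uniform(-9, 0, 300)
        r1 = {g: _gene(g, p) for g, p in zip(gids, p1)}
        r2 = {g: _gene(g, p) for g, p in zip(gids, p2)}
        metas = [self._meta(g, p) for g, p in zip(gids, pm)]
        rep = novel_signal_filter(r1, r2, metas, alpha, nominal)
        expect = (
            (pm < alpha)
            & (p1 < nominal) & (p2 < nominal)
            & (p1 >= alpha) & (p2 >= alpha)
        )
        np.testing.assert_array_equal(rep["retained"].to_numpy(), expect)

    def test_recurrence_counts_across_pairs(self):
        rep_a = pd.DataFrame({"gene_id": ["G1", "G2"],
                              "retained": [True, True]})
        rep_b = pd.DataFrame({"gene_id": ["G1", "G3"],
                              "retained": [True, False]})
        rec = count_recurrence({"pairA": rep_a, "pairB": rep_b})
        assert rec.loc[rec["gene_id"] == "G1", "n_pairs"].item() == 2
        assert "G3" not in set(rec["gene_id"])


def _meta(gid, p_meta):
    from pairmeta.meta import MetaResult

    return MetaResult(gene_id=gid, z_meta=probit_z(p_meta), p_meta=p_meta,
                      log_p_meta=math.log(p_meta), method="stouffer",
                      n1=1.0, n2=1.0)


class TestWorkedExample:
    def test_all_published_rows_pass_the_retained_predicate(self):
        for row in TABLE1:
            assert row.p_meta_published < 2.7e-6, row.gene
            assert row.p_sz < 0.05 and row.p_sud < 0.05, row.gene
            assert row.p_sz >= 2.7e-6 and row.p_sud >= 2.7e-6, row.gene

    def test_non_cannabis_rows_reproduce_within_five_percent(self):
        for row in TABLE1:
            if row.partner == "CUD":
                continue
            assert reproduce_meta(row) == pytest.approx(
                row.p_meta_published, rel=0.05
            ), f"{row.gene}+{row.partner}"
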