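import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pairmeta.genesets import (
    competitive_geneset_test,
    default_covariates,
    run_geneset_collection,
)
from pairmeta.io import GeneSetCollection


def _gene_table(z, n_snps=None, rng=None):
    m = len(z)
    if n_snps is None:
        n_snps = (rng or np.random.default_rng(0)).integers(2, 60, size=m)
    return pd.DataFrame(
        {
            "gene_id": [f"G{i}" for i in range(m)],
            "z": z,
            "n_snps": n_snps,
        }
    )


def _collection(sets):
    return GeneSetCollection(collection_name="toy", sets=sets)


class TestCompetitiveTest:
    def test_constant_membership_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            competitive_geneset_test(np.zeros(10), np.ones(10))

    def test_null_type_i_error_calibrated(self):
        rng = np.random.default_rng(4)
        m, n_sets, size = 2000, 400, 50
        z = rng.standard_normal(m)
        cov = np.column_stack([rng.integers(2, 60, m)]).astype(float)
        ps = []
        for _ in range(n_sets):
            s = np.zeros(m)
            s[rng.choice(m, size, replace=False)] = 1.0
            ps.append(competitive_geneset_test(z, s, cov)[2])
        frac = np.mean(np.array(ps) < 0.05)
        half = 2.576 * math.sqrt(0.05 * 0.95 / n_sets)
        assert abs(frac - 0.05) < half

    def test_enriched_sets_rank_near_the_top(self):
        # per replicate: the typical (median) enriched set must land in the
        # top decile of the 200 set p-values
        rng = np.random.default_rng(5)
        m, n_sets, n_true, size = 2000, 200, 20, 50
        good_reps = 0
        for rep in range(5):
            z = rng.standard_normal(m)
            members = [rng.choice(m, size, replace=False)
                       for _ in range(n_sets)]
            for t in range(n_true):
                z[members[t]] += 0.3       # mean-shift enrichment
            ps = []
            for s_idx in members:
                s = np.zeros(m)
                s[s_idx] = 1.0
                ps.append(competitive_geneset_test(z, s)[2])
            ps = np.array(ps)
            decile = np.quantile(ps, 0.10)
            good_reps += np.median(ps[:n_true]) <= decile
        assert good_reps >= 4

    def test_orthogonal_covariate_leaves_beta_unchanged(self):
        rng = np.random.default_rng(6)
        m = 500
        z = rng.standard_normal(m)
        s = np.zeros(m)
        s[:50] = 1.0
        # covariate orthogonal to [1, s] by explicit projection
        c = rng.standard_normal(m)
        X = np.column_stack([np.ones(m), s])
        c -= X @ np.linalg.lstsq(X, c, rcond=None)[0]
        b0, _, _ = competitive_geneset_test(z, s)
        b1, _, _ = competitive_geneset_test(z, s, c[:, None])
        assert b1 == pytest.approx(b0, abs=1e-8)

    def test_collinear_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(7)
        m = 200
        z = rng.standard_normal(m)
        s = np.zeros(m)
        s[:40] = 1.0
        c = rng.standard_normal(m)
        C = np.column_stack([c, 2 * c])
        with pytest.warns(UserWarning, match="collinear"):
            beta, se, p = competitive_geneset_test(z, s, C)
        assert math.isfinite(beta) and se > 0

    def test_permuting_labels_destroys_enrichment(self):
        rng = np.random.default_rng(8)
        m, size = 1000, 80
        z = rng.standard_normal(m)
        idx = rng.choice(m, size, replace=False)
        z[idx] += 0.5
        s = np.zeros(m)
        s[idx] = 1.0
        _, _, p_real = competitive_geneset_test(z, s)
        assert p_real < 1e-3
        perm_ps = []
        for _ in range(200):
            sp = rng.permutation(s)
            perm_ps.append(competitive_geneset_test(z, sp)[2])
        ks = stats.kstest(perm_ps, "uniform")
        assert ks.pvalue > 0.01


class TestRunCollection:
    def test_bh_qvalues_match_hand_oracle(self):
        # step-up on (0.001, 0.01, 0.02, 0.8) -> (0.004, 0.02, 0.0267, 0.8)
        rng = np.random.default_rng(9)
        m = 400
        z = rng.standard_normal(m)
        tab = _gene_table(z, rng=rng)
        sets = {f"S{i}": [f"G{j}" for j in range(i * 20, i * 20 + 20)]
                for i in range(4)}
        res = run_geneset_collection(tab, _collection(sets))
        p = res["p"].to_numpy()
        order = np.argsort(p)
        m_sets = len(p)
        expect_q = np.empty(m_sets)
        running = 1.0
        for rank, i in enumerate(order[::-1]):
            running = min(running, p[i] * m_sets / (m_sets - rank))
            expect_q[i] = running
        np.testing.assert_allclose(res["q"].to_numpy(), expect_q, rtol=1e-12)

    def test_bh_on_fixed_vector(self):
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests([0.001, 0.01, 0.02, 0.8], method="fdr_bh")
        np.testing.assert_allclose(q, [0.004, 0.02, 0.8 / 30, 0.8],
                                   rtol=1e-10)

    def test_all_p_one_nothing_significant(self):
        m = 100
        tab = _gene_table(np.zeros(m))
        tab["z"] = 0.0
        sets = {"S0": [f"G{j}" for j in range(10)],
                "S1": [f"G{j}" for j in range(50, 70)]}
        res = run_geneset_collection(tab, _collection(sets))
        assert not res["significant"].any()

    def test_undersized_set_skipped_and_reported(self):
        rng = np.random.default_rng(10)
        tab = _gene_table(rng.standard_normal(100), rng=rng)
        sets = {"tiny": ["G0", "G1"],
                "ok": [f"G{j}" for j in range(5, 25)]}
        res = run_geneset_collection(tab, _collection(sets), min_set_size=3)
        tiny = res.set_index("set_id").loc["tiny"]
        assert bool(tiny["skipped"]) and math.isnan(tiny["p"])

    def test_novelty_flag_vs_single_trait_run(self):
        rng = np.random.default_rng(11)
        m = 500
        z = rng.standard_normal(m)
        members = list(range(40))
        z[members] += 1.0
        tab = _gene_table(z, rng=rng)
        sets = {"enriched": [f"G{j}" for j in members],
                "random": [f"G{j}" for j in range(100, 140)]}
        prev = pd.DataFrame({"set_id": ["enriched", "random"],
                             "significant": [False, False]})
        res = run_geneset_collection(tab, _collection(sets), compare_run=prev)
        row = res.set_index("set_id").loc["enriched"]
        assert bool(row["significant"]) and bool(row["novel_vs_single_trait"])

    def test_empty_after_filtering_is_error(self):
        tab = _gene_table(np.zeros(10))
        sets = {"S": ["nope1", "nope2", "nope3"]}
        with pytest.raises(ValueError, match="no set"):
            run_geneset_collection(tab, _collection(sets))

    def test_default_covariates_shape(self):
        tab = _gene_table(np.zeros(10))
        C = default_covariates(tab)
        assert C.shape == (10, 2)
        tab["mac"] = 100.0
        assert default_covariates(tab).shape == (10, 4)
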