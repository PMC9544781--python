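"""TMM normalization, NB exact test, DEG-elimination normalization."""

import numpy as np
import pandas as pd
import pytest

from chronofield.deg import (
    call_degs_per_timepoint,
    ideges_normalize,
    nb_exact_test,
    tmm_factors,
)
from chronofield.matrix import ExpressionMatrix
from chronofield.simulate import SimConfig, simulate_experiment


def nb_counts(rng, mu, phi, size):
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + np.asarray(mu)), size=size)


class TestTmm:
    def test_identical_samples_give_unit_factors(self):
        c = pd.DataFrame({"s1": [100, 200, 50, 400], "s2": [100, 200, 50, 400]})
        np.testing.assert_allclose(tmm_factors(c)["norm_factor"], 1.0)

    def test_pure_depth_change_gives_unit_factors(self):
        c = pd.DataFrame({"s1": [100, 200, 50, 400], "s2": [300, 600, 150, 1200]})
        np.testing.assert_allclose(tmm_factors(c)["norm_factor"], 1.0)

    def test_depth_scaling_invariance(self):
        # scaling every sample together leaves factors exactly unchanged;
        # scaling one sample only moves its factor through the precision
        # weights, which tighten with depth, so that holds approximately
        rng = np.random.default_rng(1)
        base = rng.integers(1, 500, size=(300, 3)).astype(float)
        f0 = tmm_factors(pd.DataFrame(base, columns=["a", "b", "c"]))
        f_all = tmm_factors(pd.DataFrame(7 * base, columns=["a", "b", "c"]))
        np.testing.assert_allclose(f0["norm_factor"], f_all["norm_factor"], rtol=1e-12)
        one = base.copy()
        one[:, 1] *= 7
        f_one = tmm_factors(pd.DataFrame(one, columns=["a", "b", "c"]))
        np.testing.assert_allclose(f0["norm_factor"], f_one["norm_factor"], rtol=0.15)

    def test_composition_bias_recovered(self):
        # 10% of genes 8-fold up in sample2; truth: unchanged genes' relative
        # abundance shrinks by S = sum of relative-abundance change, so the
        # pairwise composition correction is 1/S (±geometric-mean scaling)
        rng = np.random.default_rng(3)
        n = 5000
        base = np.exp(rng.normal(4, 1, n))
        up = np.zeros(n, dtype=bool)
        up[rng.choice(n, n // 10, replace=False)] = True
        mu2 = np.where(up, 8.0 * base, base)
        y1 = rng.poisson(base)
        y2 = rng.poisson(mu2)
        f = tmm_factors(pd.DataFrame({"s1": y1, "s2": y2}))["norm_factor"]
        S = mu2.sum() / base.sum()
        estimated_ratio = f["s2"] / f["s1"]
        assert estimated_ratio == pytest.approx(1.0 / S, rel=0.05)

    def test_disjoint_support_errors(self):
        c = pd.DataFrame({"s1": [5, 0, 9, 0], "s2": [0, 7, 0, 3]})
        with pytest.raises(ValueError, match="no nonzero genes"):
            tmm_factors(c)


class TestExactTest:
    def test_identical_groups_give_p_one(self):
        c = pd.DataFrame(
            np.tile([[10, 10, 10, 10, 10, 10]], (5, 1)) + np.arange(5)[:, None] * 3
        )
        res = nb_exact_test(c, ["a", "a", "a", "b", "b", "b"], dispersion=0.1)
        np.testing.assert_allclose(res["pvalue"], 1.0)

    def test_group_label_swap_symmetry(self):
        rng = np.random.default_rng(2)
        c = pd.DataFrame(nb_counts(rng, 100, 0.1, (200, 8)))
        g1 = ["a"] * 4 + ["b"] * 4
        g2 = ["b"] * 4 + ["a"] * 4
        r1 = nb_exact_test(c, g1, dispersion=0.1)
        r2 = nb_exact_test(c, g2, dispersion=0.1)
        np.testing.assert_allclose(r1["pvalue"], r2["pvalue"], rtol=1e-12)
        assert r1.attrs["groups"] == ("a", "b")
        assert r2.attrs["groups"] == ("b", "a")
        # swapping which columns carry which label negates the fold-change
        swapped = c[list(c.columns[4:]) + list(c.columns[:4])]
        swapped.columns = c.columns
        r3 = nb_exact_test(swapped, g1, dispersion=0.1)
        np.testing.assert_allclose(r1["pvalue"], r3["pvalue"], rtol=1e-12)
        np.testing.assert_allclose(r1["log2fc"], -r3["log2fc"], rtol=1e-12)

    def test_qvalues_dominate_pvalues_and_order_invariance(self):
        rng = np.random.default_rng(4)
        c = pd.DataFrame(nb_counts(rng, 80, 0.1, (300, 8)))
        res = nb_exact_test(c, ["a"] * 4 + ["b"] * 4)
        assert (res["qvalue"] >= res["pvalue"] - 1e-15).all()
        perm = rng.permutation(300)
        res_perm = nb_exact_test(c.iloc[perm], ["a"] * 4 + ["b"] * 4)
        pd.testing.assert_frame_equal(res_perm.sort_index(), res.sort_index())

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(11)
        c = pd.DataFrame(nb_counts(rng, 100, 0.1, (2000, 8)))
        res = nb_exact_test(c, ["a"] * 4 + ["b"] * 4)
        rate = float((res["pvalue"] < 0.05).mean())
        assert 0.03 <= rate <= 0.07
        assert res.attrs["dispersion"] == pytest.approx(0.1, abs=0.03)

    def test_power_for_fourfold_changes(self):
        rng = np.random.default_rng(11)
        mu = np.full(2000, 100.0)
        mu_b = mu.copy()
        mu_b[:200] = 400.0
        ya = nb_counts(rng, mu[:, None], 0.1, (2000, 4))
        yb = nb_counts(rng, mu_b[:, None], 0.1, (2000, 4))
        c = pd.DataFrame(np.hstack([ya, yb]))
        factors = ideges_normalize(c, ["a"] * 4 + ["b"] * 4)
        res = nb_exact_test(c, ["a"] * 4 + ["b"] * 4, factors=factors)
        assert res["is_deg"][:200].mean() >= 0.8

    def test_all_zero_group_errors(self):
        c = pd.DataFrame({"a1": [0, 0], "a2": [0, 0], "b1": [5, 3], "b2": [4, 6]})
        with pytest.raises(ValueError, match="zero counts"):
            nb_exact_test(c, ["a", "a", "b", "b"], dispersion=0.1)

    def test_empty_matrix_gives_empty_result(self):
        c = pd.DataFrame(np.empty((0, 4)), columns=["a1", "a2", "b1", "b2"])
        res = nb_exact_test(c, ["a", "a", "b", "b"])
        assert res.empty


class TestIdeges:
    def test_zero_elimination_threshold_equals_tmm(self):
        rng = np.random.default_rng(6)
        c = pd.DataFrame(nb_counts(rng, 60, 0.1, (400, 8)))
        f_tmm = tmm_factors(c)
        f_ideges = ideges_normalize(c, ["a"] * 4 + ["b"] * 4, elim_fdr=0.0)
        np.testing.assert_allclose(f_ideges["norm_factor"], f_tmm["norm_factor"])

    def test_null_data_step3_close_to_step1(self):
        rng = np.random.default_rng(8)
        c = pd.DataFrame(nb_counts(rng, 100, 0.1, (1500, 8)))
        f1 = tmm_factors(c)["norm_factor"].to_numpy()
        f3 = ideges_normalize(c, ["a"] * 4 + ["b"] * 4)["norm_factor"].to_numpy()
        assert np.max(np.abs(f3 / f1 - 1)) < 0.02

    def test_one_directional_degs_step3_closer_to_truth(self):
        # 25% of genes 4-fold up in group b: the uncorrected TMM factors absorb
        # part of the composition shift; elimination should undo it
        rng = np.random.default_rng(5)
        n = 2000
        mu = np.exp(rng.normal(4, 0.8, n))
        up = np.zeros(n, dtype=bool)
        up[rng.choice(n, n // 4, replace=False)] = True
        mu_b = np.where(up, 4 * mu, mu)
        ya = nb_counts(rng, mu[:, None], 0.1, (n, 4))
        yb = nb_counts(rng, mu_b[:, None], 0.1, (n, 4))
        c = pd.DataFrame(np.hstack([ya, yb]))
        groups = ["a"] * 4 + ["b"] * 4

        # construction truth: effective sizes lib×f must be proportional to
        # the unchanged-gene totals, so f is the unchanged-gene share of
        # each library (geometric-mean scaled)
        lib = c.sum(axis=0).to_numpy()
        truth = np.array([c.iloc[~up, j].sum() / lib[j] for j in range(8)])
        truth /= np.exp(np.mean(np.log(truth)))

        f1 = tmm_factors(c)["norm_factor"].to_numpy()
        f3 = ideges_normalize(c, groups)["norm_factor"].to_numpy()
        err1 = np.abs(np.log(f1 / truth)).sum()
        err3 = np.abs(np.log(f3 / truth)).sum()
        assert err3 < err1


class TestPerTimepoint:
    def test_null_preset_deg_counts_bounded(self):
        cfg = SimConfig(n_genes=300, effect_log2fc=0.0, seed=21, design="exp1")
        m, _ = simulate_experiment(cfg)
        res = call_degs_per_timepoint(m, "FIELD", "CL_CTH")
        assert set(res) == set(int(t) for t in m.timepoints())
        for tp, table in res.items():
            assert table["is_deg"].sum() <= 3 * 0.05 * 300

    def test_effect_preset_degs_peak_at_affected_timepoints(self):
        cfg = SimConfig(
            n_genes=300, seed=9, design="exp1",
            class_fractions={"LIGHT": 0.15},
        )
        m, truth = simulate_experiment(cfg)
        res = call_degs_per_timepoint(m, "FIELD", "CL_CTH")
        counts = {tp: int(t["is_deg"].sum()) for tp, t in res.items()}
        affected = set(truth.affected_timepoints["LIGHT"])
        mean_affected = np.mean([counts[tp] for tp in affected])
        mean_rest = np.mean([c for tp, c in counts.items() if tp not in affected])
        assert mean_affected > 10 * max(mean_rest, 1e-9)

    def test_zero_genes_give_empty_results(self):
        cfg = SimConfig(n_genes=40, seed=1)
        m, _ = simulate_experiment(cfg)
        empty = ExpressionMatrix(m.values.iloc[:0], m.samples.copy(), "counts")
        res = call_degs_per_timepoint(empty, "FIELD", "CL_CTH")
        assert all(table.empty for table in res.values())

    def test_missing_timepoint_skipped_with_warning(self):
        cfg = SimConfig(n_genes=40, seed=1)
        m, _ = simulate_experiment(cfg)
        tp = m.sample_timepoints()
        first = m.timepoints()[0]
        keep = ~((m.samples["condition"] == "CL_CTH") & (tp == first))
        pruned = m.subset_samples(keep.to_numpy())
        with pytest.warns(UserWarning, match="skipped"):
            res = call_degs_per_timepoint(pruned, "FIELD", "CL_CTH")
        assert int(first) not in res
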