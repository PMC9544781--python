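"""Similarity summaries: correlations, rank-sum tests, PCA, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from chronofield.matrix import ExpressionMatrix, compute_rpm, log_transform
from chronofield.simulate import SimConfig, simulate_experiment
from chronofield.summarize import (
    correlation_hclust,
    cut_to_clusters,
    pca_scores,
    per_gene_correlation,
    rank_sum_compare,
    timepoint_condition_correlation,
)


@pytest.fixture(scope="module")
def log_preset():
    cfg = SimConfig(n_genes=1000, seed=17)
    m, truth = simulate_experiment(cfg)
    return log_transform(compute_rpm(m)), truth


def duplicate_conditions_matrix(noise_sd=0.0, seed=0, n_genes=60):
    """Two conditions whose expected profiles are identical."""
    cfg = SimConfig(
        n_genes=n_genes, seed=seed, effect_log2fc=0.0, nb_dispersion=0.0,
        library_size_range=(1.0, 1.0),
    )
    m, _ = simulate_experiment(cfg)
    if noise_sd == 0.0:
        # replace Poisson draws with exact means for the zero-noise case
        truth_cfg = cfg
        _, truth = simulate_experiment(truth_cfg)
        tp = m.sample_timepoints()
        vals = m.values.copy()
        for sid in vals.columns:
            cond = m.samples.loc[sid, "condition"]
            vals[sid] = truth.condition_time_means[(cond, tp[sid])].to_numpy()
        m = ExpressionMatrix(vals, m.samples.copy(), "counts")
    return log_transform(compute_rpm(m))


class TestTimepointCorrelation:
    def test_identical_profiles_give_r_one(self):
        lg = duplicate_conditions_matrix()
        corr = timepoint_condition_correlation(lg, "FIELD", ["FL_FTH"])
        np.testing.assert_allclose(corr["r"], 1.0, atol=1e-12)

    def test_replicate_pairing_combinatorics(self, log_preset):
        lg, _ = log_preset
        corr = timepoint_condition_correlation(lg, "FIELD", ["CL_CTH"])
        per_tp = corr.groupby("timepoint").size()
        assert (per_tp == 16).all()  # 4×4 replicate pairings

    def test_full_simulation_closer_than_square_wave(self, log_preset):
        # condition effects are absent in FL_FTH and present in CL_CTH, so
        # FIELD correlates better with the full simulation at affected times
        lg, truth = log_preset
        corr = timepoint_condition_correlation(lg, "FIELD", ["FL_FTH", "CL_CTH"])
        affected = set().union(*truth.affected_timepoints.values()) - set(
            truth.affected_timepoints["UNREP"]
        )
        sub = corr[corr["timepoint"].isin(affected)]
        means = sub.groupby("condition")["r"].mean()
        assert means["FL_FTH"] > means["CL_CTH"]


class TestRankSum:
    def test_identical_groups_p_one(self):
        res = rank_sum_compare({"a": [1, 1, 1, 1], "b": [1, 1, 1, 1]})
        assert res["pvalue"].iloc[0] == 1.0
        assert res["qvalue"].iloc[0] == 1.0

    def test_complete_separation_extreme_statistic(self):
        res = rank_sum_compare({"lo": [1, 2, 3, 4, 5], "hi": [6, 7, 8, 9, 10]})
        assert res["U"].iloc[0] == 0.0

    def test_symmetry_in_group_order(self):
        g = {"a": [1.0, 3.0, 2.5, 4.0], "b": [2.0, 5.0, 3.5, 1.5]}
        p_ab = rank_sum_compare(g)["pvalue"].iloc[0]
        p_ba = rank_sum_compare(dict(reversed(g.items())))["pvalue"].iloc[0]
        assert p_ab == pytest.approx(p_ba, rel=1e-12)

    def test_null_calibration(self):
        rng = np.random.default_rng(21)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            res = rank_sum_compare(
                {"a": rng.normal(0, 1, 16), "b": rng.normal(0, 1, 16)}
            )
            rejections += res["pvalue"].iloc[0] < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestPerGeneCorrelation:
    def test_self_comparison_counts_nonconstant_genes(self, log_preset):
        lg, _ = log_preset
        table, count = per_gene_correlation(lg, "FIELD", "FIELD")
        np.testing.assert_allclose(table["r"], 1.0, atol=1e-12)
        assert count == len(table)

    def test_independent_time_courses_rarely_pass(self):
        rng = np.random.default_rng(17)
        cfg = SimConfig(n_genes=2000, seed=3, fraction_rhythmic=0.0, effect_log2fc=0.0)
        m, _ = simulate_experiment(cfg)
        lg = log_transform(compute_rpm(m))
        _, count = per_gene_correlation(lg, "FIELD", "CL_CTH")
        assert count <= 0.01 * 2000

    def test_pvalue_matches_t_distribution(self, log_preset):
        lg, _ = log_preset
        table, _ = per_gene_correlation(lg, "FIELD", "FL_FTH")
        n = 13
        r = table["r"].iloc[0]
        t = r * np.sqrt((n - 2) / (1 - r**2))
        assert table["pvalue"].iloc[0] == pytest.approx(2 * stats.t.sf(abs(t), n - 2))


class TestPca:
    def test_duplicated_sample_identical_scores(self, log_preset):
        lg, _ = log_preset
        vals = lg.values.copy()
        samples = lg.samples.copy()
        dup_id = "dup_sample"
        vals[dup_id] = vals.iloc[:, 0]
        dup_meta = samples.iloc[[0]].copy()
        dup_meta.index = [dup_id]
        dup_meta["replicate"] = 99
        dup = ExpressionMatrix(vals, pd.concat([samples, dup_meta]), "log2rpm")
        scores, _, _ = pca_scores(dup, n_components=5)
        np.testing.assert_allclose(
            scores.iloc[0].to_numpy(), scores.loc[dup_id].to_numpy(), atol=1e-8
        )

    def test_variance_fractions_spectral_properties(self, log_preset):
        lg, _ = log_preset
        _, _, var = pca_scores(lg, n_components=10)
        assert var.sum() <= 1.0 + 1e-12
        assert (np.diff(var) <= 1e-12).all()

    def test_reconstruction_at_full_rank(self):
        lg = duplicate_conditions_matrix(seed=2, n_genes=30)
        sub = ExpressionMatrix(
            lg.values.iloc[:, :20], lg.samples.iloc[:20].copy(), "log2rpm"
        )
        X = sub.values.to_numpy().T
        from sklearn.decomposition import PCA

        pca = PCA(svd_solver="full")
        S = pca.fit_transform(X)
        np.testing.assert_allclose(S @ pca.components_ + pca.mean_, X, atol=1e-8)

    def test_pc1_group_means_track_sampling_time(self, log_preset):
        # time of day is circular, so PC1 should align with one harmonic
        # axis of the clock; averaging scores per condition × timepoint
        # removes replicate noise
        lg, _ = log_preset
        scores, _, _ = pca_scores(lg, n_components=2)
        df = scores[["PC1"]].copy()
        df["cond"] = lg.samples["condition"]
        df["tp"] = lg.sample_timepoints()
        gm = df.groupby(["cond", "tp"]).mean().reset_index()
        angle = 2 * np.pi * (gm["tp"] % 1440) / 1440
        best = max(
            abs(stats.spearmanr(gm["PC1"], np.cos(angle)).statistic),
            abs(stats.spearmanr(gm["PC1"], np.sin(angle)).statistic),
        )
        assert best > 0.8


class TestHclust:
    def test_identical_samples_merge_first(self):
        lg = duplicate_conditions_matrix(seed=3, n_genes=40)
        vals = lg.values.iloc[:, :6].copy()
        vals.iloc[:, 1] = vals.iloc[:, 0]  # exact duplicate pair
        m = ExpressionMatrix(vals, lg.samples.iloc[:6].copy(), "log2rpm")
        Z, newick = correlation_hclust(m)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(int(i) for i in Z[0, :2]) == {0, 1}
        assert newick.count("(") == 5  # binary tree over 6 tips

    def test_correlated_pair_merges_before_anticorrelated(self):
        rng = np.random.default_rng(4)
        base = rng.normal(0, 1, 50)
        vals = pd.DataFrame(
            {
                "s1": base,
                "s2": base + rng.normal(0, 0.1, 50),
                "s3": -base,
            },
            index=[f"g{i}" for i in range(50)],
        )
        samples = pd.DataFrame(
            {
                "condition": ["FIELD"] * 3,
                "clock_time": [0, 120, 240],
                "day": 0,
                "replicate": [1, 1, 1],
                "experiment": "exp1",
            },
            index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
        )
        m = ExpressionMatrix(vals, samples, "log2rpm")
        Z, _ = correlation_hclust(m)
        assert set(int(i) for i in Z[0, :2]) == {0, 1}

    def test_cutting_recovers_timepoints_when_rhythm_dominates(self):
        # when most genes cycle with high amplitude and little count noise,
        # cutting the tree into 13 clusters recovers the 13 timepoints
        cfg = SimConfig(
            n_genes=600, seed=17, fraction_rhythmic=0.9, nb_dispersion=0.01,
            rhythm_amplitude_range=(0.5, 0.9), effect_log2fc=0.0,
        )
        m, _ = simulate_experiment(cfg)
        lg = log_transform(compute_rpm(m))
        Z, _ = correlation_hclust(lg)
        found = cut_to_clusters(Z, 13)
        true = pd.factorize(lg.sample_timepoints())[0]
        assert adjusted_rand_score(true, found) >= 0.8
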