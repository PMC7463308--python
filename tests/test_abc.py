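"""Reference-table ABC: summaries, scenario choice, estimation, checking."""

import numpy as np
import pandas as pd
import pytest

from relictgen import abc as rabc
from relictgen.abc import (
    ReferenceTable,
    build_reference,
    cv_estimation,
    cv_model_selection,
    estimate_params,
    generations_to_years,
    model_check_pca,
    model_posterior,
    summarize,
    summarize_counts,
)
from relictgen.coalescent_sim import builtin_scenarios

from conftest import make_matrix, make_popmap


def synthetic_table(rng, n_per=500, scenarios=("A", "B"), sep=0.0, n_stats=4,
                    param_fn=None, stat_fn=None):
    """Hand-built reference table: Gaussian summaries, uniform parameters."""
    rows, params, labels = [], [], []
    for s_i, s in enumerate(scenarios):
        for _ in range(n_per):
            theta = rng.uniform(0, 1, 2) if param_fn is None else param_fn(rng)
            if stat_fn is None:
                stats = rng.normal(s_i * sep, 1.0, n_stats)
            else:
                stats = stat_fn(theta, rng)
            rows.append(stats)
            params.append(theta)
            labels.append(s)
    return ReferenceTable(
        scenarios=np.asarray(labels),
        params=pd.DataFrame(np.asarray(params),
                            columns=[f"p{i}" for i in range(len(params[0]))]),
        summaries=pd.DataFrame(np.asarray(rows),
                               columns=[f"s{i}" for i in range(n_stats)]),
        priors={s: {f"p{i}": (0.0, 1.0) for i in range(len(params[0]))}
                for s in scenarios},
        registry=[f"s{i}" for i in range(n_stats)],
    )


class TestSummaries:
    def test_monomorphic_group(self):
        counts = np.zeros((2, 5))
        counts[1] = [1, 2, 3, 1, 2]
        sv = summarize_counts(counts, np.array([10.0, 10.0]), ["a", "b"])
        s = sv.as_series()
        assert s["propmono_a"] == 1.0
        assert s["meanH_a"] == 0.0

    def test_identical_groups_fst_near_zero(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.3, 0.7, 400)
        c = np.vstack([rng.binomial(40, p), rng.binomial(40, p)]).astype(float)
        sv = summarize_counts(c, np.array([40.0, 40.0]))
        assert abs(sv.as_series()["fst_g0_g1"]) < 0.02

    def test_hand_computed_vector(self):
        # 2 groups x 5 loci, n = 4 genes each; worked by hand
        counts = np.array([[0, 1, 2, 4, 2], [0, 0, 2, 2, 3]], dtype=float)
        sv = summarize_counts(counts, np.array([4.0, 4.0]), ["x", "y"])
        s = sv.as_series()
        assert s["propmono_x"] == pytest.approx(2 / 5)  # loci 0 and 3
        # mean unbiased H for x: loci H = 0, 2*.25*.75*(4/3)=.5, 2*.25=..
        hx = [0.0, 0.5, 2 * 0.5 * 0.5 * 4 / 3, 0.0, 2 * 0.5 * 0.5 * 4 / 3]
        assert s["meanH_x"] == pytest.approx(np.mean(hx))
        assert s["propmono_x_y"] == pytest.approx(1 / 5)  # only locus 0
        # pooled pair monomorphism requires the same fixed state
        counts2 = counts.copy()
        counts2[1, 3] = 0  # x fixed alt, y fixed ref at locus 3 -> polymorphic
        s2 = summarize_counts(counts2, np.array([4.0, 4.0]), ["x", "y"]).as_series()
        assert s2["propmono_x_y"] == pytest.approx(1 / 5)

    def test_matrix_and_count_paths_agree(self):
        rng = np.random.default_rng(1)
        geno = rng.integers(0, 3, size=(12, 30)).astype(np.int8)
        m = make_matrix(geno)
        pmap = make_popmap(12, [6, 6], {"pop0": "G1", "pop1": "G2"})
        sv1 = summarize(m, pmap)
        counts = np.vstack([geno[:6].sum(axis=0), geno[6:].sum(axis=0)])
        sv2 = summarize_counts(counts, np.array([12.0, 12.0]), ["G1", "G2"])
        assert np.allclose(sv1.values, sv2.values)


class TestBuildReference:
    def test_row_count_and_reproducibility(self):
        specs = [builtin_scenarios()["divergence"][k] for k in ("S1", "S2")]
        ref1 = build_reference(specs, 10, 20, np.random.default_rng(5))
        ref2 = build_reference(specs, 10, 20, np.random.default_rng(5))
        assert len(ref1) == 20
        assert np.array_equal(ref1.summaries.to_numpy(),
                              ref2.summaries.to_numpy())
        assert not ref1.summaries.isna().any().any()

    def test_summary_means_stable_across_seeds(self):
        spec = builtin_scenarios()["divergence"]["S1"]
        refs = [build_reference([spec], 150, 40, np.random.default_rng(s))
                for s in (1, 2)]
        for col in ("meanH_SW", "fst_SW_JP"):
            a = refs[0].summaries[col]
            b = refs[1].summaries[col]
            se = np.sqrt(a.var() / len(a) + b.var() / len(b))
            assert abs(a.mean() - b.mean()) < 3 * se


class TestModelPosterior:
    def test_identical_scenarios_are_symmetric(self):
        ref = synthetic_table(np.random.default_rng(2), n_per=2500, sep=0.0)
        res = model_posterior(ref, np.zeros(4), tolerance=0.2, method="rejection")
        assert res["probabilities"]["A"] == pytest.approx(0.5, abs=0.05)

    def test_separable_scenarios_confident(self):
        ref = synthetic_table(np.random.default_rng(3), n_per=800, sep=8.0)
        for method in ("rejection", "mnlogit", "neuralnet"):
            res = model_posterior(ref, np.zeros(4), tolerance=0.1, method=method)
            assert res["probabilities"]["A"] > 0.95
            assert sum(res["probabilities"].values()) == pytest.approx(1.0)

    def test_tolerance_one_rejection_gives_prior_frequencies(self):
        rng = np.random.default_rng(4)
        ref = synthetic_table(rng, n_per=300, sep=1.0)
        res = model_posterior(ref, np.zeros(4), tolerance=1.0, method="rejection")
        assert res["probabilities"]["A"] == pytest.approx(0.5, abs=1e-12)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        ref = synthetic_table(rng, n_per=400, sep=2.0)
        obs = np.array([0.5, -0.2, 0.1, 0.0])
        r1 = model_posterior(ref, obs, 0.1, "rejection")["probabilities"]
        ref2 = ReferenceTable(ref.scenarios, ref.params,
                              ref.summaries * 7.0 + 3.0, ref.priors,
                              ref.registry)
        r2 = model_posterior(ref2, obs * 7.0 + 3.0, 0.1, "rejection")[
            "probabilities"]
        assert r1 == pytest.approx(r2)

    def test_bayes_factors_consistent(self):
        ref = synthetic_table(np.random.default_rng(6), n_per=300, sep=3.0)
        res = model_posterior(ref, np.zeros(4), 0.2, "mnlogit")
        p = res["probabilities"]
        assert res["bayes_factors"][("A", "B")] == pytest.approx(
            (p["A"] + 1e-12) / (p["B"] + 1e-12)
        )


class TestCvModelSelection:
    def test_duplicated_scenarios_rate_half(self):
        ref = synthetic_table(np.random.default_rng(7), n_per=400, sep=0.0)
        res = cv_model_selection(ref, 40, 0.2, "rejection",
                                 np.random.default_rng(0))
        assert res["rate"] == pytest.approx(0.5, abs=0.15)

    def test_separated_scenarios_high_rate_and_row_sums(self):
        ref = synthetic_table(np.random.default_rng(8), n_per=300,
                              scenarios=("A", "B", "C", "D", "E"), sep=6.0)
        res = cv_model_selection(ref, 10, 0.1, "mnlogit",
                                 np.random.default_rng(1))
        assert res["rate"] >= 0.9
        assert (res["confusion"].sum(axis=1) == 10).all()


class TestEstimateParams:
    def test_tolerance_one_no_regression_recovers_prior(self):
        rng = np.random.default_rng(9)
        ref = synthetic_table(rng, n_per=4000, scenarios=("A",), sep=0.0)
        est = estimate_params(ref, np.zeros(4), tolerance=1.0,
                              regression="none")
        assert est.table.loc["p0", "median"] == pytest.approx(0.5, abs=0.03)
        assert est.table.loc["p0", "q2.5"] == pytest.approx(0.025, abs=0.02)
        assert est.table.loc["p0", "q97.5"] == pytest.approx(0.975, abs=0.02)

    def test_noise_free_linear_summaries_collapse_on_truth(self):
        rng = np.random.default_rng(10)
        truth = np.array([0.37, 0.81])
        stat_fn = lambda th, r: np.array(
            [th[0] + th[1], th[0] - th[1], 2 * th[0], 3 * th[1]]
        )
        ref = synthetic_table(rng, n_per=2000, scenarios=("A",),
                              stat_fn=stat_fn)
        est = estimate_params(ref, stat_fn(truth, None), tolerance=0.05,
                              regression="loclinear", transform="none")
        for i, t in enumerate(truth):
            row = est.table.loc[f"p{i}"]
            assert row["median"] == pytest.approx(t, abs=1e-6)
            assert row["q97.5"] - row["q2.5"] < 0.01  # < 1% of prior range
        # the logit transform keeps the median but widens slightly (curvature)
        est_l = estimate_params(ref, stat_fn(truth, None), tolerance=0.05,
                                regression="loclinear", transform="logit")
        for i, t in enumerate(truth):
            assert est_l.table.loc[f"p{i}", "median"] == pytest.approx(t, abs=0.01)

    def test_estimates_within_prior_bounds(self):
        rng = np.random.default_rng(11)
        ref = synthetic_table(rng, n_per=500, scenarios=("A",), sep=0.0)
        est = estimate_params(ref, 50 * np.ones(4), tolerance=0.05)
        assert ((est.table >= 0.0) & (est.table <= 1.0)).all().all()

    def test_multi_scenario_table_rejected(self):
        ref = synthetic_table(np.random.default_rng(12), n_per=50)
        with pytest.raises(ValueError, match="single scenario"):
            estimate_params(ref, np.zeros(4))


class TestCvEstimation:
    def test_uninformative_and_informative_errors(self):
        rng = np.random.default_rng(13)
        noise = synthetic_table(rng, n_per=1500, scenarios=("A",), sep=0.0)
        err_noise = cv_estimation(noise, 40, [0.1], ["loclinear"],
                                  np.random.default_rng(2))
        linear = synthetic_table(
            rng, n_per=1500, scenarios=("A",),
            stat_fn=lambda th, r: np.array([th[0], th[1], th[0] + th[1],
                                            th[0] - th[1]]),
        )
        err_lin = cv_estimation(linear, 40, [0.1], ["loclinear"],
                                np.random.default_rng(3))
        assert (err_noise["error"] > 0).all()
        assert err_noise["error"].mean() == pytest.approx(1.0, abs=0.35)
        assert (err_lin["error"] < 0.05).all()
        assert np.isfinite(err_lin["error"]).all()


class TestModelCheck:
    def test_observed_at_cloud_mean_inside(self):
        rng = np.random.default_rng(14)
        ref = synthetic_table(rng, n_per=800, scenarios=("A",), sep=0.0)
        post = rng.normal(0, 0.5, size=(200, 4))
        res = model_check_pca(ref, post, np.zeros(4))
        assert res["inside_prior"] and res["inside_posterior"]

    def test_displaced_observation_outside(self):
        rng = np.random.default_rng(15)
        ref = synthetic_table(rng, n_per=800, scenarios=("A",), sep=0.0)
        post = rng.normal(0, 1, size=(200, 4))
        res = model_check_pca(ref, post, 10.0 * np.ones(4))
        assert not res["inside_prior"]

    def test_projection_preserves_centroid_distance_ranks(self):
        # 3 summaries lying near a 2-D plane: PCA distances to the centroid
        # should preserve the full-space rank order
        rng = np.random.default_rng(16)
        z = rng.normal(size=(300, 2))
        X = np.column_stack([z[:, 0], z[:, 1], z[:, 0] + z[:, 1]
                             + rng.normal(0, 0.01, 300)])
        ref = ReferenceTable(
            np.array(["A"] * 300),
            pd.DataFrame({"p0": rng.uniform(size=300)}),
            pd.DataFrame(X, columns=["s0", "s1", "s2"]),
            {"A": {"p0": (0, 1)}}, ["s0", "s1", "s2"],
        )
        from scipy.stats import spearmanr

        res = model_check_pca(ref, X[:10], X[0])
        Z = (X - X.mean(0)) / X.std(0)
        full = np.linalg.norm(Z - Z.mean(0), axis=1)
        proj = np.linalg.norm(res["prior_coords"]
                              - res["prior_coords"].mean(0), axis=1)
        assert spearmanr(full, proj).statistic > 0.99


class TestUnits:
    def test_study_scale_conversion(self):
        assert generations_to_years(6.39e5) == pytest.approx(6.39e6)

    def test_zero_and_linearity(self):
        assert generations_to_years(0) == 0
        a, b = 123.0, 77.0
        assert generations_to_years(a + b) == pytest.approx(
            generations_to_years(a) + generations_to_years(b)
        )
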