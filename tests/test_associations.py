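import numpy as np
import pandas as pd
import pytest

from dysbiokit.associations import (
    RandomInterceptLMM,
    bh_adjust,
    build_design,
    differential_abundance,
    residualize,
    spearman_network,
)
from dysbiokit.profiles import AbundanceTable, prevalence_variance_filter
from dysbiokit.synthetic import CohortConfig, simulate_cohort


def _simulate_lmm(rng, n_subj=20, m=5, beta=(1.0, 0.5, -0.8), sigma_b=0.7, sigma_e=0.5):
    groups = np.repeat(np.arange(n_subj), m)
    x = np.column_stack(
        [np.ones(n_subj * m), rng.normal(size=n_subj * m), rng.integers(0, 2, n_subj * m)]
    )
    y = (
        x @ np.asarray(beta)
        + np.repeat(rng.normal(0, sigma_b, n_subj), m)
        + rng.normal(0, sigma_e, n_subj * m)
    )
    return x, y, groups


class TestRandomInterceptLMM:
    def test_zero_subject_variance_reduces_to_ols(self, rng):
        x, y, groups = _simulate_lmm(rng, sigma_b=0.0)
        fit = RandomInterceptLMM().fit(x, y, groups)
        ols = np.linalg.lstsq(x, y, rcond=None)[0]
        assert fit.sigma2_subject_ < 0.05
        assert np.allclose(fit.coef_, ols, atol=1e-2)
        # with theta pinned at zero the GLS solution IS the OLS solution
        fit0 = RandomInterceptLMM(theta_bounds=(1e-12, 1e-11)).fit(x, y, groups)
        assert np.allclose(fit0.coef_, ols, atol=1e-6)

    def test_reml_objective_beats_dense_grid(self, rng):
        """The profiled optimum is at least as good as a 1,000-point theta
        grid (the independent oracle for the 1-D search)."""
        for _ in range(3):
            x, y, groups = _simulate_lmm(rng, n_subj=12, m=4)
            model = RandomInterceptLMM().fit(x, y, groups)
            grid = np.logspace(-8, 8, 1000)
            oracle = min(model.reml_criterion(t, x, y, groups) for t in grid)
            assert model.reml_criterion_ <= oracle + 1e-6

    def test_matches_statsmodels_mixedlm(self, rng):
        import statsmodels.api as sm

        x, y, groups = _simulate_lmm(rng)
        fit = RandomInterceptLMM().fit(x, y, groups)
        ref = sm.MixedLM(y, x, groups=groups).fit(reml=True)
        assert np.allclose(fit.coef_, ref.fe_params, atol=1e-4)
        assert fit.sigma2_resid_ == pytest.approx(float(ref.scale), rel=1e-3)
        assert fit.sigma2_subject_ == pytest.approx(
            float(np.asarray(ref.cov_re)[0, 0]), rel=1e-2, abs=1e-4
        )

    def test_coefficient_recovery_is_nearly_unbiased(self, rng):
        """Balanced two-group design: mean estimate within 5% of the true
        effect across replicates."""
        beta_hat = []
        for _ in range(200):
            groups = np.repeat(np.arange(50), 6)
            x = np.column_stack([np.ones(300), np.tile([0, 0, 0, 1, 1, 1], 50)])
            y = x @ np.array([0.5, 1.0]) + np.repeat(rng.normal(0, 0.7, 50), 6) + rng.normal(0, 0.5, 300)
            beta_hat.append(RandomInterceptLMM().fit(x, y, groups).coef_[1])
        assert abs(np.mean(beta_hat) - 1.0) < 0.05

    def test_rank_deficient_design_names_columns(self, rng):
        x = pd.DataFrame(
            {"intercept": 1.0, "a": rng.normal(size=20), "a_copy": 0.0}
        )
        x["a_copy"] = x["a"]
        with pytest.raises(ValueError, match="a_copy"):
            RandomInterceptLMM().fit(x, rng.normal(size=20), np.repeat([0, 1], 10))

    def test_conditional_residuals_orthogonal_to_design(self, rng):
        x, y, groups = _simulate_lmm(rng)
        fit = RandomInterceptLMM().fit(x, y, groups)
        assert np.abs(fit.resid_ @ x).max() < 1e-8

    def test_wald_outputs_shaped_and_finite(self, rng):
        x, y, groups = _simulate_lmm(rng)
        fit = RandomInterceptLMM().fit(x, y, groups)
        assert fit.pvalues_.shape == (3,)
        assert np.isfinite(fit.pvalues_).all()


class TestBH:
    def test_hand_step_up_example(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestDifferentialAbundance:
    def test_planted_taxa_recovered(self):
        cohort = simulate_cohort(
            CohortConfig(n_subjects_per_group={"nonIBD": 10, "UC": 5, "CD": 5}, seed=3)
        )
        table = prevalence_variance_filter(cohort.taxa_table)
        results = differential_abundance(table, cohort.metadata)
        truth = set(cohort.truth_depleted) | set(cohort.truth_enriched)
        hits = set(
            results[(results["q"] < 0.05) & results["term"].eq("dysbiotic[CD]")]["feature"]
        )
        assert len(hits & truth) / len(truth) >= 0.9

    def test_signs_match_planted_direction(self):
        cohort = simulate_cohort(
            CohortConfig(n_subjects_per_group={"nonIBD": 8, "CD": 6}, seed=5)
        )
        results = differential_abundance(cohort.taxa_table, cohort.metadata)
        cd = results[results["term"] == "dysbiotic[CD]"].set_index("feature")
        dep = cd.loc[cohort.truth_depleted, "coef"]
        enr = cd.loc[cohort.truth_enriched, "coef"]
        assert (dep < 0).mean() > 0.9
        assert (enr > 0).mean() > 0.9


class TestResidualize:
    def test_short_series_subjects_dropped(self, small_cohort):
        meta = small_cohort.metadata
        counts = meta.groupby("subject_id").size()
        res = residualize(small_cohort.taxa_table, meta, min_samples_per_subject=20)
        kept_subjects = meta.set_index("sample_id").loc[res.columns, "subject_id"].unique()
        assert all(counts[s] >= 20 for s in kept_subjects)

    def test_subject_offsets_removed(self, rng):
        # planted subject offsets dominate the raw values but not the residuals
        n_subj, m = 10, 6
        meta = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n_subj * m)],
                "subject_id": np.repeat([f"u{i}" for i in range(n_subj)], m),
                "week": np.tile(np.arange(m) * 2.0, n_subj),
                "diagnosis": "nonIBD",
                "dysbiotic": False,
            }
        )
        values = np.repeat(rng.normal(0, 3.0, n_subj), m) + rng.normal(0, 0.3, n_subj * m)
        table = AbundanceTable(
            pd.DataFrame([values - values.min() + 0.1], index=["f"],
                         columns=meta["sample_id"])
        )
        res = residualize(table, meta)
        raw_between = pd.Series(values, index=meta["subject_id"].to_numpy()).groupby(level=0).mean().var()
        res_between = res.iloc[0].groupby(meta.set_index("sample_id")["subject_id"]).mean().var()
        assert res_between < raw_between / 50

    def test_pure_noise_residuals_close_to_centered_input(self, rng):
        meta = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(40)],
                "subject_id": np.repeat([f"u{i}" for i in range(8)], 5),
                "week": np.tile(np.arange(5) * 2.0, 8),
                "diagnosis": "nonIBD",
                "dysbiotic": False,
            }
        )
        noise = rng.normal(5.0, 1.0, 40)
        table = AbundanceTable(
            pd.DataFrame([noise], index=["f"], columns=meta["sample_id"])
        )
        res = residualize(table, meta).iloc[0].to_numpy()
        centered = noise - noise.mean()
        assert np.corrcoef(res, centered)[0, 1] > 0.9


class TestSpearmanNetwork:
    def test_duplicated_feature_reaches_rho_one(self, rng):
        shared = rng.normal(size=30)
        a = pd.DataFrame([shared, rng.normal(size=30)], index=["dup", "noiseA"],
                         columns=[f"m{i}" for i in range(30)])
        b = pd.DataFrame([shared, rng.normal(size=30)], index=["dup_b", "noiseB"],
                         columns=[f"m{i}" for i in range(30)])
        net = spearman_network({"A": a, "B": b})
        edge = net.edges[(net.edges["source"] == "dup") & (net.edges["target"] == "dup_b")]
        assert len(edge) == 1
        assert edge.iloc[0]["rho"] == pytest.approx(1.0)

    def test_all_null_residuals_produce_almost_no_edges(self, rng):
        cols = [f"m{i}" for i in range(40)]
        a = pd.DataFrame(rng.normal(size=(60, 40)), columns=cols,
                         index=[f"a{i}" for i in range(60)])
        b = pd.DataFrame(rng.normal(size=(60, 40)), columns=cols,
                         index=[f"b{i}" for i in range(60)])
        net = spearman_network({"A": a, "B": b})
        # BH at q<0.05 over an all-null family rejects anything at all with
        # probability <= ~0.05
        assert len(net.edges) <= 3

    def test_top_k_budget_and_ranking(self, rng):
        common = rng.normal(size=(12, 30))
        a = pd.DataFrame(common + rng.normal(0, 0.3, (12, 30)),
                         index=[f"fa{i}" for i in range(12)],
                         columns=[f"m{i}" for i in range(30)])
        b = pd.DataFrame(common + rng.normal(0, 0.3, (12, 30)),
                         index=[f"fb{i}" for i in range(12)],
                         columns=[f"m{i}" for i in range(30)])
        net = spearman_network({"A": a, "B": b}, top_k=5)
        assert len(net.edges) == 5
        assert (np.diff(net.edges["p"].to_numpy()) >= -1e-15).all()

    def test_q_monotone_in_p_within_pair(self, rng):
        a = pd.DataFrame(rng.normal(size=(10, 25)), index=[f"fa{i}" for i in range(10)],
                         columns=[f"m{i}" for i in range(25)])
        b = pd.DataFrame(rng.normal(size=(10, 25)), index=[f"fb{i}" for i in range(10)],
                         columns=[f"m{i}" for i in range(25)])
        net = spearman_network({"A": a, "B": b}, fdr_standard=1.1, top_k=10**6)
        e = net.edges.sort_values("p")
        assert (np.diff(e["q"].to_numpy()) >= -1e-12).all()

    def test_hub_flagging(self, rng):
        hub_vals = rng.normal(size=40)
        a = pd.DataFrame([hub_vals], index=["hub"], columns=[f"m{i}" for i in range(40)])
        b = pd.DataFrame(
            hub_vals + rng.normal(0, 0.1, (25, 40)),
            index=[f"fb{i}" for i in range(25)],
            columns=[f"m{i}" for i in range(40)],
        )
        net = spearman_network({"A": a, "B": b}, hub_degree=20)
        assert "hub" in net.hubs

    def test_pairs_with_too_few_samples_skipped(self, rng):
        a = pd.DataFrame(rng.normal(size=(3, 5)), index=list("xyz"),
                         columns=[f"m{i}" for i in range(5)])
        b = pd.DataFrame(rng.normal(size=(3, 5)), index=list("uvw"),
                         columns=[f"m{i}" for i in range(5)])
        net = spearman_network({"A": a, "B": b}, min_samples=8)
        assert len(net.edges) == 0

    def test_dysbiosis_mediated_edges_vanish_after_adjustment(self):
        """Cross-type correlations driven solely by the latent dysbiosis
        state survive the unadjusted residualisation but are removed when
        dysbiosis is included as a covariate."""
        cohort = simulate_cohort(
            CohortConfig(n_subjects_per_group={"nonIBD": 8, "CD": 8}, seed=17)
        )
        meta = cohort.metadata
        taxa = prevalence_variance_filter(cohort.taxa_table)
        nets = {}
        for adjusted in (False, True):
            res_a = residualize(taxa, meta, adjust_for_dysbiosis=adjusted,
                                transform="arcsinsqrt")
            res_b = residualize(cohort.coupled_table, meta,
                                adjust_for_dysbiosis=adjusted, transform="log")
            shared = res_a.columns.intersection(res_b.columns)
            nets[adjusted] = spearman_network(
                {"MGX": res_a[shared], "MBX": res_b[shared]}, top_k=10**6
            )
        responsive = set(cohort.truth_depleted) | set(cohort.truth_enriched)
        coupled_responsive = {f"metabolite{i:03d}" for i in range(16)}

        def mediated_edges(net):
            e = net.edges
            fwd = e["source"].isin(responsive) & e["target"].isin(coupled_responsive)
            rev = e["source"].isin(coupled_responsive) & e["target"].isin(responsive)
            return (fwd | rev).sum()

        assert mediated_edges(nets[False]) > 10
        assert mediated_edges(nets[True]) < mediated_edges(nets[False]) / 2


class TestBuildDesign:
    def test_nested_dysbiosis_columns(self, small_cohort):
        design = build_design(small_cohort.metadata)
        assert "dysbiotic[CD]" in design.columns
        assert "diagnosis[UC]" in design.columns
        assert (design["intercept"] == 1.0).all()

    def test_all_zero_nested_term_dropped(self):
        meta = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c", "d"],
                "subject_id": ["u1", "u1", "u2", "u2"],
                "week": [0.0, 2.0, 0.0, 2.0],
                "diagnosis": ["CD", "CD", "nonIBD", "nonIBD"],
                "dysbiotic": [True, False, False, False],
            }
        )
        design = build_design(meta)
        assert "dysbiotic[CD]" in design.columns
        assert "dysbiotic[nonIBD]" not in design.columns
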