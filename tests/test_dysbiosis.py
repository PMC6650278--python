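import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from skbio.stats.distance import DistanceMatrix

from dysbiokit.dissimilarity import bray_curtis
from dysbiokit.dysbiosis import (
    DysbiosisClassifier,
    build_reference_set,
    censored_exponential_mean,
    classify_dysbiosis,
    cross_type_concordance,
    dysbiosis_score,
    dysbiosis_scores,
    dysbiosis_threshold,
    extract_episodes,
    kaplan_meier,
    score_against_external_reference,
)
from dysbiokit.synthetic import CohortConfig, simulate_cohort


def _meta(sample_ids, subjects, weeks, diagnoses):
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subject_id": subjects,
            "week": weeks,
            "diagnosis": diagnoses,
        }
    )


class TestReferenceSet:
    META = _meta(
        ["a", "b", "c", "d"],
        ["u1", "u1", "u2", "u3"],
        [22.0, 20.0, 30.0, 30.0],
        ["nonIBD", "nonIBD", "CD", "nonIBD"],
    )

    def test_after_min_week_included(self):
        assert "a" in build_reference_set(self.META)

    def test_exact_boundary_excluded(self):
        assert "b" not in build_reference_set(self.META)

    def test_ibd_samples_excluded(self):
        assert "c" not in build_reference_set(self.META)

    def test_empty_reference_errors(self):
        meta = self.META.assign(diagnosis=["CD"] * 4)
        with pytest.raises(ValueError, match="empty reference"):
            build_reference_set(meta)


class TestScore:
    def test_identical_to_reference_scores_zero(self):
        ids = ["q", "r1", "r2"]
        dm = DistanceMatrix(np.zeros((3, 3)), ids=ids)
        meta = _meta(ids, ["u0", "u1", "u2"], [0, 30, 30], ["CD", "nonIBD", "nonIBD"])
        assert dysbiosis_score("q", ["r1", "r2"], dm, meta) == 0.0

    def test_odd_count_median(self):
        ids = ["q", "r1", "r2", "r3"]
        d = np.zeros((4, 4))
        for i, v in enumerate([0.2, 0.4, 0.9], start=1):
            d[0, i] = d[i, 0] = v
        dm = DistanceMatrix(d, ids=ids)
        meta = _meta(ids, ["u0", "u1", "u2", "u3"], [0, 30, 30, 30],
                     ["CD", "nonIBD", "nonIBD", "nonIBD"])
        assert dysbiosis_score("q", ["r1", "r2", "r3"], dm, meta) == pytest.approx(0.4)

    def test_own_subject_reference_excluded(self):
        # q's own subject contributes the extreme reference value 0.9:
        # with it the median is 0.4, without it 0.3
        ids = ["q", "own", "r1", "r2"]
        d = np.zeros((4, 4))
        for i, v in enumerate([0.9, 0.2, 0.4], start=1):
            d[0, i] = d[i, 0] = v
        dm = DistanceMatrix(d, ids=ids)
        meta = _meta(ids, ["u0", "u0", "u1", "u2"], [0, 30, 30, 30],
                     ["CD", "nonIBD", "nonIBD", "nonIBD"])
        with_own = float(np.median([0.9, 0.2, 0.4]))
        assert with_own == pytest.approx(0.4)
        assert dysbiosis_score("q", ["own", "r1", "r2"], dm, meta) == pytest.approx(0.3)

    def test_all_references_own_subject_errors(self):
        ids = ["q", "own"]
        dm = DistanceMatrix(np.array([[0.0, 0.5], [0.5, 0.0]]), ids=ids)
        meta = _meta(ids, ["u0", "u0"], [0, 30], ["CD", "CD"])
        with pytest.raises(ValueError, match="share"):
            dysbiosis_score("q", ["own"], dm, meta)

    def test_invariant_to_reference_order_and_query_duplication(self):
        ids = ["q", "qdup", "r1", "r2", "r3"]
        rng = np.random.default_rng(0)
        d = np.zeros((5, 5))
        iu, ju = np.triu_indices(5, k=1)
        vals = rng.uniform(0.1, 0.9, len(iu))
        d[iu, ju] = d[ju, iu] = vals
        d[0, 1] = d[1, 0] = 0.0  # duplicate of the query
        dm = DistanceMatrix(d, ids=ids)
        meta = _meta(ids, ["u0", "u0", "u1", "u2", "u3"], [0, 0, 30, 30, 30],
                     ["CD", "CD", "nonIBD", "nonIBD", "nonIBD"])
        s1 = dysbiosis_score("q", ["r1", "r2", "r3"], dm, meta)
        s2 = dysbiosis_score("q", ["r3", "r1", "r2"], dm, meta)
        assert s1 == s2
        # and the vectorised path agrees
        assert dysbiosis_scores(dm, meta, ["r1", "r2", "r3"])["q"] == pytest.approx(s1)


class TestThresholdAndClassification:
    def test_type7_percentile(self):
        scores = pd.Series(np.arange(0.1, 1.05, 0.1), index=[f"s{i}" for i in range(10)])
        meta = _meta(list(scores.index), [f"u{i}" for i in range(10)], [30] * 10,
                     ["nonIBD"] * 10)
        assert dysbiosis_threshold(scores, meta) == pytest.approx(0.91)

    def test_all_equal_scores(self):
        scores = pd.Series([0.3, 0.3], index=["a", "b"])
        meta = _meta(["a", "b"], ["u1", "u2"], [30, 30], ["nonIBD"] * 2)
        assert dysbiosis_threshold(scores, meta) == pytest.approx(0.3)

    def test_no_non_ibd_errors(self):
        scores = pd.Series([0.3], index=["a"])
        meta = _meta(["a"], ["u1"], [30], ["CD"])
        with pytest.raises(ValueError, match="non-IBD"):
            dysbiosis_threshold(scores, meta)

    def test_tie_at_threshold_is_not_dysbiotic(self):
        labels = classify_dysbiosis(pd.Series([0.5, 0.5000001]), 0.5)
        assert list(labels) == [False, True]

    def test_nonibd_fraction_near_ten_percent(self):
        cohort = simulate_cohort(
            CohortConfig(n_subjects_per_group={"nonIBD": 15}, seed=21)
        )
        clf = DysbiosisClassifier().fit(cohort.taxa_table, cohort.metadata)
        frac = clf.labels_.mean()
        assert abs(frac - 0.10) < 0.02


class TestExternalReference:
    def test_external_equal_to_cohort_reproduces_median_scoring(self, small_cohort):
        table = small_cohort.taxa_table
        meta = small_cohort.metadata
        ref_ids = build_reference_set(meta)
        external = table.subset_samples(ref_ids)
        result, rho = score_against_external_reference(table, meta, external)
        # plain median against the same profiles (no own-subject exclusion)
        dm = bray_curtis(table)
        idx = {s: i for i, s in enumerate(dm.ids)}
        expected = np.median(
            dm.data[np.ix_([idx[s] for s in result.scores.index], [idx[r] for r in ref_ids])],
            axis=1,
        )
        assert np.allclose(result.scores.to_numpy(), expected, atol=1e-12)
        assert rho > 0.95

    def test_permuting_external_order_changes_nothing(self, small_cohort):
        table = small_cohort.taxa_table
        meta = small_cohort.metadata
        ref_ids = build_reference_set(meta)
        a, _ = score_against_external_reference(table, meta, table.subset_samples(ref_ids))
        b, _ = score_against_external_reference(
            table, meta, table.subset_samples(ref_ids[::-1])
        )
        assert a.scores.equals(b.scores)

    def test_independent_same_population_reference_concordant(self):
        """Scoring against held-out same-population reference subjects gives
        concordant scores and classifications (high Spearman rho, odds >> 1)."""
        cohort = simulate_cohort(
            CohortConfig(n_subjects_per_group={"nonIBD": 24, "UC": 8, "CD": 8}, seed=7)
        )
        meta = cohort.metadata
        held_out = [f"nonIBD-{i:03d}" for i in range(12, 24)]
        ext_meta = meta[meta["subject_id"].isin(held_out)]
        study_meta = meta[~meta["subject_id"].isin(held_out)].reset_index(drop=True)
        study_table = cohort.taxa_table.subset_samples(study_meta["sample_id"])
        ref = cohort.taxa_table.subset_samples(build_reference_set(ext_meta))
        result, rho = score_against_external_reference(study_table, study_meta, ref)
        internal = DysbiosisClassifier().fit(study_table, study_meta)
        pairs = pd.DataFrame(
            {"sample_a": internal.labels_.index, "sample_b": internal.labels_.index}
        )
        odds, p, _ = cross_type_concordance(
            internal.labels_, result.labels[internal.labels_.index], pairs
        )
        assert rho > 0.8
        assert odds > 10


class TestEpisodes:
    def _frame(self, weeks, states):
        n = len(weeks)
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "subject_id": ["u1"] * n,
                "week": weeks,
                "diagnosis": ["CD"] * n,
                "dysbiotic": states,
            }
        )

    def test_series_starting_dysbiotic_excluded_from_durations(self):
        eps = extract_episodes(self._frame([0, 2, 4], [True, True, False]))
        assert (eps["kind"] != "duration").all()

    def test_complete_duration(self):
        eps = extract_episodes(self._frame([0, 2, 4, 6], [False, True, True, False]))
        dur = eps[eps["kind"] == "duration"]
        assert len(dur) == 1
        assert dur.iloc[0]["length"] == 4.0
        assert not dur.iloc[0]["censored"]

    def test_censored_duration_at_series_end(self):
        eps = extract_episodes(self._frame([0, 2, 4], [False, True, True]))
        dur = eps[eps["kind"] == "duration"]
        assert len(dur) == 1
        assert dur.iloc[0]["length"] == 2.0
        assert bool(dur.iloc[0]["censored"])

    def test_include_initial_run_flag(self):
        eps = extract_episodes(
            self._frame([0, 2, 4], [True, True, False]), include_initial_run=True
        )
        assert (eps["kind"] == "duration").sum() == 1


class TestCensoredExponentialMean:
    def test_reduces_to_sample_mean_without_censoring(self):
        eps = pd.DataFrame(
            {"subject_id": "u", "kind": "duration", "length": [2.0, 4.0, 6.0],
             "censored": [False] * 3}
        )
        mean, se = censored_exponential_mean(eps)
        assert mean == pytest.approx(4.0)
        assert se == pytest.approx(4.0 / np.sqrt(3))

    def test_censored_closed_form(self):
        eps = pd.DataFrame(
            {"subject_id": "u", "kind": "duration", "length": [4.0, 6.0, 8.0],
             "censored": [False, False, True]}
        )
        assert censored_exponential_mean(eps)[0] == pytest.approx(9.0)

    def test_no_events_errors(self):
        eps = pd.DataFrame(
            {"subject_id": "u", "kind": "duration", "length": [4.0], "censored": [True]}
        )
        with pytest.raises(ValueError):
            censored_exponential_mean(eps)

    def test_matches_numeric_likelihood_maximiser(self, rng):
        """The closed form agrees with a numeric maximiser of the censored
        exponential log-likelihood to 1e-6 on random instances."""
        for _ in range(10):
            lengths = rng.exponential(5.0, 25)
            censored = rng.random(25) < 0.3
            eps = pd.DataFrame(
                {"subject_id": "u", "kind": "duration", "length": lengths,
                 "censored": censored}
            )
            if (~censored).sum() == 0:
                continue

            def negll(mu):
                n_events = (~censored).sum()
                return n_events * np.log(mu) + lengths.sum() / mu

            res = optimize.minimize_scalar(negll, bounds=(1e-3, 1e3), method="bounded",
                                           options={"xatol": 1e-10})
            assert censored_exponential_mean(eps)[0] == pytest.approx(res.x, abs=1e-6)


class TestKaplanMeier:
    def _eps(self, lengths, censored):
        return pd.DataFrame(
            {"subject_id": "u", "kind": "duration", "length": lengths,
             "censored": censored}
        )

    def test_no_censoring(self):
        km = kaplan_meier(self._eps([2.0, 4.0], [False, False])).set_index("time")
        assert km.loc[2.0, "survival"] == pytest.approx(0.5)
        assert km.loc[4.0, "survival"] == pytest.approx(0.0)

    def test_tied_event_and_censoring(self):
        km = kaplan_meier(self._eps([2.0, 4.0, 4.0], [False, False, True])).set_index("time")
        assert km.loc[2.0, "survival"] == pytest.approx(2 / 3)
        assert km.loc[4.0, "survival"] == pytest.approx(1 / 3)

    def test_all_censored_survival_stays_one(self):
        km = kaplan_meier(self._eps([2.0, 4.0], [True, True]))
        assert (km["survival"] == 1.0).all()


class TestConcordance:
    def _run(self, n11, n10, n01, n00):
        a = [True] * (n11 + n10) + [False] * (n01 + n00)
        b = [True] * n11 + [False] * n10 + [True] * n01 + [False] * n00
        ids = [f"s{i}" for i in range(len(a))]
        labels_a = pd.Series(a, index=ids)
        labels_b = pd.Series(b, index=ids)
        pairs = pd.DataFrame({"sample_a": ids, "sample_b": ids})
        return cross_type_concordance(labels_a, labels_b, pairs)

    def test_perfect_agreement(self):
        odds, p, _ = self._run(10, 0, 0, 10)
        assert np.isinf(odds)
        assert p < 1e-4

    def test_independence(self):
        odds, p, _ = self._run(5, 5, 5, 5)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_sample_odds_ratio(self):
        odds, _, table = self._run(20, 10, 10, 20)
        assert odds == pytest.approx(4.0)
        assert table.tolist() == [[20, 10], [10, 20]]
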