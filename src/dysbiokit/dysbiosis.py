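"""Dysbiosis scoring, classification, episode statistics, and concordance.

A sample's dysbiosis score is its median Bray–Curtis dissimilarity to a
reference set of non-IBD samples (taken after each reference subject's 20th
week, to avoid early-series gastrointestinal symptoms), excluding reference
samples from the sample's own subject.  Samples scoring above the 90th
percentile of the non-IBD score distribution — i.e. with a feature
configuration having less than 10% probability of occurring in a
participant without IBD — are classified dysbiotic.

Per-subject classification series decompose into episodes: maximal runs of
dysbiotic samples (durations) and eubiotic runs between excursions
(intervals), right-censored when a subject's series ends mid-run.  Sojourn
means are estimated by the censored maximum-likelihood estimator for an
exponential mean; Kaplan–Meier curves summarise the distributions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from sklearn.base import BaseEstimator
from skbio.stats.distance import DistanceMatrix

from .dissimilarity import bray_curtis
from .profiles import AbundanceTable

DURATION = "duration"
INTERVAL = "interval"


@dataclasses.dataclass
class DysbiosisResult:
    """Scores, cohort threshold, and binary classification for a sample set."""

    scores: pd.Series  # per-sample dysbiosis score in [0, 1]
    threshold: float
    labels: pd.Series  # bool, True = dysbiotic (score > threshold)
    reference_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dysbiosis_score": self.scores, "dysbiotic": self.labels}
        ).rename_axis("sample_id")


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def build_reference_set(
    metadata: pd.DataFrame,
    min_week: float = 20.0,
    reference_diagnosis: str = "nonIBD",
) -> list[str]:
    """Reference sample IDs: non-IBD samples strictly after ``min_week``.

    "After the 20th week" is read as week > 20 since the subject's first
    sample; the boundary is configurable.
    """
    mask = (metadata["diagnosis"] == reference_diagnosis) & (metadata["week"] > min_week)
    ids = metadata.loc[mask, "sample_id"].astype(str).tolist()
    if not ids:
        raise ValueError(
            f"no {reference_diagnosis} samples after week {min_week}: empty reference set"
        )
    return ids


def dysbiosis_score(
    sample_id: str,
    reference_ids: list[str],
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
) -> float:
    """Median dissimilarity from one sample to the reference set.

    Reference samples from the query's own subject are excluded so a
    subject cannot anchor its own reference.
    """
    subject_of = metadata.set_index("sample_id")["subject_id"]
    own = subject_of[sample_id]
    eligible = [r for r in reference_ids if subject_of[r] != own]
    if not eligible:
        raise ValueError(
            f"all reference samples share subject {own!r} with query {sample_id!r}"
        )
    d = np.array([dm[sample_id, r] for r in eligible])
    return float(np.median(d))


def dysbiosis_scores(
    dm: DistanceMatrix, metadata: pd.DataFrame, reference_ids: list[str]
) -> pd.Series:
    """Vectorised leave-own-subject-out median scores for every sample."""
    ids = list(dm.ids)
    idx = {s: i for i, s in enumerate(ids)}
    subject_of = metadata.set_index("sample_id")["subject_id"]
    ref_idx = np.array([idx[r] for r in reference_ids])
    ref_subjects = subject_of[reference_ids].to_numpy()
    out = {}
    for s in ids:
        mask = ref_subjects != subject_of[s]
        if not mask.any():
            raise ValueError(f"all reference samples share the subject of {s!r}")
        out[s] = np.median(dm.data[idx[s], ref_idx[mask]])
    return pd.Series(out, name="dysbiosis_score")


def dysbiosis_threshold(
    scores: pd.Series, metadata: pd.DataFrame, percentile: float = 90.0
) -> float:
    """Classification threshold: percentile of the non-IBD score distribution.

    Linear-interpolation (type-7) percentile, the ecosystem default.
    """
    non_ibd = metadata.loc[metadata["diagnosis"] == "nonIBD", "sample_id"].astype(str)
    non_ibd = [s for s in non_ibd if s in scores.index]
    if not non_ibd:
        raise ValueError("no non-IBD samples among the scored set")
    return float(np.percentile(scores[non_ibd], percentile))


def classify_dysbiosis(scores: pd.Series, threshold: float) -> pd.Series:
    """Binary classification with a strict inequality: score > threshold.

    Ties at the threshold are non-dysbiotic ("less than 10% probability").
    """
    return (scores > threshold).rename("dysbiotic")


class DysbiosisClassifier(BaseEstimator):
    """Reference-based dysbiosis scorer/classifier with a cohort threshold.

    fit() computes the Bray–Curtis matrix over the cohort, builds the
    non-IBD reference set, scores every sample (leave-own-subject-out
    median), sets the threshold at ``percentile`` of the non-IBD scores and
    classifies the fitted samples.  predict() scores new samples against
    the fitted reference profiles and applies the fitted threshold.

    Attributes (after fit)
    ----------------------
    reference_ids_ : list of reference sample IDs
    scores_, labels_ : per-sample score and classification
    threshold_ : the cohort threshold
    """

    def __init__(self, min_week: float = 20.0, percentile: float = 90.0):
        self.min_week = min_week
        self.percentile = percentile

    def fit(self, table: AbundanceTable, metadata: pd.DataFrame) -> "DysbiosisClassifier":
        dm = bray_curtis(table)
        self.reference_ids_ = build_reference_set(metadata, self.min_week)
        self.scores_ = dysbiosis_scores(dm, metadata, self.reference_ids_)
        self.threshold_ = dysbiosis_threshold(self.scores_, metadata, self.percentile)
        self.labels_ = classify_dysbiosis(self.scores_, self.threshold_)
        self._reference_table = table.subset_samples(self.reference_ids_)
        self._reference_subjects = (
            metadata.set_index("sample_id").loc[self.reference_ids_, "subject_id"]
        )
        return self

    def result_(self) -> DysbiosisResult:
        return DysbiosisResult(
            self.scores_, self.threshold_, self.labels_, list(self.reference_ids_)
        )

    def predict(self, table: AbundanceTable, subject_ids: pd.Series | None = None) -> pd.Series:
        """Classify new samples against the fitted reference and threshold."""
        scores = self.score_samples(table, subject_ids)
        return classify_dysbiosis(scores, self.threshold_)

    def score_samples(
        self, table: AbundanceTable, subject_ids: pd.Series | None = None
    ) -> pd.Series:
        from scipy.spatial.distance import cdist

        q = table.values().T
        r = self._reference_table.values().T
        d = cdist(q, r, metric="braycurtis")
        out = {}
        for i, s in enumerate(table.samples):
            mask = np.ones(len(self.reference_ids_), dtype=bool)
            if subject_ids is not None:
                mask = (self._reference_subjects != subject_ids[str(s)]).to_numpy()
            out[str(s)] = np.median(d[i, mask])
        return pd.Series(out, name="dysbiosis_score")


def score_against_external_reference(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    external_table: AbundanceTable,
    percentile: float = 90.0,
) -> tuple[DysbiosisResult, float]:
    """Score the cohort against an external reference cohort.

    The external cohort contributes the reference profiles (no own-subject
    exclusion applies); the threshold is still the ``percentile`` of the
    resulting scores among the study's non-IBD samples.  Returns the result
    and the Spearman concordance of the external-reference scores with the
    internal-reference scores.
    """
    from scipy.spatial.distance import cdist

    q = table.values().T
    r = external_table.values().T
    d = cdist(q, r, metric="braycurtis")
    scores = pd.Series(
        np.median(d, axis=1), index=[str(s) for s in table.samples], name="dysbiosis_score"
    )
    threshold = dysbiosis_threshold(scores, metadata, percentile)
    labels = classify_dysbiosis(scores, threshold)
    internal = DysbiosisClassifier(percentile=percentile).fit(table, metadata)
    rho = float(stats.spearmanr(scores[internal.scores_.index], internal.scores_)[0])
    result = DysbiosisResult(scores, threshold, labels, [str(s) for s in external_table.samples])
    return result, rho


# ---------------------------------------------------------------------------
# Episodes
# ---------------------------------------------------------------------------

def extract_episodes(
    metadata: pd.DataFrame,
    labels: pd.Series | None = None,
    include_initial_run: bool = False,
) -> pd.DataFrame:
    """Decompose per-subject classification series into episodes.

    Within each subject's week-sorted series, a maximal run of dysbiotic
    samples is a *duration* episode and a eubiotic run between excursions
    an *interval* episode.  A complete episode's length is
    ``week(first sample of next run) - week(first sample of run)``; a run
    still in progress at the last sample is right-censored at
    ``week(last sample) - week(run start)``.  Runs in progress at the start
    of a series are ambiguous on the left and excluded by default
    (``include_initial_run=True`` keeps them, censored on the left being
    ignored — lengths then measure from the first observed sample).

    Returns a frame with columns ``subject_id, kind, length, censored``.
    """
    if labels is None:
        if "dysbiotic" not in metadata.columns:
            raise ValueError("metadata lacks a 'dysbiotic' column and no labels given")
        labels = metadata.set_index("sample_id")["dysbiotic"]
    meta = metadata.copy()
    meta["dysbiotic"] = labels[meta["sample_id"]].to_numpy()
    rows = []
    for subject, grp in meta.groupby("subject_id"):
        srt = grp.sort_values("week")
        weeks = srt["week"].to_numpy(dtype=float)
        states = srt["dysbiotic"].to_numpy(dtype=bool)
        runs = _runs(states)
        for k, (state, i, j) in enumerate(runs):
            if k == 0 and not include_initial_run:
                continue
            censored = k == len(runs) - 1
            if censored:
                length = weeks[j] - weeks[i]
            else:
                length = weeks[runs[k + 1][1]] - weeks[i]
            rows.append(
                {
                    "subject_id": subject,
                    "kind": DURATION if state else INTERVAL,
                    "length": float(length),
                    "censored": bool(censored),
                }
            )
    return pd.DataFrame(rows, columns=["subject_id", "kind", "length", "censored"])


def _runs(states: np.ndarray) -> list[tuple[bool, int, int]]:
    """Maximal constant runs as (state, first index, last index)."""
    runs = []
    i = 0
    n = len(states)
    while i < n:
        j = i
        while j + 1 < n and states[j + 1] == states[i]:
            j += 1
        runs.append((bool(states[i]), i, j))
        i = j + 1
    return runs


def censored_exponential_mean(episodes: pd.DataFrame) -> tuple[float, float]:
    """Censored MLE of an exponential mean from episode lengths.

    mean = (sum of all observed lengths, censored included) / (number of
    uncensored episodes); SE = mean / sqrt(uncensored count).  Censored
    observations contribute observation time but no event, avoiding the
    underestimate a naive mean of complete episodes would give.
    """
    lengths = episodes["length"].to_numpy(dtype=float)
    censored = episodes["censored"].to_numpy(dtype=bool)
    n_events = int((~censored).sum())
    if n_events == 0:
        raise ValueError("censored exponential MLE requires >= 1 uncensored episode")
    mean = float(lengths.sum() / n_events)
    return mean, mean / np.sqrt(n_events)


def kaplan_meier(episodes: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival curve of episode lengths.

    Events precede censorings at tied times (the standard convention).
    Returns a step function as a frame with columns ``time, survival``.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(
        episodes["length"].to_numpy(dtype=float),
        event_observed=(~episodes["censored"].to_numpy(dtype=bool)).astype(int),
    )
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()})


# ---------------------------------------------------------------------------
# Cross-measurement-type concordance
# ---------------------------------------------------------------------------

def cross_type_concordance(
    labels_a: pd.Series, labels_b: pd.Series, matched_pairs: pd.DataFrame
) -> tuple[float, float, np.ndarray]:
    """Concordance of two dysbiosis classifications on matched sample pairs.

    ``matched_pairs`` has columns ``sample_a, sample_b``.  Returns the
    sample odds ratio of the 2x2 contingency table (Haldane–Anscombe 0.5
    correction only when a margin is zero), the two-sided Fisher exact
    p-value, and the table itself ([[both, A only], [B only, neither]]).
    """
    a = labels_a[matched_pairs["sample_a"]].to_numpy(dtype=bool)
    b = labels_b[matched_pairs["sample_b"]].to_numpy(dtype=bool)
    table = np.array(
        [
            [int((a & b).sum()), int((a & ~b).sum())],
            [int((~a & b).sum()), int((~a & ~b).sum())],
        ]
    )
    t = table.astype(float)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        t = t + 0.5  # Haldane–Anscombe, only when a margin is empty
    with np.errstate(divide="ignore", invalid="ignore"):
        odds_ratio = float((t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]))
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return odds_ratio, float(p), table
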