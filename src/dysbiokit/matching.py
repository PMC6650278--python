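"""Lenient cross-measurement-type temporal matching.

Multi-omic measurements are rarely produced from exactly the same stool
sample, so analyses that need one sample per measurement type build
*matched sets*: tuples of samples, one per type, taken within a short time
window (0, 2 or 4 weeks) of each other, each sample used at most once.

The matching scans each subject's timeline left to right: find the first
window of width ``w`` in which every type has at least one remaining
sample; inside it pick the target week where most types have a sample
exactly (ties toward earlier weeks); per type select the sample nearest the
target (ties toward earlier); then discard, per type, everything up to and
including the later of the selected sample and the target, and repeat.
Window starts are scanned over the sorted union of remaining sample weeks —
any feasible window can be slid left until its start hits a sample week
without losing members, so this finds the first feasible window.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import pandas as pd


@dataclasses.dataclass
class MatchedSet:
    """One matched tuple: per-type selected sample week (and optional ID)."""

    subject_id: str
    target_week: float
    selections: dict  # type -> (week, sample_id or None)

    def week_of(self, mtype: str) -> float:
        return self.selections[mtype][0]


def match_samples(
    weeks_by_type: Mapping[str, Sequence[float]],
    window: float,
    subject_id: str = "",
    sample_ids_by_type: Mapping[str, Sequence[str]] | None = None,
) -> list[MatchedSet]:
    """Match one subject's samples across measurement types.

    ``weeks_by_type`` maps measurement type to its ascending sample weeks.
    ``window`` is the leniency in weeks (0 demands exact co-occurrence).
    Optional ``sample_ids_by_type`` aligns IDs with the week lists.
    """
    if window < 0:
        raise ValueError("window must be nonnegative")
    if not weeks_by_type or any(len(v) == 0 for v in weeks_by_type.values()):
        return []
    remaining: dict[str, list[tuple[float, str | None]]] = {}
    for mtype, weeks in weeks_by_type.items():
        ids = (
            list(sample_ids_by_type[mtype])
            if sample_ids_by_type is not None
            else [None] * len(weeks)
        )
        pairs = sorted(zip([float(w) for w in weeks], ids))
        remaining[mtype] = pairs

    matches: list[MatchedSet] = []
    while True:
        # (1) first window start (over union of remaining weeks) covering all types
        union = sorted({w for lst in remaining.values() for w, _ in lst})
        start = None
        for t in union:
            if all(any(t <= w <= t + window for w, _ in lst) for lst in remaining.values()):
                start = t
                break
        if start is None:
            break
        # (2) target = in-window week where most types have a sample exactly
        in_window = sorted({w for lst in remaining.values() for w, _ in lst if start <= w <= start + window})
        counts = {
            w: sum(any(abs(wk - w) < 1e-9 for wk, _ in lst) for lst in remaining.values())
            for w in in_window
        }
        best = max(counts.values())
        target = min(w for w, c in counts.items() if c == best)
        # (3) per type: nearest in-window sample to the target, ties earlier
        selections = {}
        for mtype, lst in remaining.items():
            cand = [(abs(w - target), w, sid) for w, sid in lst if start <= w <= start + window]
            cand.sort(key=lambda t3: (t3[0], t3[1]))
            _, w_sel, sid = cand[0]
            selections[mtype] = (w_sel, sid)
        matches.append(MatchedSet(subject_id, target, selections))
        # (4) discard everything up to max(selected, target), per type
        for mtype, lst in remaining.items():
            cutoff = max(selections[mtype][0], target)
            remaining[mtype] = [(w, sid) for w, sid in lst if w > cutoff]
    return matches


def match_cohort(
    metadata_by_type: Mapping[str, pd.DataFrame], window: float
) -> pd.DataFrame:
    """Match samples across types for every subject of a cohort.

    Each metadata frame needs ``sample_id, subject_id, week``.  Returns a
    wide frame: one row per matched set with per-type sample IDs and weeks.
    """
    subjects = sorted(
        set.intersection(
            *(set(m["subject_id"].unique()) for m in metadata_by_type.values())
        )
    )
    rows = []
    for subject in subjects:
        weeks, ids = {}, {}
        for mtype, meta in metadata_by_type.items():
            sub = meta[meta["subject_id"] == subject].sort_values("week")
            weeks[mtype] = sub["week"].tolist()
            ids[mtype] = sub["sample_id"].tolist()
        for ms in match_samples(weeks, window, subject_id=subject, sample_ids_by_type=ids):
            row = {"subject_id": subject, "target_week": ms.target_week}
            for mtype, (w, sid) in ms.selections.items():
                row[f"{mtype}_week"] = w
                row[f"{mtype}_sample"] = sid
            rows.append(row)
    return pd.DataFrame(rows)


def completeness_report(
    metadata_by_type: Mapping[str, pd.DataFrame],
    type_subsets: Sequence[Sequence[str]],
    windows: Sequence[float] = (0.0, 2.0, 4.0),
) -> pd.DataFrame:
    """Matched-set counts per measurement-type subset and leniency window.

    Counts typically grow with the window, though the greedy matcher does
    not guarantee monotonicity (a wide window can merge near-coincident
    sets that a strict window keeps separate).
    """
    rows = []
    for subset in type_subsets:
        sub_meta = {t: metadata_by_type[t] for t in subset}
        for w in windows:
            n = len(match_cohort(sub_meta, w))
            rows.append({"types": "+".join(subset), "window": w, "n_matched": n})
    return pd.DataFrame(rows)
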