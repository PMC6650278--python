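"""Pairwise dissimilarities and their within/between-subject decomposition.

Bray–Curtis dissimilarity between relative-abundance profiles is the working
metric throughout; dietary questionnaires use an ordinal Manhattan distance.
Matrices are held in scikit-bio :class:`~skbio.stats.distance.DistanceMatrix`
objects, which enforce symmetry, hollowness and carry the sample IDs.

The longitudinal decomposition pairs every two samples and labels the pair
``intra`` (same subject, optionally restricted to consecutive time points)
or ``inter`` (different subjects), annotated with the intervening time
difference in weeks.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from .profiles import AbundanceTable, ProfileValidationError

#: Pair relation labels.
INTRA_CONSECUTIVE = "intra-consecutive"
INTRA_ANY = "intra-any"
INTER = "inter"


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarity matrix over the samples of a table.

    d(x, y) = sum|x - y| / sum(x + y); entries lie in [0, 1] for
    nonnegative inputs.  All-zero samples are rejected (undefined
    denominator).
    """
    values = table.values().T  # samples x features
    sums = values.sum(axis=1)
    if (sums == 0).any():
        bad = table.samples[sums == 0].tolist()
        raise ProfileValidationError(f"all-zero samples have undefined Bray–Curtis: {bad}")
    condensed = pdist(values, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(s) for s in table.samples])


def ordinal_manhattan(dietary: pd.DataFrame, level_order: list[str]) -> DistanceMatrix:
    """Manhattan distance between samples after ordinal coding of levels.

    ``dietary`` is samples x items with categorical frequency levels; levels
    are ranked by their position in ``level_order`` (less to more frequent)
    and coded as integers 0, 1, 2, ...  Unknown labels raise.
    """
    codes = {lvl: i for i, lvl in enumerate(level_order)}
    unknown = set(np.unique(dietary.to_numpy().astype(str))) - set(codes)
    if unknown:
        raise ValueError(f"dietary levels not in level_order: {sorted(unknown)}")
    coded = dietary.apply(lambda col: col.map(codes)).to_numpy(dtype=float)
    condensed = pdist(coded, metric="cityblock")
    return DistanceMatrix(squareform(condensed), ids=[str(s) for s in dietary.index])


def build_pair_sets(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    consecutive_only: bool = False,
) -> pd.DataFrame:
    """List all sample pairs with dissimilarity, time gap, and relation.

    Returns a long-format frame with columns ``sample_i, sample_j,
    dissimilarity, delta_weeks, relation``.  ``relation`` is
    ``intra-consecutive`` / ``intra-any`` for same-subject pairs (the former
    restricted to adjacent time points in that subject's series) and
    ``inter`` otherwise.  ``delta_weeks`` is computed from the ``week``
    metadata field, never from sample order, so technical replicates at the
    same week form legitimate delta = 0 intra pairs.

    With ``consecutive_only`` the intra pairs are restricted to
    ``intra-consecutive`` (inter pairs are always retained).
    """
    meta = metadata.set_index("sample_id").loc[list(dm.ids)]
    subjects = meta["subject_id"].to_numpy()
    weeks = meta["week"].to_numpy(dtype=float)
    n = len(dm.ids)
    data = dm.data

    # Mark consecutive (adjacent-in-time) pairs per subject.
    consecutive = set()
    order = pd.DataFrame({"subject": subjects, "week": weeks, "idx": np.arange(n)})
    for _, grp in order.groupby("subject"):
        srt = grp.sort_values(["week", "idx"])
        idx = srt["idx"].to_numpy()
        for a, b in zip(idx[:-1], idx[1:]):
            consecutive.add((min(a, b), max(a, b)))

    iu, ju = np.triu_indices(n, k=1)
    same = subjects[iu] == subjects[ju]
    rows = []
    for i, j, intra in zip(iu, ju, same):
        if intra:
            relation = INTRA_CONSECUTIVE if (i, j) in consecutive else INTRA_ANY
            if consecutive_only and relation != INTRA_CONSECUTIVE:
                continue
        else:
            relation = INTER
        rows.append(
            (
                dm.ids[i],
                dm.ids[j],
                data[i, j],
                abs(weeks[i] - weeks[j]),
                relation,
            )
        )
    return pd.DataFrame(
        rows, columns=["sample_i", "sample_j", "dissimilarity", "delta_weeks", "relation"]
    )


def subject_mean_profiles(table: AbundanceTable, metadata: pd.DataFrame) -> AbundanceTable:
    """Average profile per subject: feature-wise mean over the subject's samples.

    The mean of compositions is itself a composition, so no renormalisation
    is applied.
    """
    meta = metadata.set_index("sample_id").loc[[str(s) for s in table.samples]]
    out = {}
    for subject, grp in meta.groupby("subject_id"):
        out[subject] = table.data.loc[:, grp.index].mean(axis=1)
    return AbundanceTable(pd.DataFrame(out), table.measurement_type)


def write_distance_tsv(dm: DistanceMatrix, path) -> None:
    """Write a labelled square distance matrix as TSV."""
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        Path(path), sep="\t", index_label="#SampleID"
    )


def write_pairs_tsv(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(Path(path), sep="\t", index=False)
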