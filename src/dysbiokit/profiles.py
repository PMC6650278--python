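"""Feature-by-sample abundance tables and sample metadata.

The substrate of every downstream stage is an :class:`AbundanceTable`: a
nonnegative feature-by-sample matrix (MetaPhlAn-style taxonomic profiles, or
metabolite / protein / functional tables in the same layout) together with a
measurement-type tag.  Sample metadata carries the longitudinal design:
subject identity, week since the subject's first stool sample, diagnosis,
and optional covariates.

Weeks are always relative to each subject's first sample; absolute dates are
out of scope.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MEASUREMENT_TYPES = ("MGX-taxa", "MTX", "MPX", "MBX", "other")

#: Required columns of a sample metadata table.
METADATA_COLUMNS = ("sample_id", "subject_id", "week", "diagnosis")

DIAGNOSES = ("nonIBD", "UC", "CD")


class ProfileValidationError(ValueError):
    """Raised when a profile table or metadata table violates its contract."""


@dataclasses.dataclass
class AbundanceTable:
    """Nonnegative feature-by-sample matrix with a measurement-type tag.

    Parameters
    ----------
    data:
        DataFrame with feature identifiers as the index and sample
        identifiers as columns.  Values must be nonnegative and finite.
    measurement_type:
        One of ``MGX-taxa``, ``MTX``, ``MPX``, ``MBX`` or ``other``.
    """

    data: pd.DataFrame
    measurement_type: str = "other"

    def __post_init__(self) -> None:
        if self.measurement_type not in MEASUREMENT_TYPES:
            raise ProfileValidationError(
                f"unknown measurement type {self.measurement_type!r}; "
                f"expected one of {MEASUREMENT_TYPES}"
            )
        validate_profile(self.data)

    # -- basic container protocol ------------------------------------
    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[:, list(sample_ids)], self.measurement_type)

    def copy_with(self, data: pd.DataFrame) -> "AbundanceTable":
        return AbundanceTable(data, self.measurement_type)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return self.measurement_type == other.measurement_type and self.data.equals(
            other.data
        )


def validate_profile(data: pd.DataFrame) -> None:
    """Check the abundance-matrix invariants, naming offenders on failure."""
    if data.index.duplicated().any():
        dupes = sorted(data.index[data.index.duplicated()].unique().tolist())
        raise ProfileValidationError(f"duplicate feature IDs: {dupes}")
    if data.columns.duplicated().any():
        dupes = sorted(data.columns[data.columns.duplicated()].unique().tolist())
        raise ProfileValidationError(f"duplicate sample IDs: {dupes}")
    values = data.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = [
            (str(data.index[i]), str(data.columns[j]))
            for i, j in zip(*np.where(~np.vectorize(_is_number)(values)))
        ]
        raise ProfileValidationError(f"non-numeric cells at (feature, sample): {bad[:10]}")
    if not np.isfinite(values).all():
        i, j = np.where(~np.isfinite(values))
        bad = [(str(data.index[a]), str(data.columns[b])) for a, b in zip(i[:10], j[:10])]
        raise ProfileValidationError(f"non-finite cells at (feature, sample): {bad}")
    if (values < 0).any():
        i, j = np.where(values < 0)
        bad = [(str(data.index[a]), str(data.columns[b])) for a, b in zip(i[:10], j[:10])]
        raise ProfileValidationError(f"negative cells at (feature, sample): {bad}")


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_profile_tsv(path, measurement_type: str = "other") -> AbundanceTable:
    """Read a tab-separated features-by-samples profile.

    First column holds feature identifiers, remaining columns one sample
    each; a header row is required.  Malformed input raises
    :class:`ProfileValidationError` naming the offending rows/columns.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    # Coerce cell-by-cell so offenders can be named.
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad_mask = numeric.isna() & raw.notna()
    if bad_mask.to_numpy().any():
        i, j = np.where(bad_mask.to_numpy())
        bad = [(str(raw.index[a]), str(raw.columns[b])) for a, b in zip(i[:10], j[:10])]
        raise ProfileValidationError(
            f"{path}: non-numeric cells at (feature, sample): {bad}"
        )
    if numeric.isna().to_numpy().any():
        raise ProfileValidationError(f"{path}: missing values are not allowed")
    table = AbundanceTable(numeric, measurement_type)
    logger.info("read %s: %d features x %d samples", path, *table.shape)
    return table


def write_profile_tsv(table: AbundanceTable, path) -> None:
    path = Path(path)
    table.data.to_csv(path, sep="\t", index_label="#FeatureID")
    logger.info("wrote %s: %d features x %d samples", path, *table.shape)


def read_metadata(path) -> pd.DataFrame:
    """Read and validate a sample metadata CSV/TSV (delimiter sniffed)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    meta = pd.read_csv(path, sep=sep)
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate the longitudinal sample metadata contract.

    Requires the columns ``sample_id, subject_id, week, diagnosis``; weeks
    nonnegative; samples unique; diagnosis constant within subject.
    """
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ProfileValidationError(f"metadata missing required columns: {missing}")
    meta = meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    meta["subject_id"] = meta["subject_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ProfileValidationError(f"duplicate sample IDs in metadata: {dupes}")
    if (meta["week"] < 0).any():
        bad = meta.loc[meta["week"] < 0, "sample_id"].tolist()
        raise ProfileValidationError(f"negative weeks for samples: {bad}")
    unknown = set(meta["diagnosis"].unique()) - set(DIAGNOSES)
    if unknown:
        raise ProfileValidationError(
            f"unknown diagnosis labels {sorted(unknown)}; expected {DIAGNOSES}"
        )
    per_subject = meta.groupby("subject_id")["diagnosis"].nunique()
    if (per_subject > 1).any():
        bad = per_subject[per_subject > 1].index.tolist()
        raise ProfileValidationError(f"diagnosis varies within subjects: {bad}")
    return meta


# ---------------------------------------------------------------------------
# Normalisation and transforms
# ---------------------------------------------------------------------------

def relative_normalize(table: AbundanceTable) -> AbundanceTable:
    """Total-sum scale every sample to relative abundances summing to 1."""
    sums = table.data.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ProfileValidationError(
            f"cannot normalize all-zero samples: {zero.index.tolist()}"
        )
    return table.copy_with(table.data.div(sums, axis=1))


def arcsinsqrt_transform(table: AbundanceTable) -> AbundanceTable:
    """Arcsine square-root variance-stabilising transform for proportions."""
    values = table.values()
    if (values < 0).any() or (values > 1).any():
        raise ProfileValidationError(
            "arcsine square-root transform requires values in [0, 1]; "
            "apply relative_normalize first"
        )
    out = pd.DataFrame(
        np.arcsin(np.sqrt(values)), index=table.features, columns=table.samples
    )
    return table.copy_with(out)


def log_pseudocount_transform(table: AbundanceTable, pseudocount: float = 1.0) -> AbundanceTable:
    """log(x + pseudocount) transform, the convention for intensity-scale data.

    The pseudocount defaults to 1 so zeros map to 0; the value used is logged.
    """
    if pseudocount <= 0:
        raise ProfileValidationError("pseudocount must be positive")
    logger.info("log transform with pseudocount %g", pseudocount)
    out = pd.DataFrame(
        np.log(table.values() + pseudocount), index=table.features, columns=table.samples
    )
    return table.copy_with(out)


def log_ratio_transform(values) -> np.ndarray:
    """Plain log of ratio-scale values, with non-finite results dropped."""
    arr = np.asarray(values, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log(arr)
    return out[np.isfinite(out)]


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def prevalence_variance_filter(
    table: AbundanceTable, max_zero_frac: float = 0.9
) -> AbundanceTable:
    """Drop features with more than ``max_zero_frac`` zeros or no variance.

    A feature observed as zero in strictly more than ``max_zero_frac`` of
    samples, or constant across samples, is removed.  Idempotent.
    """
    values = table.values()
    zero_frac = (values == 0).mean(axis=1)
    variance = values.var(axis=1)
    keep = (zero_frac <= max_zero_frac) & (variance > 0)
    if not keep.any():
        warnings.warn("prevalence/variance filter removed every feature", stacklevel=2)
    kept = table.data.loc[table.features[keep]]
    logger.info(
        "prevalence/variance filter: kept %d of %d features", keep.sum(), len(keep)
    )
    return table.copy_with(kept)


def species_level(table: AbundanceTable) -> AbundanceTable:
    """Keep MetaPhlAn-style lineage rows that terminate at the species rank.

    Rows whose pipe-delimited lineage ends in an ``s__`` clade are retained;
    higher ranks and strain-level (``t__``) rows are dropped.
    """
    keep = [f for f in table.features if str(f).split("|")[-1].startswith("s__")]
    return table.copy_with(table.data.loc[keep])


# ---------------------------------------------------------------------------
# Per-sample summaries
# ---------------------------------------------------------------------------

def gini_simpson(sample) -> float:
    """Gini–Simpson alpha diversity, 1 - sum(p_i^2), of one sample vector."""
    arr = np.asarray(sample, dtype=float)
    if arr.size == 0:
        raise ValueError("empty sample")
    if (arr < 0).any():
        raise ValueError("negative abundances")
    total = arr.sum()
    if total == 0:
        raise ValueError("all-zero sample has undefined diversity")
    p = arr / total
    return float(1.0 - np.sum(p**2))


def transcription_ratio(
    mtx_table: AbundanceTable, mgx_table: AbundanceTable, clade: str
) -> pd.Series:
    """Per-sample transcription ratio of a clade: sum(MTX) / sum(MGX).

    Both tables must be sum-normalised and stratified by clade (the clade
    token appears as one pipe-delimited rank of the feature ID).  Where the
    metagenomic denominator is zero the ratio is undefined and reported as
    NaN rather than an error.
    """
    samples = mtx_table.samples.intersection(mgx_table.samples)
    if len(samples) == 0:
        raise ValueError("no shared samples between MTX and MGX tables")

    def clade_sum(table: AbundanceTable) -> pd.Series:
        rows = [f for f in table.features if clade in str(f).split("|")]
        return table.data.loc[rows, samples].sum(axis=0)

    num = clade_sum(mtx_table)
    den = clade_sum(mgx_table)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den.replace(0.0, np.nan)
    ratio.name = f"transcription_ratio[{clade}]"
    return ratio
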