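"""Microbiome shift detection between consecutive samples.

A *shift* occurs between two consecutive samples of one subject when their
Bray–Curtis dissimilarity is more likely under the between-person
distribution than under the within-person distribution at that time gap.
Thresholds come from the crossing point of two kernel density estimates —
within-subject dissimilarities of reference (non-IBD) subjects, windowed by
time difference, against pooled between-subject dissimilarities — with the
constraint that the threshold is monotone nondecreasing in the time
difference (individual microbiomes drift, so larger gaps tolerate larger
dissimilarity before a pair looks inter-individual).

Kernel bandwidths use the Sheather–Jones solve-the-equation plug-in where
pair counts permit (implemented here; no installed dependency provides it)
with a Silverman fallback for small windows.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.base import BaseEstimator

from .dissimilarity import INTRA_ANY, INTRA_CONSECUTIVE, INTER
from .profiles import AbundanceTable

_SQRT2PI = np.sqrt(2.0 * np.pi)

WEEKS_PER_YEAR = 52.0


# ---------------------------------------------------------------------------
# Bandwidth selectors
# ---------------------------------------------------------------------------

def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule of thumb, 0.9 min(sd, IQR/1.349) n^(-1/5)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("bandwidth selection needs >= 2 points")
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(x.std(ddof=1), iqr / 1.349) or x.std(ddof=1) or 1.0
    return 0.9 * scale * n ** (-0.2)


def _phi4_sum(delta: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * delta**2) * (delta**4 - 6 * delta**2 + 3)


def _phi6_sum(delta: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * delta**2) * (delta**6 - 15 * delta**4 + 45 * delta**2 - 15)


def sheather_jones_bandwidth(x: np.ndarray, nbins: int = 1000) -> float:
    """Sheather–Jones solve-the-equation plug-in bandwidth.

    Pairwise-difference functionals are evaluated on a binned approximation
    (``nbins`` bins over the data range) so cost stays O(nbins^2) for any
    sample size.  Falls back to Silverman's rule when the root search
    cannot bracket a solution (e.g. heavily discretised data).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("bandwidth selection needs >= 2 points")
    rng = x.max() - x.min()
    if rng == 0:
        raise ValueError("degenerate sample: all values identical")
    # Binned pair-distance counts.
    d = rng * 1.01 / nbins
    idx = np.minimum(((x - x.min()) / d).astype(int), nbins - 1)
    counts = np.bincount(idx, minlength=nbins).astype(float)
    # cnt[k] = number of pairs with binned distance k*d, k >= 0
    cnt = np.correlate(counts, counts, mode="full")[nbins - 1 :]
    cnt[0] = (counts * (counts - 1) / 2).sum()
    k = np.arange(nbins, dtype=float)
    dist = k * d

    def sdh(h: float) -> float:
        delta = dist / h
        s = 2 * (cnt * _phi4_sum(delta)).sum() + n * 3.0
        return s / (n * (n - 1) * h**5 * _SQRT2PI)

    def tdh(h: float) -> float:
        delta = dist / h
        s = 2 * (cnt * _phi6_sum(delta)).sum() + n * (-15.0)
        return s / (n * (n - 1) * h**7 * _SQRT2PI)

    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.349) or sd
    a = 1.24 * scale * n ** (-1.0 / 7.0)
    b = 1.23 * scale * n ** (-1.0 / 9.0)
    c1 = 1.0 / (2.0 * np.sqrt(np.pi) * n)
    td = -tdh(b)
    if not td > 0:
        return silverman_bandwidth(x)
    alph2 = 1.357 * (sdh(a) / td) ** (1.0 / 7.0)

    def fsd(h: float) -> float:
        s = sdh(alph2 * h ** (5.0 / 7.0))
        if not s > 0:
            return -h
        return (c1 / s) ** 0.2 - h

    hmax = 1.144 * sd * n ** (-0.2)
    lower, upper = 0.1 * hmax, hmax
    for _ in range(99):
        if fsd(lower) * fsd(upper) <= 0:
            break
        lower *= 0.9
        upper *= 1.2
    else:
        return silverman_bandwidth(x)
    return float(brentq(fsd, lower, upper, xtol=0.01 * lower))


def gaussian_kde_on_grid(
    x: np.ndarray,
    grid: np.ndarray,
    bandwidth: float,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """(Weighted) Gaussian kernel density estimate evaluated on a grid."""
    x = np.asarray(x, dtype=float)
    if weights is None:
        weights = np.full(len(x), 1.0 / len(x))
    else:
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()
    z = (grid[:, None] - x[None, :]) / bandwidth
    return (np.exp(-0.5 * z**2) @ weights) / (bandwidth * _SQRT2PI)


def weighted_density(
    values: np.ndarray,
    subject_ids: np.ndarray | None = None,
    grid: np.ndarray | None = None,
    bandwidth: float | str = "sheather_jones",
) -> tuple[np.ndarray, np.ndarray, float]:
    """Subject-weighted density estimate of per-sample values.

    Each sample is weighted by the inverse of its subject's sample count,
    so densely sampled subjects do not dominate the estimate; a subject
    contributing ten samples carries the same total mass as a singleton.
    Bandwidth defaults to Sheather–Jones.  Returns (grid, density,
    bandwidth).
    """
    values = np.asarray(values, dtype=float)
    if grid is None:
        pad = 3 * values.std(ddof=1) if len(values) > 1 else 1.0
        grid = np.linspace(values.min() - pad, values.max() + pad, 512)
    if subject_ids is None:
        weights = np.full(len(values), 1.0 / len(values))
    else:
        subject_ids = np.asarray(subject_ids)
        counts = pd.Series(subject_ids).value_counts()
        weights = 1.0 / counts[subject_ids].to_numpy(dtype=float)
        weights = weights / weights.sum()
    if bandwidth == "sheather_jones":
        bw = sheather_jones_bandwidth(values)
    elif bandwidth == "silverman":
        bw = silverman_bandwidth(values)
    else:
        bw = float(bandwidth)
    return grid, gaussian_kde_on_grid(values, grid, bw, weights), bw


# ---------------------------------------------------------------------------
# Threshold curve
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ShiftThresholdCurve:
    """Monotone map from time gap (weeks) to a dissimilarity threshold."""

    window_centers: np.ndarray  # weeks, increasing
    thresholds: np.ndarray  # running-maximum enforced
    raw_thresholds: np.ndarray
    bandwidths: list  # per-window (rule, value)
    monotone_enforced: bool = True

    def threshold_for(self, delta_weeks: float) -> float:
        """Threshold of the window nearest in time gap (ties toward lower)."""
        centers = self.window_centers
        i = int(np.argmin(np.abs(centers - delta_weeks)))
        # ties toward the lower center
        if i + 1 < len(centers) and abs(centers[i + 1] - delta_weeks) < abs(
            centers[i] - delta_weeks
        ):
            i += 1
        return float(self.thresholds[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "delta_weeks": self.window_centers,
                "threshold": self.thresholds,
                "raw_threshold": self.raw_thresholds,
                "bandwidth_rule": [b[0] for b in self.bandwidths],
                "bandwidth": [b[1] for b in self.bandwidths],
            }
        )


def _density_crossing(
    intra: np.ndarray, inter: np.ndarray, grid: np.ndarray
) -> float:
    """Smallest grid value above the intra mode where inter exceeds intra.

    The search prefers dissimilarities above the intra-density mode (the
    intended threshold bounds the upper tail, and low-end tail artefacts of
    the KDEs must not trigger it); the crossing is linearly interpolated
    between grid points.  When no crossing exists above the mode — e.g. the
    inter distribution sits entirely below the intra one — the scan falls
    back to the whole grid; if the inter density never exceeds the intra
    density anywhere, the grid maximum is returned.
    """
    mode = int(np.argmax(intra))
    diff = inter - intra
    above = np.nonzero(diff[mode:] > 0)[0]
    if len(above) > 0:
        k = mode + above[0]
    else:
        anywhere = np.nonzero(diff > 0)[0]
        if len(anywhere) == 0:
            return float(grid[-1])
        k = int(anywhere[0])
        mode = 0
    if k == mode or diff[k - 1] > 0:
        return float(grid[k])
    g0, g1 = grid[k - 1], grid[k]
    d0, d1 = diff[k - 1], diff[k]
    return float(g0 + (g1 - g0) * (-d0) / (d1 - d0))


def fit_threshold_curve(
    pairs: pd.DataFrame,
    sampling_interval: float = 2.0,
    min_pairs: int = 30,
    min_sj: int = 20,
    grid_size: int = 512,
) -> ShiftThresholdCurve:
    """Fit the time-gap-dependent shift threshold curve from reference pairs.

    ``pairs`` is a pair table (see :func:`~dysbiokit.dissimilarity.build_pair_sets`)
    from subjects without IBD.  Within-subject pairs are windowed into bins
    centred on multiples of ``sampling_interval`` (half-interval tolerance);
    bins with fewer than ``min_pairs`` pairs are pooled upward into the next
    bin.  Between-subject dissimilarities are pooled across all pairs.  Per
    window, Gaussian KDEs of the two sets are compared on a fixed grid over
    [0, 1]; the raw threshold is the density crossing above the intra mode
    and the final curve is the running maximum over increasing time gap.
    """
    intra = pairs[pairs["relation"].isin([INTRA_ANY, INTRA_CONSECUTIVE])]
    inter_d = pairs.loc[pairs["relation"] == INTER, "dissimilarity"].to_numpy(dtype=float)
    if len(intra) == 0:
        raise ValueError("no within-subject reference pairs: cannot fit thresholds")
    if len(inter_d) < 2:
        raise ValueError("need >= 2 between-subject reference pairs")
    grid = np.linspace(0.0, 1.0, grid_size)
    inter_bw = (
        sheather_jones_bandwidth(inter_d) if len(inter_d) >= min_sj else silverman_bandwidth(inter_d)
    )
    inter_density = gaussian_kde_on_grid(inter_d, grid, inter_bw)

    bins = np.round(intra["delta_weeks"].to_numpy(dtype=float) / sampling_interval).astype(int)
    windows: list[tuple[float, np.ndarray]] = []
    carry = np.array([], dtype=float)
    for b in sorted(set(bins)):
        vals = np.concatenate([carry, intra.loc[bins == b, "dissimilarity"].to_numpy(dtype=float)])
        if len(vals) < min_pairs:
            carry = vals  # pool sparse bins upward
            continue
        windows.append((b * sampling_interval, vals))
        carry = np.array([], dtype=float)
    if len(carry) and windows:
        center, vals = windows[-1]
        windows[-1] = (center, np.concatenate([vals, carry]))
    elif len(carry) >= 2 and not windows:
        windows.append((float(np.median(intra["delta_weeks"])), carry))
    if not windows:
        raise ValueError("no time-difference window has enough pairs")

    centers, raw, bandwidths = [], [], []
    for center, vals in windows:
        if len(vals) >= min_sj and np.ptp(vals) > 0:
            rule, bw = "sheather_jones", sheather_jones_bandwidth(vals)
        else:
            rule, bw = "silverman", silverman_bandwidth(vals)
        intra_density = gaussian_kde_on_grid(vals, grid, bw)
        centers.append(center)
        raw.append(_density_crossing(intra_density, inter_density, grid))
        bandwidths.append((rule, bw))
    raw_arr = np.asarray(raw)
    thresholds = np.maximum.accumulate(raw_arr)
    curve = ShiftThresholdCurve(
        np.asarray(centers, dtype=float), thresholds, raw_arr, bandwidths
    )
    assert np.all(np.diff(curve.thresholds) >= 0), "threshold curve must be monotone"
    return curve


def single_threshold_variant(pairs: pd.DataFrame, min_sj: int = 20, grid_size: int = 512) -> ShiftThresholdCurve:
    """Single time-gap-independent threshold from pooled within-subject pairs.

    Used for sparsely sampled measurement types (e.g. metabolomics) whose
    dissimilarities show no strong trend with time difference.
    """
    pooled = pairs.copy()
    pooled["delta_weeks"] = 0.0
    return fit_threshold_curve(
        pooled, sampling_interval=1.0, min_pairs=2, min_sj=min_sj, grid_size=grid_size
    )


# ---------------------------------------------------------------------------
# Calling and attribution
# ---------------------------------------------------------------------------

def call_shifts(
    pairs: pd.DataFrame, curve: ShiftThresholdCurve, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Flag consecutive within-subject pairs exceeding the threshold curve.

    Returns one row per shift with subject, weeks, dissimilarity, and the
    threshold applied.
    """
    cons = pairs[pairs["relation"] == INTRA_CONSECUTIVE]
    meta = metadata.set_index("sample_id")
    rows = []
    for _, r in cons.iterrows():
        thr = curve.threshold_for(r["delta_weeks"])
        if r["dissimilarity"] > thr:
            wi = float(meta.loc[r["sample_i"], "week"])
            wj = float(meta.loc[r["sample_j"], "week"])
            first, second = (
                (r["sample_i"], r["sample_j"]) if wi <= wj else (r["sample_j"], r["sample_i"])
            )
            rows.append(
                {
                    "subject_id": meta.loc[r["sample_i"], "subject_id"],
                    "sample_from": first,
                    "sample_to": second,
                    "week_from": min(wi, wj),
                    "week_to": max(wi, wj),
                    "dissimilarity": float(r["dissimilarity"]),
                    "threshold": thr,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "sample_from",
            "sample_to",
            "week_from",
            "week_to",
            "dissimilarity",
            "threshold",
        ],
    )


def attribute_shift(
    sample_from: str, sample_to: str, table: AbundanceTable
) -> tuple[pd.Series, str]:
    """Per-feature signed change across a shift and its primary contributor.

    The primary contributor is the feature with the largest absolute
    change; exact ties break toward the lexicographically smaller ID.
    """
    delta = table.data[sample_to] - table.data[sample_from]
    order = sorted(delta.index, key=lambda f: (-abs(delta[f]), str(f)))
    return delta, str(order[0])


def attribute_shifts(calls: pd.DataFrame, table: AbundanceTable) -> pd.DataFrame:
    """Annotate shift calls with their primary contributing feature."""
    out = calls.copy()
    out["primary_contributor"] = [
        attribute_shift(r["sample_from"], r["sample_to"], table)[1]
        for _, r in calls.iterrows()
    ]
    return out


def shift_rate(
    calls: pd.DataFrame,
    pairs: pd.DataFrame,
    metadata: pd.DataFrame,
    group: str | None = None,
) -> float:
    """Shifts per year of observed consecutive-pair time in a diagnosis group.

    rate = (#calls in group) / (sum of consecutive-pair time gaps, years).
    """
    meta = metadata.set_index("sample_id")
    cons = pairs[pairs["relation"] == INTRA_CONSECUTIVE]
    if group is not None:
        in_group = meta["diagnosis"] == group
        cons = cons[cons["sample_i"].map(in_group).to_numpy(dtype=bool)]
        calls = calls[calls["subject_id"].map(
            metadata.drop_duplicates("subject_id").set_index("subject_id")["diagnosis"]
        ) == group] if len(calls) else calls
    total_weeks = cons["delta_weeks"].sum()
    if total_weeks == 0:
        raise ValueError("no observed consecutive-pair time in group")
    return float(len(calls) / (total_weeks / WEEKS_PER_YEAR))


class ShiftDetector(BaseEstimator):
    """Estimator facade: fit thresholds on reference pairs, flag new pairs.

    Attributes after fit: ``curve_`` (:class:`ShiftThresholdCurve`).
    """

    def __init__(
        self,
        sampling_interval: float = 2.0,
        min_pairs: int = 30,
        min_sj: int = 20,
        grid_size: int = 512,
        single_threshold: bool = False,
    ):
        self.sampling_interval = sampling_interval
        self.min_pairs = min_pairs
        self.min_sj = min_sj
        self.grid_size = grid_size
        self.single_threshold = single_threshold

    def fit(self, reference_pairs: pd.DataFrame) -> "ShiftDetector":
        if self.single_threshold:
            self.curve_ = single_threshold_variant(
                reference_pairs, min_sj=self.min_sj, grid_size=self.grid_size
            )
        else:
            self.curve_ = fit_threshold_curve(
                reference_pairs,
                sampling_interval=self.sampling_interval,
                min_pairs=self.min_pairs,
                min_sj=self.min_sj,
                grid_size=self.grid_size,
            )
        return self

    def predict(self, pairs: pd.DataFrame) -> np.ndarray:
        """Boolean shift flag for each consecutive within-subject pair row."""
        thr = np.array([self.curve_.threshold_for(d) for d in pairs["delta_weeks"]])
        return pairs["dissimilarity"].to_numpy(dtype=float) > thr
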