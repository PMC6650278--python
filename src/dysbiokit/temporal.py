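"""Temporal divergence models and restricted-permutation community tests.

Within-subject dissimilarity grows with the intervening time difference;
the trend is summarised by a power law with free intercept,
``d(dt) = a * dt**b + c``, fit by derivative-free least squares and tested
against a flat line (and between disease groups) with nested F-tests.

Community-level covariation uses Mantel tests — cross-sectional on
subject-averaged profiles with free permutations, longitudinal on
within-subject distances only with permutations restricted to subject
blocks — and PERMANOVA with permutation schemes that respect the repeated
measures: time-varying variables are permuted within subject, whereas
subject-constant variables are permuted across subjects and samples
relabelled from their permuted subject.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from skbio.stats.distance import DistanceMatrix

FREE = "free"
WITHIN_SUBJECT = "within-subject"
SUBJECT_RELABEL = "subject-relabel"


# ---------------------------------------------------------------------------
# Power-law divergence
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PowerLawFit:
    """Least-squares fit of d = a * dt**b + c with its flat-model baseline."""

    a: float
    b: float
    c: float
    rss: float
    flat_rss: float
    n: int
    group: str | None = None

    def predict(self, dt) -> np.ndarray:
        dt = np.asarray(dt, dtype=float)
        return self.a * np.power(dt, self.b, where=dt > 0, out=np.zeros_like(dt)) + self.c


def _profiled_rss(b: float, dt: np.ndarray, d: np.ndarray) -> tuple[float, float, float]:
    """Closed-form (a, c) and RSS for a fixed exponent b (linear submodel)."""
    with np.errstate(over="ignore", invalid="ignore"):
        col = np.power(dt, b, where=dt > 0, out=np.zeros_like(dt))
    if not np.isfinite(col).all():
        return np.inf, 0.0, float(d.mean())
    # 2x2 normal equations for (a, c); fall back to flat when singular
    n = len(dt)
    su, suu = col.sum(), col @ col
    sd, sud = d.sum(), col @ d
    det = suu * n - su * su
    if det <= 1e-12 * max(suu * n, 1e-300):
        c = float(d.mean())
        return float(((d - c) ** 2).sum()), 0.0, c
    a = (n * sud - su * sd) / det
    c = (suu * sd - su * sud) / det
    resid = d - a * col - c
    return float(resid @ resid), float(a), float(c)


def fit_powerlaw(
    delta_weeks, dissimilarity, b_range: tuple[float, float] = (-5.0, 5.0),
    grid_size: int = 201, group: str | None = None,
) -> PowerLawFit:
    """Derivative-free least-squares fit of the power law.

    The surface is multimodal in the exponent b, but for fixed b the model
    is linear in (a, c), so b is profiled out: the profiled RSS is scanned
    on a dense grid over ``b_range`` (unconstrained in sign, as a free
    simplex search would be) and the best bracket refined with Brent's
    derivative-free minimiser; amplitude and intercept follow in closed
    form.  The b = 0 grid point reduces to the flat model, so
    ``rss <= flat_rss`` always.  Time differences must be positive
    (negative exponents are admissible).
    """
    dt = np.asarray(delta_weeks, dtype=float)
    d = np.asarray(dissimilarity, dtype=float)
    if len(dt) < 4:
        raise ValueError("power-law fit needs >= 4 pairs")
    if (dt <= 0).any():
        raise ValueError("power-law fit requires positive time differences")
    if len(np.unique(dt)) < 2:
        raise ValueError("power-law fit needs >= 2 distinct time differences")
    flat_rss = float(((d - d.mean()) ** 2).sum())
    bgrid = np.linspace(b_range[0], b_range[1], grid_size)
    if not np.any(bgrid == 0.0):
        bgrid = np.sort(np.append(bgrid, 0.0))
    rss_grid = np.array([_profiled_rss(b, dt, d)[0] for b in bgrid])
    k = int(np.argmin(rss_grid))
    lo = bgrid[max(k - 1, 0)]
    hi = bgrid[min(k + 1, grid_size - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda b: _profiled_rss(b, dt, d)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-12},
        )
        b_hat = float(res.x) if res.fun <= rss_grid[k] else float(bgrid[k])
    else:
        b_hat = float(bgrid[k])
    rss, a, c = _profiled_rss(b_hat, dt, d)
    if rss >= flat_rss:  # degenerate: no trend beats the flat model
        a, b_hat, c, rss = 0.0, 0.0, float(d.mean()), flat_rss
    return PowerLawFit(a, b_hat, c, rss, flat_rss, len(dt), group)


def powerlaw_vs_flat_test(fit: PowerLawFit) -> tuple[float, float]:
    """Nested F-test of the power law (3 params) against a flat line (1).

    F = ((RSS0 - RSS1)/2) / (RSS1/(n - 3)).
    """
    if fit.n <= 3:
        raise ValueError("F-test needs n > 3")
    df1, df2 = 2, fit.n - 3
    if fit.rss == 0:
        return np.inf, 0.0
    f = ((fit.flat_rss - fit.rss) / df1) / (fit.rss / df2)
    return float(f), float(stats.f.sf(f, df1, df2))


def powerlaw_group_compare(pairs_by_group: dict[str, tuple]) -> tuple[float, float]:
    """F-test comparing one joint power law with separate per-group fits.

    ``pairs_by_group`` maps group label to ``(delta_weeks, dissimilarity)``.
    The joint model (3 parameters) is nested in the separate-fits model
    (3 per group).
    """
    if len(pairs_by_group) < 2:
        raise ValueError("group comparison needs >= 2 groups")
    dts, ds, sep_rss = [], [], 0.0
    for group, (dt, d) in pairs_by_group.items():
        fit = fit_powerlaw(dt, d, group=group)
        sep_rss += fit.rss
        dts.append(np.asarray(dt, dtype=float))
        ds.append(np.asarray(d, dtype=float))
    joint = fit_powerlaw(np.concatenate(dts), np.concatenate(ds))
    n = joint.n
    k_sep = 3 * len(pairs_by_group)
    df1 = k_sep - 3
    df2 = n - k_sep
    if df2 <= 0:
        raise ValueError("too few pairs for the separate-fits model")
    if sep_rss == 0:
        return np.inf, 0.0
    f = ((joint.rss - sep_rss) / df1) / (sep_rss / df2)
    f = max(f, 0.0)
    return float(f), float(stats.f.sf(f, df1, df2))


class PowerLawTrend(BaseEstimator, RegressorMixin):
    """sklearn-style facade for the power-law divergence fit."""

    def __init__(self, b_range: tuple[float, float] = (-5.0, 5.0), grid_size: int = 201):
        self.b_range = b_range
        self.grid_size = grid_size

    def fit(self, X, y) -> "PowerLawTrend":
        X = np.asarray(X, dtype=float).reshape(-1)
        self.fit_ = fit_powerlaw(X, y, b_range=self.b_range, grid_size=self.grid_size)
        self.coef_ = np.array([self.fit_.a, self.fit_.b, self.fit_.c])
        return self

    def predict(self, X) -> np.ndarray:
        return self.fit_.predict(np.asarray(X, dtype=float).reshape(-1))


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PermutationTestResult:
    """Outcome of a permutation test with its scheme and permutation count."""

    statistic: float
    p_value: float
    n_permutations: int
    scheme: str
    r_squared: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        assert self.p_value >= 1.0 / (self.n_permutations + 1) - 1e-12


def _permutation_p(perm_stats: np.ndarray, observed: float) -> float:
    """(1 + #{perm >= obs}) / (1 + n_perm)."""
    return float((1 + np.sum(perm_stats >= observed - 1e-12)) / (1 + len(perm_stats)))


def within_subject_permutation(
    rng: np.random.Generator, subjects: np.ndarray
) -> np.ndarray:
    """Index permutation that shuffles sample positions within each subject."""
    perm = np.arange(len(subjects))
    for s in pd.unique(subjects):
        idx = np.nonzero(subjects == s)[0]
        perm[idx] = rng.permutation(idx)
    return perm


def subject_relabel_permutation(
    rng: np.random.Generator, subjects: np.ndarray, values: np.ndarray
) -> np.ndarray:
    """Permute a subject-constant variable across subjects, relabel samples.

    Every permutation keeps the variable constant within subject.
    """
    uniq = pd.unique(subjects)
    value_of = {}
    for s in uniq:
        vals = values[subjects == s]
        if len(pd.unique(vals)) > 1:
            raise ValueError(f"variable is not constant within subject {s!r}")
        value_of[s] = vals[0]
    shuffled = rng.permutation(uniq)
    new_value = {s: value_of[t] for s, t in zip(uniq, shuffled)}
    return np.array([new_value[s] for s in subjects])


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------

def mantel_inter(
    dm_a: DistanceMatrix,
    dm_b: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermutationTestResult:
    """Cross-sectional Mantel test on subject-level distance matrices.

    Pearson correlation of the off-diagonal entries; the null distribution
    permutes subject labels of one matrix freely.  One-sided (greater), the
    convention for positive covariation between measurement types;
    ``r_squared`` reports the variance explained.
    """
    if list(dm_a.ids) != list(dm_b.ids):
        dm_b = dm_b.filter(dm_a.ids)
    a = dm_a.condensed_form()
    b = dm_b.condensed_form()
    observed = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    n = len(dm_a.ids)
    data_b = dm_b.data
    perm_stats = np.empty(n_perm)
    for i in range(n_perm):
        p = rng.permutation(n)
        bp = data_b[np.ix_(p, p)][np.triu_indices(n, k=1)]
        perm_stats[i] = np.corrcoef(a, bp)[0, 1]
    return PermutationTestResult(
        observed,
        _permutation_p(perm_stats, observed),
        n_perm,
        FREE,
        r_squared=observed**2,
        n=n,
    )


def mantel_intra(
    dm_a: DistanceMatrix,
    dm_b: DistanceMatrix,
    metadata: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    permutation_audit: list | None = None,
) -> PermutationTestResult:
    """Longitudinal Mantel test restricted to within-subject distances.

    The statistic is the Pearson correlation between the two matrices'
    entries over within-subject sample pairs only; the null permutes sample
    labels independently within each subject block of one matrix, never
    across subjects.  Pass a list as ``permutation_audit`` to capture every
    permutation used (for auditing the restriction).
    """
    ids = list(dm_a.ids)
    if list(dm_b.ids) != ids:
        dm_b = dm_b.filter(ids)
    subjects = metadata.set_index("sample_id").loc[ids, "subject_id"].to_numpy()
    iu, ju = np.triu_indices(len(ids), k=1)
    within = subjects[iu] == subjects[ju]
    if within.sum() < 3:
        raise ValueError("need >= 3 within-subject pairs")
    ai, aj = iu[within], ju[within]
    a = dm_a.data[ai, aj]
    data_b = dm_b.data
    observed = float(np.corrcoef(a, data_b[ai, aj])[0, 1])
    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_perm)
    for i in range(n_perm):
        perm = within_subject_permutation(rng, subjects)
        if permutation_audit is not None:
            permutation_audit.append(perm.copy())
        perm_stats[i] = np.corrcoef(a, data_b[perm[ai], perm[aj]])[0, 1]
    return PermutationTestResult(
        observed,
        _permutation_p(perm_stats, observed),
        n_perm,
        WITHIN_SUBJECT,
        r_squared=observed**2,
        n=int(within.sum()),
    )


# ---------------------------------------------------------------------------
# PERMANOVA with restricted permutations
# ---------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centred inner-product matrix G = -(1/2) J (D*D) J."""
    a = -0.5 * d**2
    n = len(d)
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _design_matrix(values: np.ndarray) -> np.ndarray:
    """Model matrix with intercept; categorical values are dummy-coded."""
    v = pd.Series(values)
    if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype) or v.dtype == bool:
        dummies = pd.get_dummies(v, drop_first=True).to_numpy(dtype=float)
    else:
        dummies = v.to_numpy(dtype=float).reshape(-1, 1)
    return np.column_stack([np.ones(len(v)), dummies])


def _permanova_stat(g: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R^2 of a single-term distance-based linear model."""
    x = _design_matrix(values)
    n, k = x.shape
    hat = x @ np.linalg.pinv(x)
    ss_total = np.trace(g)
    # tr(H G H) = tr(G H) for an idempotent symmetric hat matrix
    ss_model = float(np.sum(g * hat))
    ss_resid = ss_total - ss_model
    df1 = k - 1
    df2 = n - k
    if df1 == 0 or df2 == 0 or ss_resid <= 0:
        return np.inf, 1.0
    f = (ss_model / df1) / (ss_resid / df2)
    return float(f), float(ss_model / ss_total)


def blocked_permanova(
    dm: DistanceMatrix,
    variable: str,
    metadata: pd.DataFrame,
    scheme: str = WITHIN_SUBJECT,
    n_perm: int = 999,
    seed: int | None = None,
    impute_mean: bool = True,
) -> PermutationTestResult:
    """Single-variable PERMANOVA with a repeated-measures permutation scheme.

    The pseudo-F and R^2 (= SS_model / SS_total) come from the
    Gower-centred distance matrix.  The null distribution honours the
    longitudinal design: ``within-subject`` permutes the variable's values
    within each subject block (time-varying variables);
    ``subject-relabel`` permutes whole subjects' values and relabels their
    samples (subject-constant variables); ``free`` permutes across all
    samples (models that include inter-individual variance).  Missing
    numeric covariate values are mean-imputed.
    """
    if scheme not in (FREE, WITHIN_SUBJECT, SUBJECT_RELABEL):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    ids = list(dm.ids)
    meta = metadata.set_index("sample_id").loc[ids]
    values = meta[variable].to_numpy()
    if impute_mean and np.issubdtype(np.asarray(values).dtype, np.number):
        v = values.astype(float)
        if np.isnan(v).any():
            v[np.isnan(v)] = np.nanmean(v)
        values = v
    subjects = meta["subject_id"].to_numpy()
    g = _gower_center(dm.data)
    observed_f, r2 = _permanova_stat(g, values)
    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_perm)
    for i in range(n_perm):
        if scheme == FREE:
            perm_values = values[rng.permutation(len(values))]
        elif scheme == WITHIN_SUBJECT:
            perm_values = values[within_subject_permutation(rng, subjects)]
        else:
            perm_values = subject_relabel_permutation(rng, subjects, values)
        perm_stats[i] = _permanova_stat(g, perm_values)[0]
    return PermutationTestResult(
        observed_f,
        _permutation_p(perm_stats, observed_f),
        n_perm,
        scheme,
        r_squared=r2,
        n=len(ids),
    )


def permanova_r2_bruteforce(d: np.ndarray, groups: np.ndarray) -> float:
    """Independent R^2 via the classic sum-of-squares decomposition.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within = per-group analogues;
    R^2 = 1 - SS_within / SS_total.  Valid for a categorical one-way
    design; used as an oracle for the Gower-trace computation.
    """
    n = len(groups)
    iu, ju = np.triu_indices(n, k=1)
    ss_total = np.sum(d[iu, ju] ** 2) / n
    ss_within = 0.0
    for grp in pd.unique(groups):
        idx = np.nonzero(groups == grp)[0]
        if len(idx) < 2:
            continue
        sub = d[np.ix_(idx, idx)]
        su, sv = np.triu_indices(len(idx), k=1)
        ss_within += np.sum(sub[su, sv] ** 2) / len(idx)
    return float(1.0 - ss_within / ss_total)
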