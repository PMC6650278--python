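"""Differential abundance, residualisation, and cross-omic networks.

Per-feature differential abundance uses a linear mixed-effects model with a
subject random intercept:

    feature ~ intercept + diagnosis + diagnosis/dysbiosis
              + antibiotic use + consent age + site

where dysbiosis enters nested within each diagnosis group and recruitment
site is adjusted as a fixed categorical covariate (keeping the model to one
variance component).  The model is fit by profiled REML: the variance ratio
theta = sigma^2_subject / sigma^2_residual is profiled out with a
one-dimensional log-scale search, the coefficients follow in closed form by
GLS, and significance is Wald's test.  Benjamini–Hochberg adjustment is
applied per term across the features of a measurement type.

Cross-measurement-type interactions correlate *residuals* of the same model
(optionally excluding dysbiosis as a covariate, to retain dysbiosis-driven
structure) all-against-all with Spearman's rho on temporally matched
samples, with BH control per type pair, a top-k edge budget, and hub
annotation.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .profiles import AbundanceTable, arcsinsqrt_transform, log_pseudocount_transform

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Random-intercept linear mixed model (profiled REML)
# ---------------------------------------------------------------------------

class RandomInterceptLMM(BaseEstimator):
    """Linear mixed model with one random intercept per group.

    y = X beta + Z b + e,  b ~ N(0, sigma_b^2),  e ~ N(0, sigma_e^2).

    The restricted likelihood is profiled over
    theta = sigma_b^2 / sigma_e^2: for fixed theta the covariance
    V = I + theta Z Z' is block diagonal with per-group inverse
    (I + theta J)^{-1} = I - theta/(1 + m theta) J, so GLS coefficients and
    the REML criterion are closed-form; theta is found by a bracketed
    log-scale one-dimensional minimisation over [1e-8, 1e8].

    Attributes after fit: ``coef_``, ``bse_``, ``zvalues_``, ``pvalues_``
    (Wald, asymptotic normal), ``theta_``, ``sigma2_resid_``,
    ``sigma2_subject_``, ``resid_`` (conditional residuals, orthogonal to
    the fixed-effect design), ``reml_criterion_``.
    """

    def __init__(self, theta_bounds: tuple[float, float] = (1e-8, 1e8)):
        self.theta_bounds = theta_bounds

    # -- internals ----------------------------------------------------
    @staticmethod
    def _group_blocks(groups: np.ndarray) -> list[np.ndarray]:
        return [np.nonzero(groups == g)[0] for g in pd.unique(groups)]

    def _profile(self, theta: float, x, y, blocks):
        """GLS fit and REML criterion at fixed variance ratio theta."""
        p = x.shape[1]
        n = len(y)
        xtvx = np.zeros((p, p))
        xtvy = np.zeros(p)
        ytvy = 0.0
        logdet_v = 0.0
        for idx in blocks:
            xg, yg = x[idx], y[idx]
            m = len(idx)
            c = theta / (1.0 + m * theta)
            sx = xg.sum(axis=0)
            sy = yg.sum()
            xtvx += xg.T @ xg - c * np.outer(sx, sx)
            xtvy += xg.T @ yg - c * sx * sy
            ytvy += yg @ yg - c * sy * sy
            logdet_v += np.log1p(m * theta)
        beta = np.linalg.solve(xtvx, xtvy)
        rss = float(ytvy - 2 * beta @ xtvy + beta @ xtvx @ beta)
        rss = max(rss, 1e-300)
        sigma2 = rss / (n - p)
        sign, logdet_xtvx = np.linalg.slogdet(xtvx)
        criterion = (n - p) * np.log(sigma2) + logdet_v + logdet_xtvx
        return criterion, beta, sigma2, xtvx

    def reml_criterion(self, theta: float, X, y, groups) -> float:
        """The profiled REML objective (up to a constant); used by oracles."""
        x = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        blocks = self._group_blocks(np.asarray(groups))
        return self._profile(theta, x, y, blocks)[0]

    def fit(self, X, y, groups) -> "RandomInterceptLMM":
        x = np.asarray(X, dtype=float)
        yv = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        n, p = x.shape
        rank = np.linalg.matrix_rank(x)
        if rank < p:
            cols = getattr(X, "columns", pd.RangeIndex(p))
            dropped = _collinear_columns(x, list(cols))
            raise ValueError(f"rank-deficient design; collinear columns: {dropped}")
        blocks = self._group_blocks(groups)

        lo, hi = np.log(self.theta_bounds[0]), np.log(self.theta_bounds[1])
        grid = np.linspace(lo, hi, 61)
        vals = [self._profile(np.exp(t), x, yv, blocks)[0] for t in grid]
        k = int(np.argmin(vals))
        bracket_lo = grid[max(k - 1, 0)]
        bracket_hi = grid[min(k + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda lt: self._profile(np.exp(lt), x, yv, blocks)[0],
            bounds=(bracket_lo, bracket_hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        theta = float(np.exp(res.x))
        # the boundary theta -> 0 (pure OLS) is always a candidate
        crit0 = self._profile(self.theta_bounds[0], x, yv, blocks)[0]
        if crit0 < res.fun:
            theta = self.theta_bounds[0]
        criterion, beta, sigma2, xtvx = self._profile(theta, x, yv, blocks)

        self.theta_ = theta
        self.reml_criterion_ = float(criterion)
        self.sigma2_resid_ = float(sigma2)
        self.sigma2_subject_ = float(theta * sigma2)
        self.coef_ = beta
        cov = np.linalg.inv(xtvx) * sigma2
        self.bse_ = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore", invalid="ignore"):
            self.zvalues_ = beta / self.bse_
        self.pvalues_ = 2 * stats.norm.sf(np.abs(self.zvalues_))
        # conditional residuals e = V^{-1}(y - X beta): subject offsets removed
        marginal = yv - x @ beta
        resid = marginal.copy()
        for idx in blocks:
            m = len(idx)
            c = theta / (1.0 + m * theta)
            resid[idx] -= c * marginal[idx].sum()
        self.resid_ = resid
        self.feature_names_ = list(getattr(X, "columns", pd.RangeIndex(p)))
        return self


def _collinear_columns(x: np.ndarray, names: list) -> list:
    """Greedy identification of columns not adding rank (for error messages)."""
    dropped = []
    kept: list[int] = []
    for j in range(x.shape[1]):
        cand = x[:, kept + [j]]
        if np.linalg.matrix_rank(cand) > len(kept):
            kept.append(j)
        else:
            dropped.append(names[j])
    return dropped


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def build_design(
    metadata: pd.DataFrame,
    nested_dysbiosis: bool = True,
    include_dysbiosis: bool = True,
    covariates: tuple[str, ...] = ("antibiotic_use", "consent_age"),
    site_column: str | None = "recruitment_site",
) -> pd.DataFrame:
    """Fixed-effect design for the differential-abundance model.

    Intercept; diagnosis dummies (nonIBD reference); dysbiosis as a binary
    indicator nested within each diagnosis group (or a single indicator
    when ``nested_dysbiosis`` is False); the listed covariates; and
    recruitment site as fixed categorical dummies.  All-zero nested columns
    (e.g. a group with no dysbiotic samples) are dropped with a log
    message.
    """
    n = len(metadata)
    cols = {"intercept": np.ones(n)}
    diag = metadata["diagnosis"].to_numpy()
    for level in ("UC", "CD"):
        if (diag == level).any():
            cols[f"diagnosis[{level}]"] = (diag == level).astype(float)
    if include_dysbiosis and "dysbiotic" in metadata.columns:
        dys = metadata["dysbiotic"].to_numpy(dtype=bool).astype(float)
        if nested_dysbiosis:
            for level in ("nonIBD", "UC", "CD"):
                col = dys * (diag == level)
                if col.any():
                    cols[f"dysbiotic[{level}]"] = col
                else:
                    logger.info("dropping all-zero nested term dysbiotic[%s]", level)
        elif dys.any():
            cols["dysbiotic"] = dys
        else:
            logger.info("dropping all-zero term dysbiotic")
    for cov in covariates:
        if cov in metadata.columns:
            cols[cov] = metadata[cov].to_numpy(dtype=float)
    if site_column and site_column in metadata.columns:
        sites = pd.get_dummies(metadata[site_column], prefix="site", drop_first=True)
        for c in sites.columns:
            cols[c] = sites[c].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=metadata["sample_id"].to_numpy())


_TRANSFORMS = {
    "arcsinsqrt": arcsinsqrt_transform,
    "log": log_pseudocount_transform,
    None: lambda t: t,
    "none": lambda t: t,
}


def differential_abundance(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    transform: str | None = "arcsinsqrt",
    **design_kwargs,
) -> pd.DataFrame:
    """Per-feature mixed-model differential abundance with BH adjustment.

    Applies the type-appropriate transform (arcsine square root for
    relative abundances, log1p-style for intensities), fits the
    random-intercept model per feature, and returns a tidy frame
    (feature, term, coef, se, z, p, q) with BH q-values computed per term
    across features.  The table should be prevalence/variance-filtered
    first.
    """
    tf = _TRANSFORMS[transform]
    data = tf(table).data
    meta = metadata.set_index("sample_id").loc[[str(s) for s in data.columns]].reset_index()
    design = build_design(meta, **design_kwargs)
    groups = meta["subject_id"].to_numpy()
    rows = []
    for feature in data.index:
        y = data.loc[feature].to_numpy(dtype=float)
        fit = RandomInterceptLMM().fit(design, y, groups)
        for term, coef, se, z, p in zip(
            fit.feature_names_, fit.coef_, fit.bse_, fit.zvalues_, fit.pvalues_
        ):
            if term == "intercept":
                continue
            rows.append(
                {"feature": feature, "term": term, "coef": coef, "se": se, "z": z, "p": p}
            )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for term, idx in out.groupby("term").groups.items():
        out.loc[idx, "q"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    return out


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    return multipletests(pvalues, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Residualisation
# ---------------------------------------------------------------------------

def residualize(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    adjust_for_dysbiosis: bool = True,
    transform: str | None = None,
    min_samples_per_subject: int = 4,
    longitudinal: bool = True,
    covariates: tuple[str, ...] = ("antibiotic_use", "consent_age"),
) -> pd.DataFrame:
    """Per-feature residuals after removing covariate and subject effects.

    Covariates: diagnosis, the listed columns, and dysbiosis status when
    ``adjust_for_dysbiosis`` (the *adjusted* model; the unadjusted variant
    omits it so dysbiosis-linked structure survives into the network).
    Longitudinal measurement types use the random-intercept model and drop
    subjects contributing fewer than ``min_samples_per_subject`` samples;
    baseline-only types use the fixed-effects model without subject
    intercepts.  Returns features x samples residuals.
    """
    tf = _TRANSFORMS[transform]
    data = tf(table).data
    meta = metadata.set_index("sample_id").loc[[str(s) for s in data.columns]].reset_index()
    if longitudinal:
        counts = meta.groupby("subject_id")["sample_id"].size()
        keep_subjects = counts[counts >= min_samples_per_subject].index
        meta = meta[meta["subject_id"].isin(keep_subjects)]
        data = data.loc[:, meta["sample_id"].to_numpy()]
        if data.shape[1] == 0:
            raise ValueError("no subject has enough samples to residualise")
    design = build_design(
        meta,
        nested_dysbiosis=False,
        include_dysbiosis=adjust_for_dysbiosis,
        covariates=covariates,
        site_column=None,
    )
    x = design.to_numpy(dtype=float)
    groups = meta["subject_id"].to_numpy()
    resids = {}
    for feature in data.index:
        y = data.loc[feature].to_numpy(dtype=float)
        if longitudinal:
            fit = RandomInterceptLMM().fit(design, y, groups)
            resids[feature] = fit.resid_
        else:
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            resids[feature] = y - x @ beta
    return pd.DataFrame(resids, index=data.columns).T


# ---------------------------------------------------------------------------
# Spearman association network
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AssociationNetwork:
    """Typed nodes with signed Spearman edges, q-values, and hub flags."""

    graph: nx.Graph
    edges: pd.DataFrame  # source, target, source_type, target_type, rho, p, q

    @property
    def hubs(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("hub")]


def _spearman_cross(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-against-all Spearman rho and t-approximation p for two blocks.

    ``a`` is (features_a, n), ``b`` is (features_b, n); average ranks
    handle ties.
    """
    n = a.shape[1]
    ra = np.apply_along_axis(stats.rankdata, 1, a)
    rb = np.apply_along_axis(stats.rankdata, 1, b)
    ra = (ra - ra.mean(axis=1, keepdims=True)) / np.sqrt(
        ((ra - ra.mean(axis=1, keepdims=True)) ** 2).sum(axis=1, keepdims=True)
    )
    rb = (rb - rb.mean(axis=1, keepdims=True)) / np.sqrt(
        ((rb - rb.mean(axis=1, keepdims=True)) ** 2).sum(axis=1, keepdims=True)
    )
    rho = np.clip(ra @ rb.T, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p[~np.isfinite(t)] = 0.0
    return rho, p


def spearman_network(
    residuals_by_type: Mapping[str, pd.DataFrame],
    fdr_standard: float = 0.05,
    fdr_serology: float = 0.25,
    top_k: int = 300,
    hub_degree: int = 20,
    min_samples: int = 8,
    dysbiosis_associated: set[str] | None = None,
) -> AssociationNetwork:
    """All-against-all Spearman network across measurement types.

    Each frame holds residuals (features x matched samples); for every type
    pair the shared sample columns are aligned (pairs with fewer than
    ``min_samples`` are skipped), correlations computed with average-rank
    ties and t-approximation p-values, BH-adjusted within the pair, kept if
    q is below the pair's FDR tier (the serology tier applies when either
    type name contains "serology"), optionally restricted to edges touching
    a dysbiosis-associated node, ranked by ascending p (ties: larger |rho|
    first) and truncated to ``top_k`` per pair.  Nodes with at least
    ``hub_degree`` connections are flagged as hubs.
    """
    types = sorted(residuals_by_type)
    edges = []
    for ta, tb in ((x, y) for i, x in enumerate(types) for y in types[i + 1 :]):
        da, db = residuals_by_type[ta], residuals_by_type[tb]
        shared = da.columns.intersection(db.columns)
        if len(shared) < min_samples:
            logger.info("skipping pair %s~%s: %d shared samples", ta, tb, len(shared))
            continue
        rho, p = _spearman_cross(
            da[shared].to_numpy(dtype=float), db[shared].to_numpy(dtype=float)
        )
        q = bh_adjust(p.ravel()).reshape(p.shape)
        tier = fdr_serology if ("serology" in ta or "serology" in tb) else fdr_standard
        ii, jj = np.nonzero(q < tier)
        pair = pd.DataFrame(
            {
                "source": da.index.to_numpy()[ii],
                "target": db.index.to_numpy()[jj],
                "source_type": ta,
                "target_type": tb,
                "rho": rho[ii, jj],
                "p": p[ii, jj],
                "q": q[ii, jj],
            }
        )
        if dysbiosis_associated is not None:
            keep = pair["source"].isin(dysbiosis_associated) | pair["target"].isin(
                dysbiosis_associated
            )
            pair = pair[keep]
        pair = pair.sort_values(
            ["p", "rho"], key=lambda s: s if s.name == "p" else -s.abs()
        ).head(top_k)
        edges.append(pair)
    edge_df = (
        pd.concat(edges, ignore_index=True)
        if edges
        else pd.DataFrame(
            columns=["source", "target", "source_type", "target_type", "rho", "p", "q"]
        )
    )
    graph = nx.Graph()
    for mtype, frame in residuals_by_type.items():
        for f in frame.index:
            graph.add_node(
                f,
                measurement_type=mtype,
                dysbiosis_associated=bool(
                    dysbiosis_associated and f in dysbiosis_associated
                ),
            )
    for _, e in edge_df.iterrows():
        graph.add_edge(
            e["source"],
            e["target"],
            rho=float(e["rho"]),
            p=float(e["p"]),
            q=float(e["q"]),
            pair=f"{e['source_type']}~{e['target_type']}",
        )
    for node in graph.nodes:
        graph.nodes[node]["hub"] = graph.degree[node] >= hub_degree
    return AssociationNetwork(graph, edge_df)
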