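"""Calibration hierarchy and multilevel validation of clustered risk models.

Calibration of a risk model is assessed at increasing strength: *mean*
calibration (observed event rate equals average predicted risk, O/E = 1 and
calibration-in-the-large intercept 0), *weak* calibration (logistic
recalibration of the outcome on logit(p) has intercept 0 and slope 1),
*moderate* calibration (the flexible calibration curve lies on the
diagonal), and *strong* calibration (event rate equals predicted risk for
every covariate pattern) -- the last tabulated only when discrete patterns
are supplied.

For multicenter data a random-intercept logistic model

    logit P(y=1 | x, cluster c) = x'beta + u_c,   u_c ~ N(0, sigma_u^2)

supports three prediction types: center-specific (include u_c), average
center (u_c = 0), and population-averaged (integrate over u).  Their
calibration slope, intercept and c-statistic differ between the population
level and the within-cluster level because conditional and marginal effects
differ; both levels are reported.  The latent-scale intraclass correlation
is sigma_u^2 / (sigma_u^2 + pi^2/3).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.special import expit, logit
from scipy.special import logsumexp
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

__all__ = [
    "RIModelFit",
    "CalibrationReport",
    "MultilevelValidationReport",
    "fit_random_intercept_logistic",
    "fit_standard_logistic",
    "predict_three_ways",
    "calibration_hierarchy",
    "multilevel_validation",
    "concordance",
    "weighted_within_concordance",
    "LOGISTIC_RESIDUAL_VAR",
]

LOGISTIC_RESIDUAL_VAR = math.pi**2 / 3


def _clip_probs(p: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        logger.warning("predicted risks at 0/1 clipped to [%g, %g]", eps, 1 - eps)
    return np.clip(p, eps, 1 - eps)


# ---------------------------------------------------------------------------
# Random-intercept logistic model (Gauss-Hermite maximum likelihood)
# ---------------------------------------------------------------------------


@dataclass
class RIModelFit:
    """Random-intercept logistic regression fit.

    ``coef`` includes the intercept first.  ``cluster_effects`` maps cluster
    label to the posterior-mean random intercept.  ``icc`` is on the latent
    scale: sigma_u^2 / (sigma_u^2 + pi^2/3).
    """

    coef: np.ndarray
    sigma2_u: float
    cluster_effects: dict
    loglik: float
    converged: bool
    names: list[str] = field(default_factory=list)

    @property
    def icc(self) -> float:
        return self.sigma2_u / (self.sigma2_u + LOGISTIC_RESIDUAL_VAR)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.coef[0] + X @ self.coef[1:]


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    # log p(y | eta), numerically stable
    return -np.logaddexp(0.0, np.where(y == 1, -eta, eta))


def fit_random_intercept_logistic(
    y,
    X,
    cluster,
    n_quad: int = 15,
) -> RIModelFit:
    """Maximum likelihood via adaptive Gauss-Hermite quadrature.

    Each cluster's likelihood integral over u ~ N(0, sigma_u^2) is evaluated
    with ``n_quad`` Hermite nodes recentred at the cluster's posterior mode
    and rescaled by its curvature (the integrand is sharply peaked in large
    clusters, where fixed nodes would be badly inaccurate); (beta,
    log sigma_u) are then optimised jointly.  Posterior-mean cluster
    intercepts are returned for center-specific prediction.
    """
    y = np.asarray(y).astype(int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    cluster = np.asarray(cluster)
    order = np.argsort(cluster, kind="stable")
    ys, Xs, cs = y[order], X[order], cluster[order]
    labels, starts = np.unique(cs, return_index=True)
    starts = np.sort(starts)
    n_clusters = len(labels)
    Xd = np.column_stack([np.ones(len(ys)), Xs])
    yv = ys.astype(float)
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    log_wstar = np.log(weights) + nodes**2  # GH weights with kernel removed

    def _cluster_logint(params, return_posterior=False):
        beta = params[:-1]
        sigma = math.exp(params[-1])
        s2 = sigma * sigma
        eta = Xd @ beta
        # posterior mode per cluster by Newton on
        # h(u) = sum_j log p(y_j | eta_j + u) - u^2 / (2 s2)
        rep = np.diff(np.append(starts, len(ys)))
        m = np.zeros(n_clusters)
        for _ in range(50):
            p = expit(eta + np.repeat(m, rep))
            g = np.add.reduceat(yv - p, starts) - m / s2
            h = -np.add.reduceat(p * (1 - p), starts) - 1.0 / s2
            step = g / h
            m -= step
            if np.max(np.abs(step)) < 1e-10:
                break
        p = expit(eta + np.repeat(m, rep))
        curv = np.add.reduceat(p * (1 - p), starts) + 1.0 / s2  # -h''(m)
        tau = 1.0 / np.sqrt(curv)
        # adaptive nodes u_ck = m_c + sqrt(2) tau_c z_k
        U = m[:, None] + math.sqrt(2.0) * tau[:, None] * nodes[None, :]
        # h(u) at the nodes
        hU = np.empty_like(U)
        for k in range(n_quad):
            uk = np.repeat(U[:, k], rep)
            Mk = eta + uk
            ll = -np.logaddexp(0.0, np.where(ys == 1, -Mk, Mk))
            hU[:, k] = (
                np.add.reduceat(ll, starts)
                - U[:, k] ** 2 / (2 * s2)
            )
        lse = logsumexp(hU + log_wstar[None, :], axis=1)
        logint = (
            0.5 * math.log(2.0)
            + np.log(tau)
            + lse
            - 0.5 * math.log(2 * math.pi * s2)
        )
        if not return_posterior:
            return logint
        wpost = np.exp(hU + log_wstar[None, :] - lse[:, None])
        wpost /= wpost.sum(axis=1, keepdims=True)
        u_hat = (wpost * U).sum(axis=1)
        return logint, u_hat

    def nll(params):
        return -float(np.sum(_cluster_logint(params)))

    glm = sm.GLM(ys, Xd, family=sm.families.Binomial()).fit()
    x0 = np.append(glm.params, math.log(0.5))
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", options={"maxiter": 300}
    )
    beta = res.x[:-1]
    sigma2 = math.exp(res.x[-1]) ** 2
    _, u_hat = _cluster_logint(res.x, return_posterior=True)
    effects = {lab: float(uh) for lab, uh in zip(labels, u_hat)}
    if not res.success:
        logger.warning("random-intercept logistic fit did not fully converge")
    return RIModelFit(
        beta,
        float(sigma2),
        effects,
        -float(res.fun),
        bool(res.success),
        names=["(intercept)"] + [f"x{i}" for i in range(1, Xd.shape[1])],
    )


def fit_standard_logistic(y, X) -> RIModelFit:
    """Ordinary logistic regression in the same container (sigma2_u = 0)."""
    y = np.asarray(y).astype(int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Xd = np.column_stack([np.ones(len(y)), X])
    glm = sm.GLM(y, Xd, family=sm.families.Binomial()).fit()
    return RIModelFit(
        np.asarray(glm.params), 0.0, {}, float(glm.llf), True,
        names=["(intercept)"] + [f"x{i}" for i in range(1, Xd.shape[1])],
    )


def predict_three_ways(
    fit: RIModelFit,
    X,
    cluster,
    n_quad: int = 50,
) -> pd.DataFrame:
    """Center-specific, average-center and population-averaged risks.

    center_specific = expit(lp + u_hat_c) (missing for unknown clusters,
    logged); average_center = expit(lp); population_averaged integrates
    expit(lp + u) over N(0, sigma_u^2) with ``n_quad`` Gauss-Hermite nodes.
    With sigma_u^2 = 0 all three coincide.
    """
    cluster = np.asarray(cluster)
    lp = fit.linear_predictor(X)
    avg = expit(lp)
    u_map = fit.cluster_effects
    u = np.array([u_map.get(c, np.nan) for c in cluster])
    n_missing = int(np.isnan(u).sum())
    if n_missing:
        logger.info(
            "center-specific predictions unavailable for %d rows (new clusters)",
            n_missing,
        )
    center = expit(lp + u)
    if fit.sigma2_u > 0:
        nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
        w = weights / math.sqrt(math.pi)
        offs = math.sqrt(2.0 * fit.sigma2_u) * nodes
        pop = expit(lp[:, None] + offs[None, :]) @ w
    else:
        pop = avg.copy()
    return pd.DataFrame(
        {
            "center_specific": center,
            "average_center": avg,
            "population_averaged": pop,
        }
    )


# ---------------------------------------------------------------------------
# Calibration hierarchy
# ---------------------------------------------------------------------------


def _rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted (natural) cubic spline basis, linear in the tails."""
    k = knots
    kn = len(k)
    norm2 = (k[-1] - k[0]) ** 2

    def pos3(v):
        return np.where(v > 0, v**3, 0.0)

    cols = [x]
    for j in range(kn - 2):
        term = (
            pos3(x - k[j])
            - pos3(x - k[-2]) * (k[-1] - k[j]) / (k[-1] - k[-2])
            + pos3(x - k[-1]) * (k[-2] - k[j]) / (k[-1] - k[-2])
        )
        cols.append(term / norm2)
    return np.column_stack(cols)


@dataclass
class CalibrationReport:
    """Mean/weak/moderate(/strong) calibration statistics."""

    n: int
    oe_ratio: float
    citl: float
    citl_se: float
    slope: float
    slope_se: float
    slope_intercept: float
    curve: pd.DataFrame | None
    strong_table: pd.DataFrame | None
    warnings: list[str] = field(default_factory=list)


def calibration_hierarchy(
    y,
    p,
    patterns=None,
    n_knots: int = 5,
    curve_grid: int = 100,
    min_n_curve: int = 50,
) -> CalibrationReport:
    """Assess calibration at every level of the hierarchy.

    * mean: O/E = event rate / mean(p); CITL from logistic regression of y on
      an offset logit(p);
    * weak: intercept and slope from logistic regression of y on logit(p);
    * moderate: flexible calibration curve from a restricted-cubic-spline
      (``n_knots`` knots at logit(p) quantiles) logistic smoother, evaluated
      on a predicted-risk grid (suppressed with a warning below
      ``min_n_curve`` subjects);
    * strong: observed event rate vs mean predicted risk per covariate
      pattern, only when ``patterns`` labels are supplied.
    """
    y = np.asarray(y).astype(int)
    p = _clip_probs(p)
    if y.shape != p.shape:
        raise ValueError("y and p must have equal length")
    n = y.size
    warns: list[str] = []
    lp = logit(p)

    oe = float(np.mean(y) / np.mean(p))
    ones = np.ones(n)
    citl_fit = sm.GLM(y, ones, family=sm.families.Binomial(), offset=lp).fit()
    weak = sm.GLM(y, np.column_stack([ones, lp]), family=sm.families.Binomial()).fit()

    curve = None
    if n >= min_n_curve:
        qs = np.array([0.05, 0.275, 0.5, 0.725, 0.95])[
            np.linspace(0, 4, n_knots).astype(int)
        ]
        knots = np.unique(np.quantile(lp, qs))
        if len(knots) >= 3:
            B = _rcs_basis(lp, knots)
            Xc = np.column_stack([ones, B])
            try:
                flex = sm.GLM(y, Xc, family=sm.families.Binomial()).fit(maxiter=100)
                grid_p = np.quantile(p, np.linspace(0.01, 0.99, curve_grid))
                gl = logit(np.clip(grid_p, 1e-6, 1 - 1e-6))
                Bg = _rcs_basis(gl, knots)
                obs = flex.predict(np.column_stack([np.ones(len(gl)), Bg]))
                curve = pd.DataFrame({"predicted": grid_p, "observed": obs})
            except Exception as e:  # pragma: no cover - separation etc.
                warns.append(f"flexible curve failed: {e}")
        else:
            warns.append("too few distinct risks for a spline curve")
    else:
        warns.append(f"curve suppressed: n={n} < {min_n_curve}")

    strong = None
    if patterns is not None:
        df = pd.DataFrame({"pattern": np.asarray(patterns), "y": y, "p": p})
        strong = (
            df.groupby("pattern")
            .agg(n=("y", "size"), event_rate=("y", "mean"), mean_risk=("p", "mean"))
            .reset_index()
        )
    return CalibrationReport(
        n=n,
        oe_ratio=oe,
        citl=float(citl_fit.params[0]),
        citl_se=float(citl_fit.bse[0]),
        slope=float(weak.params[1]),
        slope_se=float(weak.bse[1]),
        slope_intercept=float(weak.params[0]),
        curve=curve,
        strong_table=strong,
        warnings=warns,
    )


# ---------------------------------------------------------------------------
# Discrimination
# ---------------------------------------------------------------------------


def concordance(y, p) -> float:
    """C-statistic over all case/non-case pairs, ties counted 1/2.

    Invariant to strictly increasing transforms of p; exactly 0.5 when all
    predictions are identical.
    """
    y = np.asarray(y).astype(int)
    p = np.asarray(p, dtype=float)
    if y.min() == y.max():
        return float("nan")
    return float(roc_auc_score(y, p))


def weighted_within_concordance(y, p, cluster) -> tuple[float, list]:
    """Pairs-weighted average of per-cluster c-statistics.

    Clusters without both an event and a non-event carry no information on
    within-cluster discrimination and are excluded (returned in the second
    element).
    """
    y = np.asarray(y).astype(int)
    p = np.asarray(p, dtype=float)
    cluster = np.asarray(cluster)
    num = den = 0.0
    excluded = []
    for c in np.unique(cluster):
        m = cluster == c
        n1 = int(y[m].sum())
        n0 = int((~y[m].astype(bool)).sum())
        if n1 == 0 or n0 == 0:
            excluded.append(c)
            continue
        w = n1 * n0
        num += w * roc_auc_score(y[m], p[m])
        den += w
    if excluded:
        logger.info("within-cluster C: %d cluster(s) excluded", len(excluded))
    return (num / den if den > 0 else float("nan")), excluded


# ---------------------------------------------------------------------------
# Multilevel validation
# ---------------------------------------------------------------------------


@dataclass
class MultilevelValidationReport:
    """Calibration slope/intercept and C at population and cluster level."""

    n: int
    n_clusters: int
    slope: float
    slope_se: float
    citl: float
    c: float
    slope_within: float
    slope_within_se: float
    citl_within: float
    c_within: float
    excluded_clusters: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "population": {"slope": self.slope, "citl": self.citl, "c": self.c},
            "within_cluster": {
                "slope": self.slope_within,
                "citl": self.citl_within,
                "c": self.c_within,
            },
            "n": self.n,
            "n_clusters": self.n_clusters,
        }


def multilevel_validation(y, p, cluster) -> MultilevelValidationReport:
    """Validate predicted risks in clustered data at both levels.

    Population level: logistic regression of y on logit(p) (slope), offset
    model (calibration-in-the-large), and the overall c-statistic.  Within
    clusters: fixed cluster-specific intercepts with one common slope,
    cluster-size-weighted mean of per-cluster offset intercepts, and the
    pairs-weighted mean of per-cluster c-statistics.  Clusters lacking an
    event or a non-event are excluded from the within-cluster metrics.
    """
    y = np.asarray(y).astype(int)
    p = _clip_probs(p)
    cluster = np.asarray(cluster)
    keep = ~np.isnan(p)
    if keep.sum() < y.size:
        logger.info("dropping %d rows with missing predictions", y.size - keep.sum())
        y, p, cluster = y[keep], p[keep], cluster[keep]
    lp = logit(p)
    n = y.size
    ones = np.ones(n)

    weak = sm.GLM(y, np.column_stack([ones, lp]), family=sm.families.Binomial()).fit()
    citl = sm.GLM(y, ones, family=sm.families.Binomial(), offset=lp).fit()
    c_pop = concordance(y, p)

    labels = np.unique(cluster)
    valid = [
        c for c in labels if 0 < y[cluster == c].sum() < (cluster == c).sum()
    ]
    excluded = [c for c in labels if c not in set(valid)]
    slope_w = slope_w_se = citl_w = c_w = float("nan")
    if valid:
        m = np.isin(cluster, valid)
        D = pd.get_dummies(pd.Series(cluster[m]).astype(str)).to_numpy(float)
        Xw = np.column_stack([D, lp[m]])
        ww = sm.GLM(y[m], Xw, family=sm.families.Binomial()).fit(maxiter=200)
        slope_w = float(ww.params[-1])
        slope_w_se = float(ww.bse[-1])
        # size-weighted mean of per-cluster offset intercepts
        tot = 0.0
        wsum = 0.0
        for c in valid:
            mm = cluster == c
            f = sm.GLM(
                y[mm], np.ones(mm.sum()), family=sm.families.Binomial(), offset=lp[mm]
            ).fit()
            tot += mm.sum() * float(f.params[0])
            wsum += mm.sum()
        citl_w = tot / wsum
        c_w, _ = weighted_within_concordance(y[m], p[m], cluster[m])
    else:
        logger.warning("no cluster with both outcome classes; within-level missing")

    return MultilevelValidationReport(
        n=n,
        n_clusters=len(labels),
        slope=float(weak.params[1]),
        slope_se=float(weak.bse[1]),
        citl=float(citl.params[0]),
        c=c_pop,
        slope_within=slope_w,
        slope_within_se=slope_w_se,
        citl_within=citl_w,
        c_within=c_w,
        excluded_clusters=excluded,
    )
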