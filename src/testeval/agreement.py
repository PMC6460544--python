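"""Variance-component analysis of repeated measurements and agreement.

Repeated quantitative measurements (per subject, possibly crossed with
rater, scanner, occasion, ...) are decomposed into variance components by a
restricted-likelihood mixed model.  The within-condition standard deviation
sigma_w -- the square root of the sum of the components that vary between
two measurements taken under "identical conditions" plus the residual --
yields the repeatability coefficient

    RC = 1.96 * sqrt(2) * sigma_w  (~ 2.77 * sigma_w),

the limit within which 95% of differences between two repeated measurements
are expected to lie.  RC equals the half-width of the Bland-Altman limits of
agreement when the bias is zero, which ties the two approaches together.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

__all__ = [
    "VCAResult",
    "BlandAltmanResult",
    "variance_components",
    "repeatability_coefficient",
    "bland_altman",
    "RC_MULTIPLIER",
]

RC_MULTIPLIER = 1.96 * math.sqrt(2.0)  # conventionally rounded to 2.77


@dataclass
class VCAResult:
    """Variance component per random factor plus residual.

    Negative method-of-moments estimates are truncated to zero and flagged in
    ``truncated``.  ``sigma_w(within=...)`` sums the components the caller
    declares as varying within-condition (plus the residual) and ``rc``
    multiplies by 1.96*sqrt(2).
    """

    components: dict[str, float]
    residual: float
    method: str
    truncated: list[str] = field(default_factory=list)
    n_obs: int = 0

    @property
    def total(self) -> float:
        return self.residual + sum(self.components.values())

    def sigma_w(self, within: Sequence[str] = ()) -> float:
        bad = [f for f in within if f not in self.components]
        if bad:
            raise KeyError(f"unknown variance component(s): {bad}")
        return math.sqrt(self.residual + sum(self.components[f] for f in within))

    def rc(self, within: Sequence[str] = ()) -> float:
        return repeatability_coefficient(self.sigma_w(within))


def repeatability_coefficient(sigma_w: float) -> float:
    """RC = 1.96 * sqrt(2) * sigma_w (the rounded convention is 2.77 * sigma_w)."""
    if sigma_w < 0:
        raise ValueError("sigma_w must be non-negative")
    return RC_MULTIPLIER * sigma_w


def _anova_oneway(df: pd.DataFrame, subject: str, value: str) -> tuple[float, float, bool]:
    """Balanced one-way expected-mean-squares estimates (subject random)."""
    groups = df.groupby(subject)[value]
    counts = groups.size()
    if counts.nunique() != 1:
        raise ValueError("ANOVA method requires a balanced one-way layout")
    k = int(counts.iloc[0])
    if k < 2:
        raise ValueError("each subject needs >= 2 replicates")
    n_sub = len(counts)
    grand = df[value].mean()
    msb = k * ((groups.mean() - grand) ** 2).sum() / (n_sub - 1)
    msw = groups.apply(lambda s: ((s - s.mean()) ** 2).sum()).sum() / (
        n_sub * (k - 1)
    )
    between = (msb - msw) / k
    truncated = between < 0
    return max(between, 0.0), msw, truncated


def variance_components(
    data: pd.DataFrame,
    subject: str = "subject",
    value: str = "value",
    random: Sequence[str] = (),
    fixed: Sequence[str] = (),
    method: str = "reml",
) -> VCAResult:
    """Decompose the variance of repeated measurements.

    Random factors (always including ``subject``) get a variance component
    each; ``fixed`` factors enter the mean model as categorical effects.
    ``method='reml'`` fits a variance-components mixed model; ``'anova'``
    uses the balanced one-way expected-mean-squares algebra (subject random,
    no other factors) and matches REML exactly on balanced data.
    """
    for f in (subject, value, *random, *fixed):
        if f not in data.columns:
            raise KeyError(f"column {f!r} not in data")
    if method == "anova":
        if random or fixed:
            raise ValueError("ANOVA method supports the one-way subject-only layout")
        between, resid, trunc = _anova_oneway(data, subject, value)
        return VCAResult(
            {subject: between},
            resid,
            "anova",
            [subject] if trunc else [],
            len(data),
        )
    if method != "reml":
        raise ValueError("method must be 'reml' or 'anova'")

    X_cols = [np.ones(len(data))]
    for f in fixed:
        X_cols.append(
            pd.get_dummies(data[f].astype(str), drop_first=True).to_numpy(float)
        )
    X = np.column_stack(X_cols)
    factors = [subject, *random]
    Z_list = [
        pd.get_dummies(data[f].astype(str)).to_numpy(float) for f in factors
    ]
    comps_arr, resid = _reml_variance_components(
        data[value].to_numpy(float), X, Z_list
    )
    comps = {name: float(v) for name, v in zip(factors, comps_arr)}
    return VCAResult(comps, float(resid), "reml", [], len(data))


def _reml_variance_components(y, X, Z_list):
    """Profiled REML for y = Xb + sum_f Z_f u_f + e, u_f ~ N(0, s_f^2 I).

    The residual variance and fixed effects are profiled out; the variance
    ratios gamma_f = s_f^2 / sigma_e^2 are optimised on the log scale and
    polished with a derivative-free pass so balanced-design estimates agree
    with the expected-mean-squares algebra to high precision.
    """
    n, p = X.shape
    ZZ = [Z @ Z.T for Z in Z_list]

    def neg_rll(log_gamma):
        gam = np.exp(log_gamma)
        V = np.eye(n)
        for g, M in zip(gam, ZZ):
            V = V + g * M
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf
        logdetV = 2 * np.sum(np.log(np.diag(L)))
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        XtViX = X.T @ Vi_X
        sign, logdetX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        r = y - X @ beta
        quad = float(r @ np.linalg.solve(V, r))
        if quad <= 0:
            return np.inf
        s2 = quad / (n - p)
        return 0.5 * (logdetV + logdetX + (n - p) * (1.0 + math.log(s2)))

    x0 = np.zeros(len(Z_list))
    res = optimize.minimize(
        neg_rll,
        x0,
        method="L-BFGS-B",
        bounds=[(-30.0, 10.0)] * len(Z_list),
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
    )
    res2 = optimize.minimize(
        neg_rll,
        res.x,
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 400},
    )
    best = res2 if res2.fun <= res.fun else res
    if not (res.success or res2.success):
        logger.warning("variance-components REML did not report convergence")
    gam = np.exp(best.x)
    V = np.eye(n)
    for g, M in zip(gam, ZZ):
        V = V + g * M
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
    r = y - X @ beta
    s2 = float(r @ np.linalg.solve(V, r)) / (n - p)
    return gam * s2, s2


@dataclass
class BlandAltmanResult:
    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    n: int

    @property
    def half_width(self) -> float:
        return 1.96 * self.sd


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland-Altman agreement of paired measurements.

    bias = mean(y - x); limits of agreement = bias +/- 1.96 * SD(y - x).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-d arrays with >= 2 pairs")
    d = y - x
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(bias, sd, bias - 1.96 * sd, bias + 1.96 * sd, x.size)
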