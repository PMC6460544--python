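"""Threshold-specific diagnostic accuracy data and bivariate random-effects meta-analysis.

A diagnostic accuracy study dichotomising a continuous marker at threshold
``c`` yields a 2x2 table (tp, fp, fn, tn).  Across studies, study-level
(logit Se, logit Sp) pairs are modelled jointly::

    (logit Se_i, logit Sp_i) ~ N(mu, Sigma + S_i)

with ``Sigma`` the between-study covariance and ``S_i`` the within-study
sampling covariance, approximated as diagonal with variances
``1/tp + 1/fn`` and ``1/fp + 1/tn``.  This is the standard normal-normal
approximation to the bivariate logistic random-effects model; estimation is
by restricted (default) or full maximum likelihood with the between-study
covariance parameterised through its Cholesky factor so it stays positive
semidefinite.  The summary ROC line and bivariate meta-regression with
study-level covariates build on the same likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "AccuracyRecord",
    "ThresholdDataset",
    "BivariateFit",
    "SROCCurve",
    "MetaRegressionFit",
    "fit_bivariate",
    "sroc_from_bivariate",
    "meta_regression",
    "InsufficientDataError",
    "MonotonicityError",
    "ConvergenceError",
]


class InsufficientDataError(ValueError):
    """Too few studies (or cells) for the requested analysis."""


class MonotonicityError(ValueError):
    """Counts violate the monotonicity implied by the positivity convention."""


class ConvergenceError(RuntimeError):
    """An iterative fit failed to converge to an admissible solution."""


def _round_half_away(x: np.ndarray | float) -> np.ndarray | float:
    return np.floor(np.abs(x) + 0.5) * np.sign(x)


@dataclass(frozen=True)
class AccuracyRecord:
    """One study's 2x2 table at one threshold.

    ``threshold`` may be ``None`` for single-threshold data.  Both disease
    groups must be represented (tp+fn >= 1 and fp+tn >= 1).
    """

    study: str
    threshold: float | None
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.tp + self.fn < 1:
            raise ValueError(f"study {self.study}: no diseased subjects (tp+fn=0)")
        if self.fp + self.tn < 1:
            raise ValueError(f"study {self.study}: no non-diseased subjects (fp+tn=0)")

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_nondiseased(self) -> int:
        return self.fp + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_diseased

    @property
    def specificity(self) -> float:
        return self.tn / self.n_nondiseased

    def logits(self) -> tuple[float, float, float, float]:
        """(logit Se, logit Sp, var logit Se, var logit Sp).

        If any cell is zero, 0.5 is added to all four cells for the logit and
        variance computation only; the raw counts are never altered.
        """
        cc = 0.5 if 0 in (self.tp, self.fp, self.fn, self.tn) else 0.0
        tp, fp, fn, tn = (self.tp + cc, self.fp + cc, self.fn + cc, self.tn + cc)
        lse = np.log(tp / fn)
        lsp = np.log(tn / fp)
        return float(lse), float(lsp), 1.0 / tp + 1.0 / fn, 1.0 / fp + 1.0 / tn


@dataclass(frozen=True)
class ThresholdDataset:
    """A collection of :class:`AccuracyRecord` with a positivity convention.

    Under the default convention (positive iff marker >= threshold), within a
    study tp is non-increasing and tn non-decreasing in threshold; violations
    raise :class:`MonotonicityError` unless ``validate=False``.
    """

    records: tuple[AccuracyRecord, ...]
    positivity_high: bool = True
    validate: bool = True

    def __init__(
        self,
        records: Iterable[AccuracyRecord],
        positivity_high: bool = True,
        validate: bool = True,
    ) -> None:
        object.__setattr__(self, "records", tuple(records))
        object.__setattr__(self, "positivity_high", bool(positivity_high))
        object.__setattr__(self, "validate", bool(validate))
        if validate:
            self._check()

    def _check(self) -> None:
        for study, recs in self.by_study().items():
            with_thr = [r for r in recs if r.threshold is not None]
            thr = [r.threshold for r in with_thr]
            if len(set(thr)) != len(thr):
                raise ValueError(f"study {study}: duplicate thresholds {thr}")
            ordered = sorted(with_thr, key=lambda r: r.threshold)
            sgn = 1 if self.positivity_high else -1
            for lo, hi in zip(ordered, ordered[1:]):
                if lo.n_diseased != hi.n_diseased or lo.n_nondiseased != hi.n_nondiseased:
                    raise ValueError(
                        f"study {study}: group sizes differ across thresholds"
                    )
                if sgn * (hi.tp - lo.tp) > 0 or sgn * (hi.tn - lo.tn) < 0:
                    raise MonotonicityError(
                        f"study {study}: counts not monotone between thresholds "
                        f"{lo.threshold} and {hi.threshold}"
                    )

    def by_study(self) -> dict[str, list[AccuracyRecord]]:
        out: dict[str, list[AccuracyRecord]] = {}
        for r in self.records:
            out.setdefault(r.study, []).append(r)
        return out

    @property
    def studies(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.study)
        return list(seen)

    @property
    def thresholds(self) -> list[float]:
        return sorted({r.threshold for r in self.records if r.threshold is not None})

    def at_threshold(self, threshold: float, tol: float = 1e-9) -> list[AccuracyRecord]:
        return [
            r
            for r in self.records
            if r.threshold is not None and abs(r.threshold - threshold) <= tol
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "study": [r.study for r in self.records],
                "threshold": [r.threshold for r in self.records],
                "tp": [r.tp for r in self.records],
                "fp": [r.fp for r in self.records],
                "fn": [r.fn for r in self.records],
                "tn": [r.tn for r in self.records],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "ThresholdDataset":
        recs = []
        for row in df.itertuples(index=False):
            thr = getattr(row, "threshold", None)
            if thr is not None and (isinstance(thr, float) and np.isnan(thr)):
                thr = None
            recs.append(
                AccuracyRecord(
                    study=str(row.study),
                    threshold=None if thr is None else float(thr),
                    tp=int(row.tp),
                    fp=int(row.fp),
                    fn=int(row.fn),
                    tn=int(row.tn),
                )
            )
        return cls(recs, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ThresholdDataset":
        """Read ``study,threshold,tp,fp,fn,tn`` CSV (blank threshold allowed)."""
        return cls.from_frame(pd.read_csv(path), **kwargs)


# ---------------------------------------------------------------------------
# Bivariate random-effects likelihood
# ---------------------------------------------------------------------------


@dataclass
class BivariateFit:
    """Pooled (logit Se, logit Sp) with between-study covariance.

    ``mu`` is the pooled mean on the logit scale, ``Sigma`` the between-study
    covariance, ``cov_mu`` the sampling covariance of ``mu``.
    """

    mu: np.ndarray
    Sigma: np.ndarray
    cov_mu: np.ndarray
    loglik: float
    n_studies: int
    converged: bool
    method: str = "reml"

    @property
    def se(self) -> float:
        return float(expit(self.mu[0]))

    @property
    def sp(self) -> float:
        return float(expit(self.mu[1]))

    @property
    def tau2_se(self) -> float:
        return float(self.Sigma[0, 0])

    @property
    def tau2_sp(self) -> float:
        return float(self.Sigma[1, 1])

    @property
    def rho(self) -> float:
        d = np.sqrt(self.Sigma[0, 0] * self.Sigma[1, 1])
        return float(self.Sigma[0, 1] / d) if d > 0 else 0.0

    def ci(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        """Wald intervals on the logit scale, back-transformed."""
        z = norm.ppf(0.5 + level / 2)
        out = {}
        for i, name in enumerate(("se", "sp")):
            s = np.sqrt(self.cov_mu[i, i])
            out[name] = (
                float(expit(self.mu[i] - z * s)),
                float(expit(self.mu[i] + z * s)),
            )
        return out

    def to_dict(self) -> dict:
        return {
            "mu": self.mu.tolist(),
            "Sigma": self.Sigma.tolist(),
            "cov_mu": self.cov_mu.tolist(),
            "loglik": self.loglik,
            "n_studies": self.n_studies,
            "converged": self.converged,
            "method": self.method,
            "se": self.se,
            "sp": self.sp,
            "tau2_se": self.tau2_se,
            "tau2_sp": self.tau2_sp,
            "rho": self.rho,
        }


def _records_from(data, threshold=None) -> list[AccuracyRecord]:
    if isinstance(data, ThresholdDataset):
        if threshold is not None:
            recs = data.at_threshold(threshold)
        else:
            recs = list(data.records)
    else:
        recs = list(data)
        if threshold is not None:
            recs = [
                r
                for r in recs
                if r.threshold is not None and abs(r.threshold - threshold) <= 1e-9
            ]
    return recs


def _study_logits(recs: Sequence[AccuracyRecord]) -> tuple[np.ndarray, np.ndarray]:
    vals = np.array([r.logits() for r in recs], dtype=float)
    return vals[:, :2], vals[:, 2:]


def _chol_to_sigma(theta: np.ndarray) -> np.ndarray:
    a, b, c = theta
    l11, l22 = np.exp(a), np.exp(c)
    return np.array([[l11 * l11, l11 * b], [l11 * b, b * b + l22 * l22]])


def _nll_profiled(theta, Y, S, X_list, reml):
    """Negative profiled (restricted) log-likelihood over theta = chol(Sigma).

    The fixed effects are profiled out by GLS at each theta.  ``X_list`` is a
    list of per-study 2 x p design matrices (p = 2 for intercept-only).
    Returns (nll, beta, cov_beta).
    """
    Sigma = _chol_to_sigma(np.asarray(theta, dtype=float))
    K = Y.shape[0]
    V00 = Sigma[0, 0] + S[:, 0]
    V11 = Sigma[1, 1] + S[:, 1]
    V01 = np.full(K, Sigma[0, 1])
    det = V00 * V11 - V01**2
    if np.any(det <= 1e-300):
        return np.inf, None, None
    i00 = V11 / det
    i11 = V00 / det
    i01 = -V01 / det

    p = X_list[0].shape[1]
    if X_list is _INTERCEPT_ONLY or (p == 2 and X_list[0] is _EYE2):
        A = np.array(
            [[np.sum(i00), np.sum(i01)], [np.sum(i01), np.sum(i11)]]
        )
        bvec = np.array(
            [
                np.sum(i00 * Y[:, 0] + i01 * Y[:, 1]),
                np.sum(i01 * Y[:, 0] + i11 * Y[:, 1]),
            ]
        )
        try:
            cov_beta = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        beta = cov_beta @ bvec
        r0 = Y[:, 0] - beta[0]
        r1 = Y[:, 1] - beta[1]
        quad = float(np.sum(i00 * r0**2 + 2 * i01 * r0 * r1 + i11 * r1**2))
    else:
        A = np.zeros((p, p))
        bvec = np.zeros(p)
        for k in range(K):
            Vi = np.array([[i00[k], i01[k]], [i01[k], i11[k]]])
            Xk = X_list[k]
            A += Xk.T @ Vi @ Xk
            bvec += Xk.T @ Vi @ Y[k]
        try:
            cov_beta = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        beta = cov_beta @ bvec

        quad = 0.0
        for k in range(K):
            r = Y[k] - X_list[k] @ beta
            quad += (
                i00[k] * r[0] ** 2 + 2 * i01[k] * r[0] * r[1] + i11[k] * r[1] ** 2
            )
    nll = 0.5 * (np.sum(np.log(det)) + quad) + K * np.log(2 * np.pi)
    if reml:
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf, None, None
        nll += 0.5 * logdetA - 0.5 * p * np.log(2 * np.pi)
    return nll, beta, cov_beta


def _mom_start(Y, S):
    """Method-of-moments (DerSimonian-Laird per margin, rho=0) start."""
    taus = []
    for j in range(2):
        w = 1.0 / S[:, j]
        ybar = np.sum(w * Y[:, j]) / np.sum(w)
        q = np.sum(w * (Y[:, j] - ybar) ** 2)
        df = len(Y) - 1
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max((q - df) / c, 1e-6) if c > 0 else 1e-6
        taus.append(tau2)
    return np.array([0.5 * np.log(taus[0]), 0.0, 0.5 * np.log(taus[1])])


_EYE2 = np.eye(2)
_INTERCEPT_ONLY = object()

try:  # fast path for the intercept-only likelihood (hot loop in simulations)
    from numba import njit

    @njit(cache=False, fastmath=False)
    def _nll_intercept_kernel(a, b, c, y0, y1, s0, s1, reml):  # pragma: no cover
        l11 = np.exp(a)
        l22 = np.exp(c)
        sig00 = l11 * l11
        sig01 = l11 * b
        sig11 = b * b + l22 * l22
        K = y0.shape[0]
        sum_logdet = 0.0
        a00 = 0.0
        a01 = 0.0
        a11 = 0.0
        b0 = 0.0
        b1 = 0.0
        for k in range(K):
            v00 = sig00 + s0[k]
            v11 = sig11 + s1[k]
            det = v00 * v11 - sig01 * sig01
            if det <= 1e-300:
                return 1e308
            sum_logdet += np.log(det)
            i00 = v11 / det
            i11 = v00 / det
            i01 = -sig01 / det
            a00 += i00
            a01 += i01
            a11 += i11
            b0 += i00 * y0[k] + i01 * y1[k]
            b1 += i01 * y0[k] + i11 * y1[k]
        detA = a00 * a11 - a01 * a01
        if detA <= 0.0:
            return 1e308
        mu0 = (a11 * b0 - a01 * b1) / detA
        mu1 = (-a01 * b0 + a00 * b1) / detA
        quad = 0.0
        for k in range(K):
            v00 = sig00 + s0[k]
            v11 = sig11 + s1[k]
            det = v00 * v11 - sig01 * sig01
            i00 = v11 / det
            i11 = v00 / det
            i01 = -sig01 / det
            r0 = y0[k] - mu0
            r1 = y1[k] - mu1
            quad += i00 * r0 * r0 + 2.0 * i01 * r0 * r1 + i11 * r1 * r1
        nll = 0.5 * (sum_logdet + quad) + K * np.log(2.0 * np.pi)
        if reml:
            nll += 0.5 * np.log(detA) - np.log(2.0 * np.pi)
        return nll

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

_THETA_BOUNDS = [(-8.0, 3.0), (-20.0, 20.0), (-8.0, 3.0)]


def _fit_mvmeta(Y, S, X_list, method="reml"):
    reml = method == "reml"
    if _HAVE_NUMBA and X_list[0] is _EYE2:
        y0 = np.ascontiguousarray(Y[:, 0])
        y1 = np.ascontiguousarray(Y[:, 1])
        s0 = np.ascontiguousarray(S[:, 0])
        s1 = np.ascontiguousarray(S[:, 1])

        def objective(th):
            return _nll_intercept_kernel(th[0], th[1], th[2], y0, y1, s0, s1, reml)

    else:

        def objective(th):
            return _nll_profiled(th, Y, S, X_list, reml)[0]

    starts = [
        _mom_start(Y, S),
        np.array([-8.0, 0.0, -8.0]),
        np.array([0.0, 0.0, 0.0]),
    ]
    best = None
    any_ok = False
    for x0 in starts:
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=_THETA_BOUNDS,
            options={"maxiter": 200},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-10):
            best = res
        any_ok = any_ok or (res.success and np.isfinite(res.fun))
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("bivariate likelihood could not be evaluated")
    nll, beta, cov_beta = _nll_profiled(best.x, Y, S, X_list, reml)
    Sigma = _chol_to_sigma(best.x)
    if not any_ok:
        logger.warning(
            "bivariate fit did not converge from any start; boundary estimates returned"
        )
    else:
        logger.info(
            "bivariate %s fit converged: loglik=%.4f tau2=(%.4g, %.4g)",
            method,
            -nll,
            Sigma[0, 0],
            Sigma[1, 1],
        )
    return beta, Sigma, cov_beta, -nll, any_ok


def fit_bivariate(
    data,
    threshold: float | None = None,
    method: str = "reml",
) -> BivariateFit:
    """Bivariate random-effects meta-analysis of (logit Se, logit Sp).

    Parameters
    ----------
    data : ThresholdDataset or iterable of AccuracyRecord
        One record per study (use ``threshold=`` to select a slice of a
        multi-threshold dataset).
    method : {"reml", "ml", "fe"}
        Restricted likelihood (default), full likelihood, or fixed-effect
        (between-study covariance constrained to zero; closed form).
    """
    recs = _records_from(data, threshold)
    if len(recs) < 2:
        raise InsufficientDataError(
            f"bivariate meta-analysis needs >= 2 studies, got {len(recs)}"
        )
    studies = [r.study for r in recs]
    if len(set(studies)) != len(studies):
        raise ValueError("more than one record per study at this threshold")
    Y, S = _study_logits(recs)
    K = len(recs)
    if method == "fe":
        mu = np.zeros(2)
        cov = np.zeros((2, 2))
        for j in range(2):
            w = 1.0 / S[:, j]
            mu[j] = np.sum(w * Y[:, j]) / np.sum(w)
            cov[j, j] = 1.0 / np.sum(w)
        ll = float(
            -0.5 * np.sum(np.log(2 * np.pi * S))
            - 0.5 * np.sum((Y - mu) ** 2 / S)
        )
        return BivariateFit(mu, np.zeros((2, 2)), cov, ll, K, True, "fe")
    if method not in ("reml", "ml"):
        raise ValueError(f"unknown method {method!r}")
    X_list = [_EYE2] * K
    mu, Sigma, cov_mu, ll, ok = _fit_mvmeta(Y, S, X_list, method)
    return BivariateFit(mu, Sigma, cov_mu, ll, K, ok, method)


# ---------------------------------------------------------------------------
# SROC
# ---------------------------------------------------------------------------


@dataclass
class SROCCurve:
    """Summary ROC line in (logit FPR, logit Se) space plus sampled points."""

    intercept: float
    slope: float
    fpr: np.ndarray
    se: np.ndarray
    degenerate: bool = False

    def evaluate(self, fpr) -> np.ndarray:
        fpr = np.asarray(fpr, dtype=float)
        return expit(self.intercept + self.slope * logit(fpr))


def sroc_from_bivariate(fit: BivariateFit, fpr_grid=None) -> SROCCurve:
    """Summary ROC curve implied by the bivariate fit.

    The curve is the regression of logit Se on logit FPR implied by the
    between-study distribution: with logit FPR = -logit Sp, the slope is
    ``-cov(logit Se, logit Sp) / tau2_sp`` and the line passes through the
    summary point.  When ``tau2_sp`` is (numerically) zero the slope is
    undefined; a constant logit-Se line is returned with a warning.
    """
    if fpr_grid is None:
        fpr_grid = np.linspace(0.01, 0.99, 99)
    fpr = np.asarray(fpr_grid, dtype=float)
    if np.any((fpr <= 0) | (fpr >= 1)):
        raise ValueError("FPR grid must lie strictly inside (0, 1)")
    tau2_sp = fit.Sigma[1, 1]
    if tau2_sp <= 1e-10:
        logger.warning("tau2_sp ~ 0: SROC slope degenerate, returning constant line")
        slope, degenerate = 0.0, True
    else:
        slope = float(-fit.Sigma[0, 1] / tau2_sp)
        degenerate = False
    intercept = float(fit.mu[0] + slope * fit.mu[1])
    se = expit(intercept + slope * logit(fpr))
    return SROCCurve(intercept, slope, fpr, se, degenerate)


# ---------------------------------------------------------------------------
# Meta-regression
# ---------------------------------------------------------------------------


@dataclass
class MetaRegressionFit:
    """Bivariate meta-regression: covariate effects on both logit means."""

    coef: pd.Series
    cov: pd.DataFrame
    wald: pd.DataFrame
    Sigma: np.ndarray
    loglik: float
    n_studies: int
    converged: bool
    method: str
    terms: list[str]
    multiplicity_note: str = (
        "Wald p-values are unadjusted for multiplicity."
    )


def _build_design(
    covariates: pd.DataFrame,
    terms: Sequence[str] | None,
    interactions: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    cols: dict[str, list[str]] = {}
    pieces = [pd.Series(1.0, index=covariates.index, name="(intercept)")]
    use = list(terms) if terms is not None else list(covariates.columns)
    for t in use:
        s = covariates[t]
        if s.dtype == object or str(s.dtype) == "category" or s.dtype == bool:
            d = pd.get_dummies(s, prefix=t, drop_first=True).astype(float)
            cols[t] = list(d.columns)
            pieces.append(d)
        else:
            cols[t] = [t]
            pieces.append(s.astype(float))
    D = pd.concat(pieces, axis=1)
    for a, b in interactions:
        for ca in cols[a]:
            for cb in cols[b]:
                D[f"{ca}:{cb}"] = D[ca] * D[cb]
    return D


def meta_regression(
    data,
    covariates: pd.DataFrame,
    terms: Sequence[str] | None = None,
    interactions: Sequence[tuple[str, str]] = (),
    threshold: float | None = None,
    method: str = "reml",
) -> MetaRegressionFit:
    """Bivariate random-effects meta-regression with study-level covariates.

    ``covariates`` is indexed by study id (or has a ``study`` column); the
    same design (with intercept) acts on both logit-Se and logit-Sp means.
    ``interactions`` lists pairs of term names whose products are added,
    e.g. ``[("assay", "direct")]`` for an assay-by-directness interaction.
    Wald statistics per coefficient are reported without multiplicity
    adjustment (flagged in the output).
    """
    recs = _records_from(data, threshold)
    if len(recs) < 2:
        raise InsufficientDataError("meta-regression needs >= 2 studies")
    cov = covariates.set_index("study") if "study" in covariates.columns else covariates
    cov = cov.loc[[r.study for r in recs]]
    D = _build_design(cov, terms, interactions)
    X = D.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns via pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(X, pivoting=True)
        bad = [D.columns[piv[i]] for i in range(rank, X.shape[1])]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    Y, S = _study_logits(recs)
    p = X.shape[1]
    X_list = []
    for k in range(len(recs)):
        Xk = np.zeros((2, 2 * p))
        Xk[0, :p] = X[k]
        Xk[1, p:] = X[k]
        X_list.append(Xk)
    beta, Sigma, cov_beta, ll, ok = _fit_mvmeta(Y, S, X_list, method)
    names = [f"logit_se:{c}" for c in D.columns] + [f"logit_sp:{c}" for c in D.columns]
    coef = pd.Series(beta, index=names)
    cov_df = pd.DataFrame(cov_beta, index=names, columns=names)
    se_ = np.sqrt(np.diag(cov_beta))
    z = beta / se_
    wald = pd.DataFrame(
        {"coef": beta, "se": se_, "z": z, "p": 2 * norm.sf(np.abs(z))}, index=names
    )
    return MetaRegressionFit(
        coef, cov_df, wald, Sigma, ll, len(recs), ok, method, list(D.columns)
    )
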