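"""Missing-threshold handling and multi-threshold meta-analysis.

Primary studies of a continuous marker report 2x2 tables at differing
threshold sets, so a per-threshold meta-analysis faces missing data.  Three
strategies are provided:

* **NI** (no imputation): meta-analyse whatever is observed at each threshold.
* **SI** (single imputation): piecewise-linear interpolation of logit Se and
  logit Sp in threshold between two observed bounding thresholds.
* **MIDC** (multiple imputation using discrete combinations): for each missing
  threshold, draw a complete 2x2 table uniformly from the set of integer
  (tp, fp) pairs lying between the tables at the two bounding thresholds,
  repeat M times, meta-analyse each completed dataset, and combine with
  Rubin's rules.

Separately, a distribution-function model pools all thresholds at once: the
cumulative proportions below each threshold in the non-diseased and diseased
groups are quantile-transformed (probit or logit) and fitted with a weighted
linear mixed model in threshold, giving group location/scale parameters, a
smooth Se(c)/Sp(c) pair, and a Youden-optimal threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from scipy.stats import norm, t as t_dist

from .dta_core import (
    AccuracyRecord,
    BivariateFit,
    ConvergenceError,
    InsufficientDataError,
    MonotonicityError,
    ThresholdDataset,
    fit_bivariate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BoundingPair",
    "RubinPooled",
    "MultiThresholdFit",
    "YoudenResult",
    "ExtrapolationError",
    "si_interpolate",
    "si_complete",
    "enumerate_combinations",
    "rubin_combine",
    "midc_meta",
    "ni_meta",
    "fit_multithreshold",
    "youden_optimal",
]


class ExtrapolationError(ValueError):
    """Target threshold lies outside the bounding interval."""


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass(frozen=True)
class BoundingPair:
    """Two observed thresholds of one study bracketing missing targets."""

    lower: AccuracyRecord
    upper: AccuracyRecord
    target_thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        lo, hi = self.lower, self.upper
        if lo.study != hi.study:
            raise ValueError("bounding records must come from the same study")
        if lo.threshold is None or hi.threshold is None or not lo.threshold < hi.threshold:
            raise ValueError("lower.threshold must be < upper.threshold")
        if lo.n_diseased != hi.n_diseased or lo.n_nondiseased != hi.n_nondiseased:
            raise ValueError("group sizes differ between bounding records")
        if hi.tp > lo.tp or hi.tn < lo.tn:
            raise MonotonicityError(
                f"study {lo.study}: bounding counts not monotone "
                f"({lo.threshold} -> {hi.threshold})"
            )
        for c in self.target_thresholds:
            if not (lo.threshold <= c <= hi.threshold):
                raise ExtrapolationError(
                    f"target {c} outside bounding interval "
                    f"[{lo.threshold}, {hi.threshold}]"
                )


def si_interpolate(pair: BoundingPair) -> list[AccuracyRecord]:
    """Single imputation by linear interpolation on the logit scale.

    logit Se and logit Sp are interpolated linearly in threshold between the
    bounds, back-converted to counts against the study's group sizes by
    rounding half away from zero, and clipped to the bounding counts so the
    completed study stays monotone.  A target equal to an observed bound
    returns that bound's counts unchanged.
    """
    lo, hi = pair.lower, pair.upper
    lse_lo, lsp_lo, _, _ = lo.logits()
    lse_hi, lsp_hi, _, _ = hi.logits()
    n1, n0 = lo.n_diseased, lo.n_nondiseased
    out = []
    for c in pair.target_thresholds:
        if c == lo.threshold:
            out.append(AccuracyRecord(lo.study, c, lo.tp, lo.fp, lo.fn, lo.tn))
            continue
        if c == hi.threshold:
            out.append(AccuracyRecord(hi.study, c, hi.tp, hi.fp, hi.fn, hi.tn))
            continue
        f = (c - lo.threshold) / (hi.threshold - lo.threshold)
        se = expit((1 - f) * lse_lo + f * lse_hi)
        sp = expit((1 - f) * lsp_lo + f * lsp_hi)
        tp = int(np.clip(_round_half_away(se * n1), hi.tp, lo.tp))
        tn = int(np.clip(_round_half_away(sp * n0), lo.tn, hi.tn))
        out.append(AccuracyRecord(lo.study, c, tp, n0 - tn, n1 - tp, tn))
    return out


def enumerate_combinations(pair: BoundingPair, target: float | None = None) -> list[tuple[int, int]]:
    """All integer (tp, fp) tables lying between the bounding tables.

    The count is ``(|tp_lo - tp_hi| + 1) * (|fp_lo - fp_hi| + 1)``; fn and tn
    are implied by the group sizes.
    """
    lo, hi = pair.lower, pair.upper
    tps = range(min(lo.tp, hi.tp), max(lo.tp, hi.tp) + 1)
    fps = range(min(lo.fp, hi.fp), max(lo.fp, hi.fp) + 1)
    return [(tp, fp) for tp in tps for fp in fps]


@dataclass(frozen=True)
class RubinPooled:
    """Rubin's-rules combination of M estimates.

    total = within + (1 + 1/M) * between;
    df = (M-1) * (1 + within / ((1+1/M) * between))^2, +inf when between = 0.
    """

    estimate: float
    within: float
    between: float
    total: float
    df: float
    m: int


def rubin_combine(estimates: Sequence[float], variances: Sequence[float]) -> RubinPooled:
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.shape != var.shape or est.ndim != 1:
        raise ValueError("estimates and variances must be equal-length 1-d sequences")
    m = len(est)
    if m < 2:
        raise ValueError("Rubin's rules need M >= 2 imputations")
    if np.any(var < 0):
        raise ValueError("variances must be non-negative")
    qbar = float(np.mean(est))
    w = float(np.mean(var))
    b = float(np.var(est, ddof=1))
    t = w + (1 + 1 / m) * b
    if b == 0:
        df = math.inf
    else:
        df = (m - 1) * (1 + w / ((1 + 1 / m) * b)) ** 2
    return RubinPooled(qbar, w, b, t, df, m)


# ---------------------------------------------------------------------------
# MIDC
# ---------------------------------------------------------------------------


def _observed_map(recs: list[AccuracyRecord]) -> dict[float, AccuracyRecord]:
    return {r.threshold: r for r in recs if r.threshold is not None}


def _complete_study_midc(
    recs: list[AccuracyRecord],
    targets: Sequence[float],
    rng: np.random.Generator,
) -> list[AccuracyRecord]:
    """One MIDC completion of one study.

    Missing targets are imputed in increasing threshold order, each drawn
    uniformly from the discrete combinations between the current lower bound
    (the previous draw, once made) and the next observed threshold above, so
    the completed study is monotone by construction.  Unbracketed targets are
    skipped.
    """
    obs = _observed_map(recs)
    obs_thr = sorted(obs)
    out = list(recs)
    study = recs[0].study
    missing = [c for c in sorted(targets) if c not in obs]
    for c in missing:
        below = [t for t in obs_thr if t < c]
        above = [t for t in obs_thr if t > c]
        if not below or not above:
            logger.info(
                "study %s: target %s not bracketed by observed thresholds; skipped",
                study,
                c,
            )
            continue
        lo_rec = obs[below[-1]]
        hi_rec = obs[above[0]]
        pair = BoundingPair(lo_rec, hi_rec, (c,))
        combos = enumerate_combinations(pair)
        tp, fp = combos[rng.integers(len(combos))]
        rec = AccuracyRecord(
            study, c, tp, fp, lo_rec.n_diseased - tp, lo_rec.n_nondiseased - fp
        )
        out.append(rec)
        obs[c] = rec  # previous draw replaces the lower bound
        obs_thr = sorted(obs)
    return out


def si_complete(data: ThresholdDataset, targets: Sequence[float]) -> ThresholdDataset:
    """Complete a dataset by single (logit-linear) imputation at ``targets``."""
    out: list[AccuracyRecord] = []
    for study, recs in data.by_study().items():
        obs = _observed_map(recs)
        obs_thr = sorted(obs)
        new = list(recs)
        for c in sorted(targets):
            if c in obs:
                continue
            below = [t for t in obs_thr if t < c]
            above = [t for t in obs_thr if t > c]
            if not below or not above:
                continue
            pair = BoundingPair(obs[below[-1]], obs[above[0]], (c,))
            new.extend(si_interpolate(pair))
        out.extend(new)
    return ThresholdDataset(out, positivity_high=data.positivity_high)


@dataclass
class MidcResult:
    """Per-threshold Rubin-pooled summaries plus the completed datasets."""

    summary: pd.DataFrame
    pooled: dict[float, dict[str, RubinPooled]]
    completed: list[ThresholdDataset]
    m: int
    level: float
    notes: dict = field(default_factory=dict)


def _summary_row(threshold, pooled_se, pooled_sp, level):
    row = {"threshold": threshold}
    for name, p in (("se", pooled_se), ("sp", pooled_sp)):
        q = norm.ppf(0.5 + level / 2) if not np.isfinite(p.df) else t_dist.ppf(
            0.5 + level / 2, p.df
        )
        half = q * math.sqrt(p.total)
        row[name] = expit(p.estimate)
        row[f"{name}_lo"] = expit(p.estimate - half)
        row[f"{name}_hi"] = expit(p.estimate + half)
        row[f"logit_{name}"] = p.estimate
        row[f"logit_{name}_var"] = p.total
        row[f"{name}_df"] = p.df
    return row


def midc_meta(
    data: ThresholdDataset,
    target_thresholds: Sequence[float],
    m: int = 10,
    rng: np.random.Generator | None = None,
    method: str = "reml",
    level: float = 0.95,
) -> MidcResult:
    """Multiple imputation of missing thresholds using discrete combinations.

    For each of ``m`` imputations every study is completed independently at
    the bracketed missing targets, a bivariate meta-analysis is run at each
    target threshold, and the M logit-scale estimates are combined with
    Rubin's rules (back-transformed point and t-interval).  With no missing
    thresholds every imputation is identical, the between-imputation variance
    is zero, and the output equals the per-threshold (NI) meta-analysis.
    """
    if m < 2:
        raise ValueError("MIDC needs M >= 2 imputations")
    rng = np.random.default_rng() if rng is None else rng
    targets = sorted(target_thresholds)
    by_study = data.by_study()
    completed: list[ThresholdDataset] = []
    fits: dict[float, list[BivariateFit]] = {c: [] for c in targets}
    for _ in range(m):
        recs: list[AccuracyRecord] = []
        for study_recs in by_study.values():
            recs.extend(_complete_study_midc(study_recs, targets, rng))
        ds = ThresholdDataset(recs, positivity_high=data.positivity_high)
        completed.append(ds)
        for c in targets:
            at_c = ds.at_threshold(c)
            if len(at_c) >= 2:
                fits[c].append(fit_bivariate(at_c, method=method))
    pooled: dict[float, dict[str, RubinPooled]] = {}
    rows = []
    for c in targets:
        if not fits[c]:
            logger.warning("threshold %s: no imputation produced >= 2 studies", c)
            continue
        mus = np.array([f.mu for f in fits[c]])
        vars_ = np.array([np.diag(f.cov_mu) for f in fits[c]])
        pse = rubin_combine(mus[:, 0], vars_[:, 0])
        psp = rubin_combine(mus[:, 1], vars_[:, 1])
        pooled[c] = {"se": pse, "sp": psp}
        rows.append(_summary_row(c, pse, psp, level))
    summary = pd.DataFrame(rows)
    notes = {
        "sampling": "uniform over the discrete-combination rectangle, tp and fp independent",
        "unbracketed": "studies whose missing threshold is not bracketed contribute no imputation there",
    }
    return MidcResult(summary, pooled, completed, m, level, notes)


def ni_meta(
    data: ThresholdDataset,
    target_thresholds: Sequence[float] | None = None,
    method: str = "reml",
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-threshold bivariate meta-analysis of observed records only."""
    targets = (
        sorted(target_thresholds) if target_thresholds is not None else data.thresholds
    )
    z = norm.ppf(0.5 + level / 2)
    rows = []
    for c in targets:
        at_c = data.at_threshold(c)
        if len(at_c) < 2:
            continue
        f = fit_bivariate(at_c, method=method)
        row = {"threshold": c, "n_studies": f.n_studies}
        for i, name in enumerate(("se", "sp")):
            s = math.sqrt(f.cov_mu[i, i])
            row[name] = expit(f.mu[i])
            row[f"{name}_lo"] = expit(f.mu[i] - z * s)
            row[f"{name}_hi"] = expit(f.mu[i] + z * s)
            row[f"logit_{name}"] = f.mu[i]
            row[f"logit_{name}_var"] = f.cov_mu[i, i]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Distribution-function multi-threshold model
# ---------------------------------------------------------------------------


def _fit_weighted_ri_lmm(groups, x, z, w, reml=True):
    """Weighted random-intercept linear mixed model, V_i = tau2*J + s2*diag(1/w).

    Fixed part a + b*x profiled out by GLS; (log tau2, log s2) optimised by
    (restricted) likelihood using the Woodbury identity per group.
    Returns (a, b, tau2, s2, resid_ok).
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    X = np.column_stack([np.ones_like(x), x])
    per = [(X[groups == g], z[groups == g], w[groups == g]) for g in uniq]

    def nll(theta):
        tau2, s2 = np.exp(theta)
        A = np.zeros((2, 2))
        bv = np.zeros(2)
        logdet = 0.0
        parts = []
        for Xg, zg, wg in per:
            d = s2 / wg
            di = 1.0 / d
            denom = 1.0 + tau2 * di.sum()
            # V^-1 = diag(di) - tau2 * di di' / denom
            Xw = Xg * di[:, None]
            zw = zg * di
            A_g = Xg.T @ Xw - tau2 * np.outer(Xw.sum(0), Xw.sum(0)) / denom
            b_g = Xg.T @ zw - tau2 * Xw.sum(0) * zw.sum() / denom
            A += A_g
            bv += b_g
            logdet += np.sum(np.log(d)) + np.log(denom)
            parts.append((Xg, zg, di, denom))
        try:
            beta = np.linalg.solve(A, bv)
        except np.linalg.LinAlgError:
            return np.inf
        quad = 0.0
        for Xg, zg, di, denom in parts:
            r = zg - Xg @ beta
            rw = r * di
            quad += r @ rw - tau2 * rw.sum() ** 2 / denom
        out = 0.5 * (logdet + quad)
        if reml:
            sign, ld = np.linalg.slogdet(A)
            if sign <= 0:
                return np.inf
            out += 0.5 * ld
        return out

    best = None
    for x0 in ([-2.0, -2.0], [-6.0, 0.0], [0.0, -6.0]):
        res = optimize.minimize(
            nll, np.array(x0), method="L-BFGS-B", bounds=[(-30, 5), (-30, 5)]
        )
        if best is None or (np.isfinite(res.fun) and res.fun < best.fun):
            best = res
    tau2, s2 = np.exp(best.x)
    # recover beta at the optimum
    theta = best.x
    t2, ss2 = np.exp(theta)
    A = np.zeros((2, 2))
    bv = np.zeros(2)
    for Xg, zg, wg in per:
        d = ss2 / wg
        di = 1.0 / d
        denom = 1.0 + t2 * di.sum()
        Xw = Xg * di[:, None]
        zw = zg * di
        A += Xg.T @ Xw - t2 * np.outer(Xw.sum(0), Xw.sum(0)) / denom
        bv += Xg.T @ zw - t2 * Xw.sum(0) * zw.sum() / denom
    beta = np.linalg.solve(A, bv)
    return float(beta[0]), float(beta[1]), float(tau2), float(s2), bool(best.success)


@dataclass
class MultiThresholdFit:
    """Marker distribution parameters per disease group from all thresholds.

    The marker (optionally log-transformed) is modelled as location-scale
    within each group: P(X <= c) = F((c - mu_g) / sigma_g) with F the standard
    normal (probit link) or logistic (logit link) CDF.  ``Se(c)`` is
    non-increasing and ``Sp(c)`` non-decreasing in c by construction.
    """

    mu0: float
    sigma0: float
    mu1: float
    sigma1: float
    dist: str
    log_thresholds: bool
    tau2: dict
    resid_var: dict
    converged: bool

    def _F(self, z):
        return norm.cdf(z) if self.dist == "normal" else expit(z)

    def _x(self, c):
        c = np.asarray(c, dtype=float)
        if self.log_thresholds:
            if np.any(c <= 0):
                raise ValueError("thresholds must be positive on the log scale")
            return np.log(c)
        return c

    def specificity(self, c):
        return self._F((self._x(c) - self.mu0) / self.sigma0)

    def sensitivity(self, c):
        return 1.0 - self._F((self._x(c) - self.mu1) / self.sigma1)


def fit_multithreshold(
    data: ThresholdDataset,
    dist: str = "normal",
    log_thresholds: bool = False,
    reml: bool = True,
) -> MultiThresholdFit:
    """Distribution-function mixed model across all reported thresholds.

    Per record, the cumulative proportions below threshold (tn/n0 in the
    non-diseased, fn/n1 in the diseased group, continuity-corrected as
    (k + 0.5)/(n + 1)) are quantile-transformed and regressed on threshold
    with study-level random intercepts per group and inverse delta-method
    weights.  The fitted line z = a_g + b_g c inverts to mu_g = -a_g/b_g and
    sigma_g = 1/b_g, accounting for within-study dependence (shared study
    effects) and between-study heterogeneity (their variance).
    """
    if dist not in ("normal", "logistic"):
        raise ValueError("dist must be 'normal' or 'logistic'")
    recs = [r for r in data.records if r.threshold is not None]
    studies = {r.study for r in recs}
    thrs = sorted({r.threshold for r in recs})
    if len(studies) < 2 or len(thrs) < 3:
        raise InsufficientDataError(
            "multi-threshold model needs >= 2 studies and >= 3 distinct thresholds"
        )
    if log_thresholds and min(thrs) <= 0:
        raise ValueError("log-threshold transform requires positive thresholds")

    params = {}
    tau2 = {}
    resid = {}
    conv = True
    for g in (0, 1):
        gs, xs, zs, ws = [], [], [], []
        for r in recs:
            n = r.n_nondiseased if g == 0 else r.n_diseased
            k = r.tn if g == 0 else r.fn
            p = (k + 0.5) / (n + 1)
            x = math.log(r.threshold) if log_thresholds else r.threshold
            if dist == "normal":
                z = norm.ppf(p)
                var = p * (1 - p) / (n * norm.pdf(z) ** 2)
            else:
                z = logit(p)
                var = 1.0 / (n * p * (1 - p))
            gs.append(r.study)
            xs.append(x)
            zs.append(z)
            ws.append(1.0 / var)
        a, b, t2, s2, ok = _fit_weighted_ri_lmm(
            np.array(gs), np.array(xs), np.array(zs), np.array(ws), reml=reml
        )
        if b <= 0:
            raise ConvergenceError(
                f"group {g}: non-positive fitted slope implies negative scale"
            )
        params[g] = (-a / b, 1.0 / b)
        tau2[g] = t2
        resid[g] = s2
        conv = conv and ok
    (mu0, s0), (mu1, s1) = params[0], params[1]
    return MultiThresholdFit(
        mu0, s0, mu1, s1, dist, log_thresholds, tau2, resid, conv
    )


@dataclass
class YoudenResult:
    """Youden-optimal threshold: J(c*) = Se(c*) + Sp(c*) - 1 maximal."""

    threshold: float
    j: float
    se: float
    sp: float
    degenerate: bool = False


def youden_optimal(fit: MultiThresholdFit, grid_size: int = 2001) -> YoudenResult:
    """Maximise the Youden index over thresholds.

    For two normal groups with equal scales the optimum is the midpoint of
    the means; with unequal scales it is the admissible root of the
    equal-density quadratic.  Other cases (logistic) are solved by a grid
    with local refinement.  Equal group distributions give the degenerate
    J = 0 result with an explicit flag.
    """
    mu0, s0, mu1, s1 = fit.mu0, fit.sigma0, fit.mu1, fit.sigma1
    if abs(mu0 - mu1) < 1e-12 and abs(s0 - s1) < 1e-12:
        c = mu0
        cstar = math.exp(c) if fit.log_thresholds else c
        return YoudenResult(cstar, 0.0, float(fit.sensitivity(cstar)),
                            float(fit.specificity(cstar)), degenerate=True)

    def j_of(x):
        # x on the (possibly log) model scale
        F = (lambda z: norm.cdf(z)) if fit.dist == "normal" else (lambda z: expit(z))
        return F((x - mu0) / s0) - F((x - mu1) / s1)

    lo = min(mu0 - 5 * s0, mu1 - 5 * s1)
    hi = max(mu0 + 5 * s0, mu1 + 5 * s1)
    candidates = []
    if fit.dist == "normal":
        if abs(s0 - s1) < 1e-9 * max(s0, s1):
            candidates.append(0.5 * (mu0 + mu1))
        else:
            # equal densities: quadratic in x
            a = 1 / s1**2 - 1 / s0**2
            b = 2 * (mu0 / s0**2 - mu1 / s1**2)
            c0 = mu1**2 / s1**2 - mu0**2 / s0**2 - 2 * math.log(s1 / s0)
            disc = b * b - 4 * a * c0
            if disc >= 0:
                r = math.sqrt(disc)
                candidates.extend([(-b + r) / (2 * a), (-b - r) / (2 * a)])
    grid = np.linspace(lo, hi, grid_size)
    jg = j_of(grid)
    gbest = grid[int(np.argmax(jg))]
    res = optimize.minimize_scalar(
        lambda x: -j_of(x),
        bounds=(max(lo, gbest - (hi - lo) / grid_size * 2),
                min(hi, gbest + (hi - lo) / grid_size * 2)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    candidates.append(float(res.x))
    best = max((x for x in candidates if lo <= x <= hi), key=j_of, default=gbest)
    cstar = math.exp(best) if fit.log_thresholds else best
    return YoudenResult(
        float(cstar),
        float(j_of(best)),
        float(fit.sensitivity(cstar)),
        float(fit.specificity(cstar)),
    )
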