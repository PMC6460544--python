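"""Translating pooled test accuracy to a new population.

Heterogeneity means a test's accuracy in a new setting can differ markedly
from the meta-analytic average, so beyond confidence intervals for the mean
this module derives

* prediction intervals for Se and Sp in a new population (t-based on the
  logit scale with variance tau^2 + Var(mu_hat));
* joint probability statements such as P(Se > 0.8 and Sp > 0.8) under the
  bivariate-normal predictive distribution of the logits;
* post-test probabilities (PPV, NPV) tailored to the prevalence of the new
  population, with predictive intervals; and
* a leave-one-study-out calibration check comparing predicted with observed
  predictive values, tailored vs untailored to each study's own prevalence.

The predictive distribution is bivariate normal on the logit scale with
covariance Sigma + cov(mu_hat); t-scaling is applied marginally only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import multivariate_normal, norm, t as t_dist

from .dta_core import (
    AccuracyRecord,
    BivariateFit,
    InsufficientDataError,
    ThresholdDataset,
    fit_bivariate,
    _records_from,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NewPopulationSummary",
    "CalibrationCheck",
    "prediction_interval",
    "joint_probability",
    "tailored_post_test",
    "loso_calibration",
    "ppv_npv",
]


def ppv_npv(se: float, sp: float, prevalence: float):
    """Positive and negative predictive value by Bayes' theorem.

    Degenerate denominators (e.g. prevalence 0 with a perfect test) resolve
    to PPV = 0 and NPV = 1 boundaries.
    """
    se = np.asarray(se, dtype=float)
    sp = np.asarray(sp, dtype=float)
    pi = prevalence
    num_p = se * pi
    den_p = num_p + (1 - sp) * (1 - pi)
    num_n = sp * (1 - pi)
    den_n = num_n + (1 - se) * pi
    ppv = np.where(den_p > 0, num_p / np.where(den_p > 0, den_p, 1.0), 0.0)
    npv = np.where(den_n > 0, num_n / np.where(den_n > 0, den_n, 1.0), 1.0)
    if ppv.ndim == 0:
        return float(ppv), float(npv)
    return ppv, npv


def _predictive_cov(fit: BivariateFit) -> np.ndarray:
    return fit.Sigma + fit.cov_mu


def prediction_interval(fit: BivariateFit, level: float = 0.95) -> dict:
    """t-based prediction intervals for Se and Sp in a new population.

    Marginal logit-scale intervals mu_j +/- t_{K-2} * sqrt(tau_j^2 +
    Var(mu_j)), back-transformed.  Requires >= 3 studies (df = K - 2 > 0).
    """
    k = fit.n_studies
    if k < 3:
        raise InsufficientDataError("prediction interval needs >= 3 studies")
    q = t_dist.ppf(0.5 + level / 2, k - 2)
    out = {}
    for i, name in enumerate(("se", "sp")):
        sd = math.sqrt(fit.Sigma[i, i] + fit.cov_mu[i, i])
        out[name] = (
            float(expit(fit.mu[i] - q * sd)),
            float(expit(fit.mu[i] + q * sd)),
        )
    return out


def joint_probability(
    fit: BivariateFit,
    a: float,
    b: float,
    mode: str = "monte-carlo",
    rng: np.random.Generator | None = None,
    n_draws: int = 200_000,
) -> tuple[float, float | None]:
    """P(Se > a and Sp > b) in a new population.

    Uses the bivariate-normal predictive distribution of (logit Se, logit Sp)
    with covariance Sigma + cov_mu.  Monte-Carlo mode returns (p, mc_se);
    ``mode='bivariate-cdf'`` evaluates the orthant probability numerically
    and returns (p, None).
    """
    if not (0 < a < 1) or not (0 < b < 1):
        raise ValueError("a and b must lie strictly inside (0, 1)")
    cov = _predictive_cov(fit)
    xa, xb = logit(a), logit(b)
    if mode == "monte-carlo":
        rng = np.random.default_rng() if rng is None else rng
        draws = rng.multivariate_normal(fit.mu, cov, size=n_draws)
        hits = (draws[:, 0] > xa) & (draws[:, 1] > xb)
        p = float(np.mean(hits))
        return p, math.sqrt(max(p * (1 - p), 1e-12) / n_draws)
    if mode == "bivariate-cdf":
        # P(X > xa, Y > xb) = F_{-X,-Y}(-xa, -xb)
        p = float(
            multivariate_normal(mean=-fit.mu, cov=cov, allow_singular=True).cdf(
                [-xa, -xb]
            )
        )
        return p, None
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class NewPopulationSummary:
    """Accuracy statements for a new population at a stated prevalence."""

    prevalence: float
    level: float
    se: float
    sp: float
    se_interval: tuple[float, float]
    sp_interval: tuple[float, float]
    ppv: float
    npv: float
    ppv_interval: tuple[float, float]
    npv_interval: tuple[float, float]
    joint_cutoffs: tuple[float, float] | None = None
    joint_probability: float | None = None
    notes: dict = field(default_factory=dict)


def tailored_post_test(
    fit: BivariateFit,
    prevalence: float,
    rng: np.random.Generator | None = None,
    level: float = 0.95,
    n_draws: int = 200_000,
    joint_cutoffs: tuple[float, float] | None = None,
) -> NewPopulationSummary:
    """PPV and NPV tailored to the prevalence of a new population.

    The point estimates apply Bayes' theorem at the pooled Se, Sp; predictive
    intervals propagate the logit-scale predictive distribution by Monte
    Carlo (percentiles of PPV/NPV over predictive draws).  Prevalence is held
    fixed at the stated value.
    """
    if not (0 <= prevalence <= 1):
        raise ValueError("prevalence must lie in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    ppv, npv = ppv_npv(fit.se, fit.sp, prevalence)
    draws = rng.multivariate_normal(fit.mu, _predictive_cov(fit), size=n_draws)
    se_d = expit(draws[:, 0])
    sp_d = expit(draws[:, 1])
    ppv_d, npv_d = ppv_npv(se_d, sp_d, prevalence)
    qs = (0.5 - level / 2, 0.5 + level / 2)
    jp = None
    if joint_cutoffs is not None:
        jp, _ = joint_probability(
            fit, joint_cutoffs[0], joint_cutoffs[1], rng=rng, n_draws=n_draws
        )
    pis = prediction_interval(fit, level) if fit.n_studies >= 3 else {
        "se": (float("nan"), float("nan")),
        "sp": (float("nan"), float("nan")),
    }
    return NewPopulationSummary(
        prevalence=prevalence,
        level=level,
        se=fit.se,
        sp=fit.sp,
        se_interval=pis["se"],
        sp_interval=pis["sp"],
        ppv=float(ppv),
        npv=float(npv),
        ppv_interval=tuple(float(np.quantile(ppv_d, q)) for q in qs),
        npv_interval=tuple(float(np.quantile(npv_d, q)) for q in qs),
        joint_cutoffs=joint_cutoffs,
        joint_probability=jp,
        notes={"prevalence": "held fixed (not treated as random)"},
    )


@dataclass
class CalibrationCheck:
    """Leave-one-study-out predicted vs observed PPV/NPV."""

    table: pd.DataFrame
    margin: float
    tailored: bool
    prop_ppv_within: float
    prop_npv_within: float

    @property
    def proportions(self) -> dict[str, float]:
        return {"ppv": self.prop_ppv_within, "npv": self.prop_npv_within}


def loso_calibration(
    data,
    threshold: float | None = None,
    margin: float = 0.10,
    tailored: bool = True,
    method: str = "reml",
) -> CalibrationCheck:
    """Leave-one-study-out calibration of predicted PPV/NPV.

    Each study is held out in turn; the bivariate model refit on the
    remainder predicts its PPV/NPV, tailored (that study's own prevalence)
    and untailored (pooled prevalence of the training studies).  "Within
    margin" means absolute difference <= margin on the probability scale.
    The ``tailored`` flag selects which column the headline proportions
    summarise; both columns are reported in the table.
    """
    recs = _records_from(data, threshold)
    if len(recs) < 3:
        raise InsufficientDataError("leave-one-study-out needs >= 3 studies")
    rows = []
    for i, held in enumerate(recs):
        train = recs[:i] + recs[i + 1 :]
        f = fit_bivariate(train, method=method)
        pi_own = held.n_diseased / (held.n_diseased + held.n_nondiseased)
        n_dis = sum(r.n_diseased for r in train)
        n_all = sum(r.n_diseased + r.n_nondiseased for r in train)
        pi_pool = n_dis / n_all
        ppv_t, npv_t = ppv_npv(f.se, f.sp, pi_own)
        ppv_u, npv_u = ppv_npv(f.se, f.sp, pi_pool)
        obs_ppv = held.tp / (held.tp + held.fp) if held.tp + held.fp > 0 else np.nan
        obs_npv = held.tn / (held.tn + held.fn) if held.tn + held.fn > 0 else np.nan
        if np.isnan(obs_ppv) or np.isnan(obs_npv):
            logger.info("study %s: observed PPV/NPV undefined (empty margin)", held.study)
        rows.append(
            {
                "study": held.study,
                "prevalence": pi_own,
                "obs_ppv": obs_ppv,
                "obs_npv": obs_npv,
                "pred_ppv_tailored": ppv_t,
                "pred_npv_tailored": npv_t,
                "pred_ppv_untailored": ppv_u,
                "pred_npv_untailored": npv_u,
            }
        )
    table = pd.DataFrame(rows)
    suffix = "tailored" if tailored else "untailored"
    table["ppv_error"] = table["obs_ppv"] - table[f"pred_ppv_{suffix}"]
    table["npv_error"] = table["obs_npv"] - table[f"pred_npv_{suffix}"]
    ok_p = (table["ppv_error"].abs() <= margin).loc[table["obs_ppv"].notna()]
    ok_n = (table["npv_error"].abs() <= margin).loc[table["obs_npv"].notna()]
    return CalibrationCheck(
        table,
        margin,
        tailored,
        float(ok_p.mean()) if len(ok_p) else float("nan"),
        float(ok_n.mean()) if len(ok_n) else float("nan"),
    )
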