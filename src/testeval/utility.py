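"""Decision-curve analysis: net benefit of risk models and default strategies.

At a threshold probability ``p_t`` (the risk at which treatment would be
recommended), classifying positive iff predicted risk >= p_t gives

    NB = tp/n - (fp/n) * p_t / (1 - p_t)

so false positives are discounted by the harm-to-benefit odds of the
threshold.  A model is compared against treating everyone (NB with all
subjects positive) and treating no one (NB = 0).  Differences between two
models divided by the prevalence express the gain as a net-sensitivity
difference: extra true-positive fraction at constant specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RiskPredictions",
    "DecisionCurveTable",
    "net_benefit",
    "decision_curve",
    "net_sensitivity_difference",
    "DEFAULT_GRID",
]

# thresholds between 5% and 50% by 1%
DEFAULT_GRID = np.round(np.arange(0.05, 0.5001, 0.01), 10)


@dataclass(frozen=True)
class RiskPredictions:
    """Per-subject predicted risks with binary outcomes for one model."""

    risk: np.ndarray
    outcome: np.ndarray
    model: str = "model"
    subject_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.risk, dtype=float)
        y = np.asarray(self.outcome)
        object.__setattr__(self, "risk", r)
        object.__setattr__(self, "outcome", y.astype(int))
        if r.shape != y.shape or r.ndim != 1:
            raise ValueError("risk and outcome must be equal-length 1-d arrays")
        if np.any((r < 0) | (r > 1)):
            raise ValueError("risks must lie in [0, 1]")
        if not np.isin(self.outcome, (0, 1)).all():
            raise ValueError("outcomes must be binary 0/1")

    @property
    def prevalence(self) -> float:
        return float(np.mean(self.outcome))


def net_benefit(tp: float, fp: float, n: float, p_t: float) -> float:
    """NB = tp/n - (fp/n) * p_t/(1-p_t); undefined at p_t in {0, 1}."""
    if not (0 < p_t < 1):
        raise ValueError("threshold probability must lie strictly inside (0, 1)")
    if tp + fp > n:
        raise ValueError("tp + fp cannot exceed n")
    return tp / n - (fp / n) * p_t / (1 - p_t)


def _nb_curve(risk: np.ndarray, outcome: np.ndarray, grid: np.ndarray) -> np.ndarray:
    # ties at the threshold classify positive (risk >= p_t)
    pos = risk[None, :] >= grid[:, None]
    n = risk.size
    tp = (pos & (outcome[None, :] == 1)).sum(axis=1)
    fp = (pos & (outcome[None, :] == 0)).sum(axis=1)
    return tp / n - (fp / n) * grid / (1 - grid)


@dataclass
class DecisionCurveTable:
    """Net benefit per threshold probability for models and defaults.

    ``table`` has one row per grid threshold with a column per model plus
    ``treat_all`` and ``treat_none``; ``ci`` maps model name to a (lo, hi)
    DataFrame of bootstrap percentile intervals when requested.
    """

    table: pd.DataFrame
    prevalence: float
    grid: np.ndarray
    ci: dict[str, pd.DataFrame] = field(default_factory=dict)
    n_boot: int = 0

    def net_benefit(self, model: str, p_t: float) -> float:
        idx = np.argmin(np.abs(self.grid - p_t))
        if abs(self.grid[idx] - p_t) > 1e-9:
            raise KeyError(f"threshold {p_t} not on the grid")
        return float(self.table.iloc[idx][model])


def decision_curve(
    preds: RiskPredictions | Sequence[RiskPredictions] | Mapping[str, RiskPredictions],
    grid: np.ndarray | None = None,
    n_boot: int = 0,
    rng: np.random.Generator | None = None,
    level: float = 0.95,
) -> DecisionCurveTable:
    """Tabulate net benefit across a threshold grid.

    All models must be scored on the same subjects (identical outcome
    vectors, and identical subject ids when provided).  Optional subject-level
    bootstrap (percentile intervals over ``n_boot`` resamples).
    """
    if isinstance(preds, RiskPredictions):
        models = {preds.model: preds}
    elif isinstance(preds, Mapping):
        models = dict(preds)
    else:
        models = {p.model: p for p in preds}
        if len(models) != len(list(preds)):
            raise ValueError("duplicate model labels")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("grid thresholds must lie strictly inside (0, 1)")

    first = next(iter(models.values()))
    for p in models.values():
        if p.risk.size != first.risk.size or not np.array_equal(
            p.outcome, first.outcome
        ):
            raise ValueError("all models must be scored on the same subjects")
        if (
            p.subject_id is not None
            and first.subject_id is not None
            and not np.array_equal(p.subject_id, first.subject_id)
        ):
            raise ValueError("mismatched subject ids across models")

    y = first.outcome
    prev = float(np.mean(y))
    data = {"threshold": grid}
    for name, p in models.items():
        data[name] = _nb_curve(p.risk, y, grid)
    data["treat_all"] = prev - (1 - prev) * grid / (1 - grid)
    data["treat_none"] = np.zeros_like(grid)
    table = pd.DataFrame(data)

    ci: dict[str, pd.DataFrame] = {}
    if n_boot > 0:
        rng = np.random.default_rng() if rng is None else rng
        n = y.size
        qs = (0.5 - level / 2, 0.5 + level / 2)
        boot = {name: np.empty((n_boot, grid.size)) for name in models}
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            for name, p in models.items():
                boot[name][b] = _nb_curve(p.risk[idx], yb, grid)
        for name in models:
            lo = np.quantile(boot[name], qs[0], axis=0)
            hi = np.quantile(boot[name], qs[1], axis=0)
            ci[name] = pd.DataFrame({"threshold": grid, "lo": lo, "hi": hi})
    return DecisionCurveTable(table, prev, grid, ci, n_boot)


def net_sensitivity_difference(nb_a: float, nb_b: float, prevalence: float) -> float:
    """(NB_a - NB_b) / prevalence: sensitivity gain at constant specificity."""
    if prevalence <= 0:
        raise ValueError("prevalence must be positive")
    return (nb_a - nb_b) / prevalence
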