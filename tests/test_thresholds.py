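"""Missing-threshold imputation and the distribution-function model."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import expit, logit
from scipy.stats import norm

from testeval.dta_core import AccuracyRecord, ThresholdDataset
from testeval.thresholds import (
    BoundingPair,
    ExtrapolationError,
    enumerate_combinations,
    fit_multithreshold,
    midc_meta,
    ni_meta,
    rubin_combine,
    si_complete,
    si_interpolate,
    youden_optimal,
)
from testeval.simulate import DtaSimScenario, simulate_dta_multithreshold


# ---------------------------------------------------------------------------
# SI interpolation
# ---------------------------------------------------------------------------


def _pair(lo_counts, hi_counts, targets, c_lo=1.0, c_hi=3.0):
    lo = AccuracyRecord("s", c_lo, *lo_counts)
    hi = AccuracyRecord("s", c_hi, *hi_counts)
    return BoundingPair(lo, hi, tuple(targets))


def test_si_identity_at_observed_threshold():
    pair = _pair((90, 20, 10, 80), (70, 10, 30, 90), [1.0])
    (rec,) = si_interpolate(pair)
    assert (rec.tp, rec.fp, rec.fn, rec.tn) == (90, 20, 10, 80)


def test_si_logit_midpoint_hand_computed():
    # Se 0.9 at c=1 and 0.7 at c=3 with 100 diseased: logit midpoint 1.5224,
    # Se = 0.8209, tp = 82
    pair = _pair((90, 20, 10, 80), (70, 10, 30, 90), [2.0])
    (rec,) = si_interpolate(pair)
    mid = 0.5 * (logit(0.9) + logit(0.7))
    assert mid == pytest.approx(1.5224, abs=1e-3)
    assert expit(mid) == pytest.approx(0.8209, abs=1e-4)
    assert rec.tp == 82


def test_si_flat_segment_copies_counts():
    pair = _pair((80, 15, 20, 85), (80, 15, 20, 85), [1.5, 2.5])
    for rec in si_interpolate(pair):
        assert (rec.tp, rec.fp, rec.fn, rec.tn) == (80, 15, 20, 85)


def test_si_extrapolation_refused():
    with pytest.raises(ExtrapolationError):
        _pair((90, 20, 10, 80), (70, 10, 30, 90), [4.0])


def test_si_interpolated_counts_monotone():
    pair = _pair((95, 40, 5, 60), (60, 5, 40, 95), [1.5, 2.0, 2.5])
    recs = si_interpolate(pair)
    tps = [95] + [r.tp for r in recs] + [60]
    tns = [60] + [r.tn for r in recs] + [95]
    assert all(a >= b for a, b in zip(tps, tps[1:]))
    assert all(a <= b for a, b in zip(tns, tns[1:]))


# ---------------------------------------------------------------------------
# discrete combinations
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "lo,hi,expected",
    [
        ((80, 20, 20, 80), (70, 10, 30, 90), 121),  # 11 x 11
        ((80, 20, 20, 80), (80, 20, 20, 80), 1),  # identical bounds
        ((5, 2, 95, 98), (4, 2, 96, 98), 2),  # 2 x 1
    ],
)
def test_combination_counts(lo, hi, expected):
    pair = _pair(lo, hi, [2.0])
    combos = enumerate_combinations(pair)
    assert len(combos) == expected
    assert len(set(combos)) == expected


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------


def test_rubin_worked_case():
    p = rubin_combine([1.0, 3.0], [1.0, 1.0])
    assert p.estimate == pytest.approx(2.0)
    assert p.within == pytest.approx(1.0)
    assert p.between == pytest.approx(2.0)
    assert p.total == pytest.approx(4.0)
    assert p.df == pytest.approx(1.778, abs=1e-3)


def test_rubin_no_between_variance():
    p = rubin_combine([0.0, 0.0, 0.0], [2.0, 2.0, 2.0])
    assert p.between == 0.0
    assert p.total == pytest.approx(2.0)
    assert math.isinf(p.df)
    q = rubin_combine([0.5, 0.5], [0.1, 0.3])
    assert q.within == pytest.approx(0.2)
    assert q.between == 0.0
    assert q.total == pytest.approx(0.2)


def test_rubin_rejects_invalid_input():
    with pytest.raises(ValueError):
        rubin_combine([1.0], [1.0])
    with pytest.raises(ValueError):
        rubin_combine([1.0, 2.0], [1.0, -1.0])


@given(
    st.lists(st.floats(-5, 5), min_size=2, max_size=8),
    st.floats(0.01, 2.0),
)
def test_rubin_total_identity_and_bounds(estimates, w):
    p = rubin_combine(estimates, [w] * len(estimates))
    assert p.total == pytest.approx(p.within + (1 + 1 / p.m) * p.between)
    assert p.total >= p.within - 1e-12


# ---------------------------------------------------------------------------
# MIDC
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def masked_dataset():
    scn = DtaSimScenario(
        n_studies=20, thresholds=(0.0, 0.5, 1.0, 1.5, 2.0), reporting=("mar", 0.4)
    )
    rng = np.random.default_rng(7)
    data, truth = simulate_dta_multithreshold(scn, rng)
    return data, truth, scn


def test_midc_equals_ni_when_nothing_missing():
    scn = DtaSimScenario(n_studies=10, thresholds=(0.0, 1.0, 2.0))
    data, _ = simulate_dta_multithreshold(scn, np.random.default_rng(3))
    res = midc_meta(data, scn.thresholds, m=3, rng=np.random.default_rng(11))
    ni = ni_meta(data, scn.thresholds)
    for name in ("se", "sp", "se_lo", "se_hi", "sp_lo", "sp_hi"):
        np.testing.assert_array_equal(res.summary[name].values, ni[name].values)
    # all imputations identical -> zero between-imputation variance
    assert all(p["se"].between == 0.0 for p in res.pooled.values())


def test_midc_completed_datasets_monotone(masked_dataset):
    data, _, scn = masked_dataset
    res = midc_meta(data, scn.thresholds, m=4, rng=np.random.default_rng(5))
    for ds in res.completed:
        for recs in ds.by_study().values():
            ordered = sorted(recs, key=lambda r: r.threshold)
            tps = [r.tp for r in ordered]
            tns = [r.tn for r in ordered]
            assert all(a >= b for a, b in zip(tps, tps[1:]))
            assert all(a <= b for a, b in zip(tns, tns[1:]))


def test_midc_seed_reproducibility(masked_dataset):
    data, _, scn = masked_dataset
    r1 = midc_meta(data, scn.thresholds, m=4, rng=np.random.default_rng(99))
    r2 = midc_meta(data, scn.thresholds, m=4, rng=np.random.default_rng(99))
    np.testing.assert_array_equal(r1.summary.values, r2.summary.values)


def test_midc_recovers_truth_and_tightens_intervals(masked_dataset):
    data, truth, scn = masked_dataset
    res = midc_meta(data, scn.thresholds, m=10, rng=np.random.default_rng(21))
    tru = truth["accuracy"].set_index("threshold")
    summ = res.summary.set_index("threshold")
    ni = ni_meta(data, scn.thresholds).set_index("threshold")
    mid = 1.0  # interior threshold where imputation happens
    mc_se = math.sqrt(summ.loc[mid, "logit_se_var"])
    assert abs(summ.loc[mid, "logit_se"] - tru.loc[mid, "logit_se"]) <= 3 * mc_se
    # a single replicate is noisy; require the interval not to blow up
    w_midc = logit(summ.loc[mid, "se_hi"]) - logit(summ.loc[mid, "se_lo"])
    w_ni = logit(ni.loc[mid, "se_hi"]) - logit(ni.loc[mid, "se_lo"])
    assert w_midc <= 1.25 * w_ni


def test_midc_reduces_sroc_bias_under_selective_reporting():
    """Directional claim: imputation reduces summary bias when reporting is
    driven by each study's empirical optimum and truth is logit-linear."""
    scn = DtaSimScenario(
        n_studies=20,
        dist="logistic",
        thresholds=(0.0, 0.5, 1.0, 1.5, 2.0),
        reporting=("selective", 0.55),
        het_sd_mu0=0.4,
        het_sd_mu1=0.4,
    )
    rng = np.random.default_rng(2718)
    reps = 120
    target = 1.5
    tru = None
    err_ni, err_midc = [], []
    for _ in range(reps):
        data, truth = simulate_dta_multithreshold(scn, rng)
        tru = truth["accuracy"].set_index("threshold")["logit_se"]
        ni = ni_meta(data, [target]).set_index("threshold")
        mi = midc_meta(data, scn.thresholds, m=5, rng=rng).summary.set_index(
            "threshold"
        )
        if target in ni.index:
            err_ni.append(ni.loc[target, "logit_se"] - tru[target])
        if target in mi.index:
            err_midc.append(mi.loc[target, "logit_se"] - tru[target])
    assert abs(np.mean(err_midc)) <= abs(np.mean(err_ni))


# ---------------------------------------------------------------------------
# distribution-function model
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def recovery_fit():
    scn = DtaSimScenario(
        n_studies=30,
        n_per_study=400,
        het_sd_mu0=0.2,
        het_sd_mu1=0.2,
        thresholds=(-0.5, 0.0, 0.5, 1.0, 1.5, 2.0, 2.5),
    )
    data, _ = simulate_dta_multithreshold(scn, np.random.default_rng(7))
    return fit_multithreshold(data)


def test_multithreshold_parameter_recovery(recovery_fit):
    fit = recovery_fit
    # truth (0, 1, 2, 1); 30 studies of 400 -> tolerances of a few MC SEs
    assert fit.converged
    assert fit.mu0 == pytest.approx(0.0, abs=0.15)
    assert fit.sigma0 == pytest.approx(1.0, abs=0.1)
    assert fit.mu1 == pytest.approx(2.0, abs=0.15)
    assert fit.sigma1 == pytest.approx(1.0, abs=0.1)


def test_specificity_half_at_nondiseased_median(recovery_fit):
    assert recovery_fit.specificity(recovery_fit.mu0) == pytest.approx(0.5, abs=1e-9)


def test_fitted_curves_monotone(recovery_fit):
    grid = np.linspace(-3, 5, 200)
    se = recovery_fit.sensitivity(grid)
    sp = recovery_fit.specificity(grid)
    assert np.all(np.diff(se) <= 1e-12)
    assert np.all(np.diff(sp) >= -1e-12)


def test_probit_link_exact_on_noiseless_proportions():
    # counts constructed from exact normal CDF values -> transformed values
    # almost exactly linear in threshold, residual variance ~ 0
    thresholds = np.array([-1.0, -0.5, 0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
    n = 100_000
    recs = []
    for s in range(3):
        for c in thresholds:
            tn = int(round(n * norm.cdf(c, 0, 1)))
            fn = int(round(n * norm.cdf(c, 2, 1)))
            recs.append(AccuracyRecord(f"s{s}", float(c), n - fn, n - tn, fn, tn))
    fit = fit_multithreshold(ThresholdDataset(recs))
    # the (k+0.5)/(n+1) correction leaves a sliver of curvature even here
    assert fit.resid_var[0] < 1e-3
    assert fit.mu0 == pytest.approx(0.0, abs=5e-3)
    assert fit.sigma0 == pytest.approx(1.0, abs=5e-3)
    assert fit.mu1 == pytest.approx(2.0, abs=5e-3)


def test_multithreshold_needs_three_thresholds():
    recs = [
        AccuracyRecord("a", 1.0, 80, 10, 20, 90),
        AccuracyRecord("a", 2.0, 70, 5, 30, 95),
        AccuracyRecord("b", 1.0, 75, 12, 25, 88),
        AccuracyRecord("b", 2.0, 65, 6, 35, 94),
    ]
    from testeval.dta_core import InsufficientDataError

    with pytest.raises(InsufficientDataError):
        fit_multithreshold(ThresholdDataset(recs))


# ---------------------------------------------------------------------------
# Youden
# ---------------------------------------------------------------------------


def _mk_fit(mu0, s0, mu1, s1, dist="normal", log_thresholds=False):
    from testeval.thresholds import MultiThresholdFit

    return MultiThresholdFit(mu0, s0, mu1, s1, dist, log_thresholds, {}, {}, True)


def test_youden_midpoint_for_equal_scales():
    res = youden_optimal(_mk_fit(0.0, 1.0, 2.0, 1.0))
    assert res.threshold == pytest.approx(1.0, abs=1e-6)
    # J = 2 Phi(1) - 1
    assert res.j == pytest.approx(2 * norm.cdf(1) - 1, abs=1e-6)


def test_youden_unequal_scales_matches_grid_search():
    fit = _mk_fit(0.0, 1.0, 2.0, 2.0)
    res = youden_optimal(fit)
    grid = np.linspace(-6, 10, 400_001)
    j = norm.cdf(grid, 0, 1) - norm.cdf(grid, 2, 2)
    c_grid = grid[np.argmax(j)]
    assert res.threshold == pytest.approx(c_grid, abs=1e-4)
    assert res.j >= j.max() - 1e-10


def test_youden_degenerate_identical_groups():
    res = youden_optimal(_mk_fit(1.0, 1.0, 1.0, 1.0))
    assert res.degenerate
    assert res.j == 0.0


def test_youden_logistic_grid():
    fit = _mk_fit(0.0, 1.0, 2.0, 1.0, dist="logistic")
    res = youden_optimal(fit)
    assert res.threshold == pytest.approx(1.0, abs=1e-4)
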