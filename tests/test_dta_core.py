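"""Bivariate random-effects meta-analysis: oracles, limits and invariances."""

import itertools

import numpy as np
import pytest
from scipy.special import expit, logit

from testeval.dta_core import (
    AccuracyRecord,
    InsufficientDataError,
    MonotonicityError,
    ThresholdDataset,
    fit_bivariate,
    meta_regression,
    sroc_from_bivariate,
    _study_logits,
)
from conftest import make_records


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


def test_record_rates_and_continuity_correction():
    r = AccuracyRecord("s", 1.0, 80, 10, 20, 90)
    assert r.sensitivity == pytest.approx(0.8)
    assert r.specificity == pytest.approx(0.9)
    lse, lsp, vse, vsp = r.logits()
    assert lse == pytest.approx(np.log(80 / 20))
    assert vse == pytest.approx(1 / 80 + 1 / 20)
    # zero cell triggers the half-count correction on all four cells
    rz = AccuracyRecord("z", 1.0, 50, 0, 10, 40)
    lse, lsp, vse, vsp = rz.logits()
    assert lsp == pytest.approx(np.log(40.5 / 0.5))
    assert vse == pytest.approx(1 / 50.5 + 1 / 10.5)


def test_record_requires_both_groups():
    with pytest.raises(ValueError):
        AccuracyRecord("s", 1.0, 0, 5, 0, 5)


def test_dataset_monotonicity_enforced_and_waivable():
    recs = [
        AccuracyRecord("s", 1.0, 70, 10, 30, 90),
        AccuracyRecord("s", 2.0, 80, 5, 20, 95),  # tp increases with threshold
    ]
    with pytest.raises(MonotonicityError):
        ThresholdDataset(recs)
    ds = ThresholdDataset(recs, validate=False)
    assert len(ds.records) == 2


def test_csv_round_trip(tmp_path, hetero_dataset):
    path = tmp_path / "data.csv"
    hetero_dataset.to_csv(path)
    back = ThresholdDataset.from_csv(path)
    assert back.to_frame().equals(hetero_dataset.to_frame())


# ---------------------------------------------------------------------------
# fit_bivariate
# ---------------------------------------------------------------------------


def test_identical_studies_collapse_heterogeneity():
    recs = [AccuracyRecord(f"s{i}", 2.0, 80, 10, 20, 90) for i in range(3)]
    f = fit_bivariate(recs)
    assert f.se == pytest.approx(0.80, abs=1e-6)
    assert f.sp == pytest.approx(0.90, abs=1e-6)
    assert f.tau2_se == pytest.approx(0.0, abs=1e-4)
    assert f.tau2_sp == pytest.approx(0.0, abs=1e-4)


def test_fixed_effect_equals_inverse_variance_means(hetero_records):
    f = fit_bivariate(hetero_records, method="fe")
    Y, S = _study_logits(hetero_records)
    w = 1.0 / S
    expected = (w * Y).sum(axis=0) / w.sum(axis=0)
    np.testing.assert_allclose(f.mu, expected, rtol=0, atol=1e-12)
    assert np.all(f.Sigma == 0)


def test_reml_limits_to_fixed_effect_without_heterogeneity():
    # identical studies: tau2 -> 0 and mu equals the inverse-variance mean
    recs = [AccuracyRecord(f"s{i}", 2.0, 75, 12, 25, 88) for i in range(4)]
    f = fit_bivariate(recs)
    fe = fit_bivariate(recs, method="fe")
    np.testing.assert_allclose(f.mu, fe.mu, atol=1e-5)


def test_insufficient_studies_raises():
    with pytest.raises(InsufficientDataError):
        fit_bivariate([AccuracyRecord("s", 1.0, 5, 5, 5, 5)])


def test_permutation_invariance(hetero_records):
    f1 = fit_bivariate(hetero_records)
    f2 = fit_bivariate(list(reversed(hetero_records)))
    # identical up to float summation order in the likelihood
    np.testing.assert_allclose(f1.mu, f2.mu, atol=1e-6)
    np.testing.assert_allclose(f1.Sigma, f2.Sigma, atol=1e-6)


def _grid_oracle_nll_factory(Y, S, reml=True):
    def nll(mu0, mu1, t0, t1, rho):
        sig01 = rho * t0 * t1
        v00 = t0 * t0 + S[:, 0]
        v11 = t1 * t1 + S[:, 1]
        det = v00 * v11 - sig01**2
        i00, i11, i01 = v11 / det, v00 / det, -sig01 / det
        r0, r1 = Y[:, 0] - mu0, Y[:, 1] - mu1
        quad = (i00 * r0**2 + 2 * i01 * r0 * r1 + i11 * r1**2).sum(axis=-1)
        out = 0.5 * (np.log(det).sum(axis=-1) + quad)
        if reml:
            a00 = i00.sum(axis=-1)
            a01 = i01.sum(axis=-1)
            a11 = i11.sum(axis=-1)
            out = out + 0.5 * np.log(a00 * a11 - a01**2)
        return out

    return nll


def grid_search_maximizer(Y, S, reml=True, rounds=6, points=7):
    """Independent brute-force maximiser of the same likelihood (K small)."""
    nll = _grid_oracle_nll_factory(Y, S, reml)
    centre = np.array([Y[:, 0].mean(), Y[:, 1].mean(), 0.4, 0.4, 0.0])
    half = np.array([1.5, 1.5, 0.45, 0.45, 0.9])
    for _ in range(rounds):
        axes = [np.linspace(c - h, c + h, points) for c, h in zip(centre, half)]
        axes[2] = np.clip(axes[2], 1e-4, None)
        axes[3] = np.clip(axes[3], 1e-4, None)
        axes[4] = np.clip(axes[4], -0.999, 0.999)
        mesh = np.meshgrid(*axes, indexing="ij")
        flat = [m.ravel() for m in mesh]
        vals = np.array(
            [
                nll(m0, m1, t0, t1, r)
                for m0, m1, t0, t1, r in zip(*flat)
            ]
        )
        best = np.argmin(vals)
        centre = np.array([f[best] for f in flat])
        half = half / 3.0
    return centre


@pytest.mark.parametrize("seed", [3, 17])
def test_likelihood_maximizer_matches_grid_search(seed):
    rng = np.random.default_rng(seed)
    recs = make_records(rng, k=5, n1=100, n0=100, mu=(1.2, 1.8), sd=(0.5, 0.5))
    Y, S = _study_logits(recs)
    oracle = grid_search_maximizer(Y, S)
    f = fit_bivariate(recs)
    assert abs(f.mu[0] - oracle[0]) <= 1e-3
    assert abs(f.mu[1] - oracle[1]) <= 1e-3
    assert abs(np.sqrt(f.tau2_se) - oracle[2]) <= 1e-3
    assert abs(np.sqrt(f.tau2_sp) - oracle[3]) <= 1e-3


# ---------------------------------------------------------------------------
# SROC
# ---------------------------------------------------------------------------


def _fit_with(mu, Sigma):
    from testeval.dta_core import BivariateFit

    return BivariateFit(
        np.asarray(mu, float), np.asarray(Sigma, float), np.eye(2) * 1e-4, 0.0, 10, True
    )


def test_sroc_zero_covariance_gives_flat_curve():
    f = _fit_with([logit(0.8), logit(0.9)], [[0.3, 0.0], [0.0, 0.2]])
    c = sroc_from_bivariate(f)
    assert c.slope == pytest.approx(0.0)
    assert np.allclose(c.se, 0.8)


def test_sroc_passes_through_summary_point():
    f = _fit_with([logit(0.8), logit(0.9)], [[0.3, -0.1], [-0.1, 0.2]])
    c = sroc_from_bivariate(f, fpr_grid=[0.1])
    assert c.se[0] == pytest.approx(0.8, abs=1e-12)


def test_sroc_matches_hand_evaluated_line():
    Sigma = np.array([[0.3, -0.12], [-0.12, 0.25]])
    mu = np.array([logit(0.75), logit(0.85)])
    f = _fit_with(mu, Sigma)
    grid = np.array([0.05, 0.2, 0.5])
    c = sroc_from_bivariate(f, grid)
    b = -Sigma[0, 1] / Sigma[1, 1]
    a = mu[0] + b * mu[1]
    np.testing.assert_allclose(c.se, expit(a + b * logit(grid)), atol=1e-12)
    # non-negative slope => Se non-decreasing in FPR
    dense = sroc_from_bivariate(f, np.linspace(0.01, 0.99, 200))
    assert np.all(np.diff(dense.se) >= 0)


def test_sroc_degenerate_tau_sp():
    f = _fit_with([logit(0.8), logit(0.9)], [[0.3, 0.0], [0.0, 0.0]])
    c = sroc_from_bivariate(f)
    assert c.degenerate
    assert np.allclose(c.se, 0.8)


# ---------------------------------------------------------------------------
# meta-regression
# ---------------------------------------------------------------------------


def test_metareg_identical_groups_zero_effects():
    import pandas as pd

    recs, cov = [], []
    for i in range(5):
        for g, lab in ((0, "a"), (1, "b")):
            recs.append(
                AccuracyRecord(f"{lab}{i}", 1.0, 80 + i, 10 + i, 20 - i, 90 - i)
            )
            cov.append({"study": f"{lab}{i}", "direct": g, "assay": i % 2})
    fit = meta_regression(
        recs, pd.DataFrame(cov), terms=["direct", "assay"], interactions=[("direct", "assay")]
    )
    for term in ("logit_se:direct", "logit_sp:direct", "logit_se:direct:assay"):
        assert abs(fit.coef[term]) < 1e-6


def test_metareg_subgroup_coefficient_equals_separate_fits():
    import pandas as pd

    # two internally homogeneous subgroups (no within-subgroup heterogeneity)
    recs, cov = [], []
    for i in range(4):
        recs.append(AccuracyRecord(f"a{i}", 1.0, 80, 10, 20, 90))
        cov.append({"study": f"a{i}", "g": 0})
        recs.append(AccuracyRecord(f"b{i}", 1.0, 70, 15, 30, 85))
        cov.append({"study": f"b{i}", "g": 1})
    fit = meta_regression(recs, pd.DataFrame(cov), terms=["g"])
    fa = fit_bivariate([r for r in recs if r.study.startswith("a")])
    fb = fit_bivariate([r for r in recs if r.study.startswith("b")])
    assert fit.coef["logit_se:g"] == pytest.approx(fb.mu[0] - fa.mu[0], abs=1e-3)
    assert fit.coef["logit_sp:g"] == pytest.approx(fb.mu[1] - fa.mu[1], abs=1e-3)


def test_metareg_recovers_simulated_covariate_effect():
    import pandas as pd

    rng = np.random.default_rng(9)
    recs, cov = [], []
    n1 = n0 = 200
    for i in range(40):
        x = i % 2
        lse = rng.normal(1.0 + 0.5 * x, 0.25)
        lsp = rng.normal(1.8, 0.25)
        tp = int(np.clip(rng.binomial(n1, expit(lse)), 1, n1 - 1))
        tn = int(np.clip(rng.binomial(n0, expit(lsp)), 1, n0 - 1))
        recs.append(AccuracyRecord(f"s{i}", 1.0, tp, n0 - tn, n1 - tp, tn))
        cov.append({"study": f"s{i}", "x": x})
    fit = meta_regression(recs, pd.DataFrame(cov), terms=["x"])
    est = fit.coef["logit_se:x"]
    se = fit.wald.loc["logit_se:x", "se"]
    assert abs(est - 0.5) < 3 * se


def test_metareg_rank_deficient_design_names_columns():
    import pandas as pd

    recs = [AccuracyRecord(f"s{i}", 1.0, 80, 10, 20, 90) for i in range(4)]
    cov = pd.DataFrame(
        {"study": [r.study for r in recs], "a": [1, 0, 1, 0], "b": [1, 0, 1, 0]}
    )
    with pytest.raises(ValueError, match="collinear"):
        meta_regression(recs, cov, terms=["a", "b"])
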