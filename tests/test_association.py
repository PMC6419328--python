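"""Logistic carrier association, Wald inference, odds ratios and BH FDR."""

import numpy as np
import pytest
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from tohscan.association import (
    associate_all,
    bh_fdr,
    fit_logistic,
    odds_ratio_ci,
    wald_test,
)
from tohscan.core import DataError
from tohscan.ctoh import CTOHRegion
from tohscan.validation import normal_tail_quadrature, stepup_bh, woolf_2x2

import pandas as pd


def two_by_two(a, b, c, d):
    """cases: a carriers / b non; controls: c carriers / d non."""
    y = np.r_[np.ones(a + b), np.zeros(c + d)]
    x = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    return y, np.column_stack([np.ones_like(y), x])


def test_intercept_only_reproduces_log_odds():
    y = np.r_[np.ones(40), np.zeros(60)]
    fit = fit_logistic(y, np.ones((100, 1)))
    assert fit.beta[0] == pytest.approx(np.log(40 / 60), abs=1e-8)


def test_independent_carrier_has_zero_coefficient():
    y, x = two_by_two(20, 30, 20, 30)
    fit = fit_logistic(y, x)
    assert abs(fit.beta[1]) < 1e-8


def test_closed_form_or_and_woolf_se():
    y, x = two_by_two(30, 70, 10, 90)
    fit = fit_logistic(y, x)
    beta, se = woolf_2x2(30, 70, 10, 90)
    assert beta == pytest.approx(np.log(3.857142857), rel=1e-9)
    assert fit.beta[1] == pytest.approx(beta, abs=1e-6)
    assert fit.se[1] == pytest.approx(se, abs=1e-6)
    odds, lo, hi = odds_ratio_ci(fit.beta[1], fit.se[1])
    assert odds == pytest.approx(3.857, abs=2e-3)
    assert lo == pytest.approx(1.77, abs=0.01)
    assert hi == pytest.approx(8.42, abs=0.01)


def test_fit_matches_statsmodels_with_covariates(rng):
    n = 300
    x = np.column_stack(
        [
            np.ones(n),
            rng.integers(0, 2, n),
            rng.integers(0, 2, n),
            rng.normal(size=n),
            rng.normal(size=n),
        ]
    )
    eta = -0.3 + 0.8 * x[:, 1] + 0.2 * x[:, 2] - 0.5 * x[:, 3]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    fit = fit_logistic(y, x)
    ref = sm.Logit(y, x).fit(disp=0)
    assert np.allclose(fit.beta, ref.params, atol=1e-6)
    assert np.allclose(fit.se, ref.bse, atol=1e-6)


def test_degenerate_inputs_raise():
    y = np.ones(10)
    with pytest.raises(DataError):
        fit_logistic(y, np.ones((10, 1)))
    y = np.r_[np.ones(5), np.zeros(5)]
    x = np.column_stack([np.ones(10), np.arange(10), 2 * np.arange(10)])
    with pytest.raises(DataError):
        fit_logistic(y, x)


def test_separation_is_flagged_not_raised():
    y = np.r_[np.ones(20), np.zeros(20)]
    x = np.column_stack([np.ones(40), y])  # carrier == outcome: separation
    fit = fit_logistic(y, x)
    assert not fit.converged


def test_wald_values(rng):
    assert wald_test(0.0, 1.0) == 1.0
    assert wald_test(1.959964, 1.0) == pytest.approx(0.05, abs=1e-6)
    for _ in range(30):
        beta = float(rng.uniform(-3, 3)) or 0.5
        se = float(rng.uniform(0.1, 2.0))
        assert wald_test(beta, se) == pytest.approx(
            normal_tail_quadrature(beta / se), abs=1e-10
        )
    with pytest.raises(DataError):
        wald_test(1.0, 0.0)


def test_ci_null_and_duality(rng):
    odds, lo, hi = odds_ratio_ci(0.0, 0.5)
    assert odds == 1.0
    assert lo * hi == pytest.approx(1.0, rel=1e-12)
    for _ in range(200):
        beta = float(rng.uniform(-2, 2)) or 0.3
        se = float(rng.uniform(0.05, 1.5))
        _o, lo, hi = odds_ratio_ci(beta, se, 0.95)
        excludes_one = lo > 1.0 or hi < 1.0
        assert excludes_one == (wald_test(beta, se) < 0.05)
    with pytest.raises(DataError):
        odds_ratio_ci(0.5, 0.1, level=1.0)


def test_bh_examples_and_oracle(rng):
    assert bh_fdr(np.array([0.03]))[0] == 0.03
    assert np.allclose(bh_fdr(np.array([0.01, 0.02, 0.03, 0.04])), 0.04)
    for _ in range(100):
        p = rng.uniform(1e-5, 1, size=int(rng.integers(1, 60)))
        q = bh_fdr(p)
        assert np.allclose(q, stepup_bh(p), atol=1e-12)
        assert np.allclose(
            q, multipletests(p, method="fdr_bh")[1], atol=1e-12
        )
        assert np.all(q >= p - 1e-12)  # step-up never undercuts the raw p-value
        # monotone in sorted-p order, permutation equivariant
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        perm = rng.permutation(len(p))
        assert np.allclose(bh_fdr(p[perm]), q[perm], atol=1e-15)
    with pytest.raises(DataError):
        bh_fdr(np.array([0.0, 0.5]))
    with pytest.raises(DataError):
        bh_fdr(np.array([1.5]))


def region(i, n_carr=0):
    return CTOHRegion(
        region_id=f"r{i}", chrom="chr1", start=0, end=99, start_bp=1,
        end_bp=1000, n_snps=100, max_coverage=12, min_coverage=10,
    )


def test_associate_all_flags_degenerate_regions(rng):
    n = 200
    y = np.r_[np.ones(100), np.zeros(100)]
    carrier = rng.integers(0, 2, n)
    carriers = pd.DataFrame(
        {"r0": np.zeros(n, dtype=int), "r1": carrier},
        index=[f"i{j}" for j in range(n)],
    )
    regions = [region(0), region(1)]
    res = associate_all(regions, carriers, y)
    r0 = res[res["region_id"] == "r0"].iloc[0]
    r1 = res[res["region_id"] == "r1"].iloc[0]
    assert not r0["estimable"] and np.isnan(r0["fdr_q"])
    assert r1["converged"] and r1["fdr_q"] == pytest.approx(r1["p_value"])
    assert (res["fdr_q"].dropna() >= res["p_value"].dropna()).all()


def test_associate_all_empty_warns():
    carriers = pd.DataFrame(index=["a", "b"])
    with pytest.warns(UserWarning):
        res = associate_all([], carriers, np.array([1, 0]))
    assert len(res) == 0
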