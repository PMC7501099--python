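"""Conjugate combination, directional probabilities, Gibbs fits, reverse-Bayes."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bayesdm.bayes import (
    McmcConfig,
    NormalSummary,
    PriorSpec,
    RegressionSpec,
    build_design,
    ci_to_sd,
    combine_normal_summaries,
    directional_probability,
    fit_bayes_lm,
    group_contrast,
    ols_fit,
    prediction_prior,
    reverse_bayes,
)

means = st.floats(-2.0, 2.0)
sds = st.floats(0.01, 3.0)


@pytest.mark.parametrize(
    "lower, upper, expected",
    [
        (-1.959964, 1.959964, 1.0),
        (0.10, 0.64, 0.1378),
        (0.00, 0.50, 0.1276),
    ],
)
def test_ci_to_sd(lower, upper, expected):
    assert ci_to_sd(lower, upper) == pytest.approx(expected, abs=1e-4)


def test_ci_to_sd_rejects_inverted_interval():
    with pytest.raises(ValueError):
        ci_to_sd(1.0, 0.0)


def test_combine_published_group_difference():
    prior = NormalSummary.from_ci(0.37, 0.10, 0.64)
    lik = NormalSummary.from_ci(0.24, -0.02, 0.51)
    post = combine_normal_summaries(prior, lik)
    assert post.mean == pytest.approx(0.30, abs=0.01)


def test_combine_published_prediction():
    prior = NormalSummary(0.25, 0.1276)
    lik = NormalSummary.from_ci(0.10, 0.01, 0.20)
    post = combine_normal_summaries(prior, lik)
    assert post.mean == pytest.approx(0.12, abs=0.01)


def test_combine_equal_sds_averages_means():
    post = combine_normal_summaries(NormalSummary(0.4, 0.2), NormalSummary(-0.2, 0.2))
    assert post.mean == pytest.approx(0.1)
    assert post.sd == pytest.approx(0.2 / math.sqrt(2))


@given(m1=means, s1=sds, m2=means, s2=sds)
@settings(deadline=None, max_examples=100)
def test_combine_properties(m1, s1, m2, s2):
    a, b = NormalSummary(m1, s1), NormalSummary(m2, s2)
    post = combine_normal_summaries(a, b)
    # symmetry, precision additivity, mean betweenness, sd shrinkage
    sym = combine_normal_summaries(b, a)
    assert post.mean == pytest.approx(sym.mean, rel=1e-9, abs=1e-12)
    assert 1 / post.sd**2 == pytest.approx(1 / s1**2 + 1 / s2**2, rel=1e-9)
    assert min(m1, m2) - 1e-9 <= post.mean <= max(m1, m2) + 1e-9
    assert post.sd <= min(s1, s2)


@pytest.mark.parametrize(
    "summary, direction, expected",
    [
        (NormalSummary(0.0, 0.3), "greater", 50.0),
        (NormalSummary(1.6449, 1.0), "greater", 95.0),
        (NormalSummary.from_ci(0.30, 0.06, 0.54), "greater", 99.0),
    ],
)
def test_directional_probability(summary, direction, expected):
    assert directional_probability(summary, direction) == pytest.approx(expected, abs=0.5)


def test_directional_probability_on_draws():
    draws = np.array([-1.0, -0.5, 0.0, 0.5, 1.0, 2.0])
    assert directional_probability(draws, "greater") == pytest.approx(100 * 3.5 / 6)


@given(m=means, s=sds)
@settings(deadline=None, max_examples=50)
def test_directions_sum_to_100(m, s):
    summary = NormalSummary(m, s)
    total = directional_probability(summary, "greater") + directional_probability(summary, "less")
    assert total == pytest.approx(100.0, abs=1e-9)


def test_prediction_prior_is_the_medium_association_normal():
    prior = prediction_prior("greater")
    assert prior.mean == 0.25
    assert prior.sd == pytest.approx(0.1276, abs=1e-4)
    assert prior.sd**2 == pytest.approx(0.016, abs=5e-4)


# ---------------------------------------------------------------------------
# Regression fits
# ---------------------------------------------------------------------------

def _toy_data(n=300, slope=0.5, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    return pd.DataFrame({"x": x, "y": slope * x + rng.standard_normal(n)})


def test_vague_prior_matches_ols(fast_mcmc):
    df = _toy_data()
    spec = RegressionSpec(outcome="y", predictor="x")
    draws = fit_bayes_lm(df, spec, PriorSpec(), fast_mcmc)
    assert draws["x"].mean() == pytest.approx(ols_fit(df, spec)["x"].mean, abs=0.01)


def test_informative_prior_matches_conjugate_combination(fast_mcmc):
    """Single-predictor fit with fixed noise variance equals the closed form."""
    import statsmodels.api as sm

    df = _toy_data(slope=0.1, seed=3)
    df["x"] = (df["x"] - df["x"].mean()) / df["x"].std(ddof=0)  # orthogonal to intercept
    spec = RegressionSpec(outcome="y", predictor="x")
    res = sm.OLS(df["y"], sm.add_constant(df["x"])).fit()
    prior = NormalSummary(0.25, 0.1276)
    draws = fit_bayes_lm(
        df, spec, PriorSpec(priors={"x": prior}), fast_mcmc, sigma2=float(res.mse_resid)
    )
    closed = combine_normal_summaries(prior, NormalSummary(float(res.params["x"]), float(res.bse["x"])))
    assert draws["x"].mean() == pytest.approx(closed.mean, abs=0.01)
    assert draws["x"].std(ddof=1) == pytest.approx(closed.sd, rel=0.1)


def test_fit_is_seed_deterministic(fast_mcmc):
    df = _toy_data()
    spec = RegressionSpec(outcome="y", predictor="x")
    a = fit_bayes_lm(df, spec, PriorSpec(), fast_mcmc)
    b = fit_bayes_lm(df, spec, PriorSpec(), fast_mcmc)
    np.testing.assert_array_equal(a["x"], b["x"])


def test_rank_deficient_design_rejected(fast_mcmc):
    df = _toy_data(n=50)
    df["x2"] = 2 * df["x"]
    spec = RegressionSpec(outcome="y", predictor="x", covariates=("x2",))
    with pytest.raises(ValueError, match="rank"):
        build_design(df, spec)


def test_mcmc_config_validation():
    with pytest.raises(ValueError):
        McmcConfig(burn_in=0, draws=100)
    with pytest.raises(ValueError):
        McmcConfig(burn_in=50, draws=100, thinning=0)


def test_group_contrast_conventions():
    d = np.array([0.1, 0.2, 0.3])
    assert group_contrast(d, d) == pytest.approx(50.0)  # ties count half
    assert group_contrast(d + 1.0, d) == 100.0
    with pytest.raises(ValueError):
        group_contrast(d, d[:2])


# ---------------------------------------------------------------------------
# Reverse-Bayes
# ---------------------------------------------------------------------------

def test_reverse_bayes_overwhelming_data_reaches_floor():
    best, trace = reverse_bayes(
        NormalSummary(10.0, 0.1), 0.02, "greater", start_mean=0.37, floor=-0.5
    )
    assert best == pytest.approx(trace[-1][0])
    assert trace[-1][0] <= -0.43  # walked the whole grid without failing


def test_reverse_bayes_start_already_failing_returns_none():
    # posterior z < 1.645: even the starting prior cannot support the claim
    best, trace = reverse_bayes(NormalSummary(0.0, 1.0), 0.02, "greater", start_mean=0.05)
    assert best is None
    assert len(trace) == 1 and trace[0][1] < 95.0


def test_reverse_bayes_published_nd_delay_grid():
    # likelihood 0.08 (sd 0.1276), prior variance 0.02, grid anchored at 0.37
    best, trace = reverse_bayes(
        NormalSummary(0.08, 0.1276), 0.02, "greater", start_mean=0.37
    )
    assert best == pytest.approx(0.27)
    # independently recompute the boundary: the next step down must fail
    next_mean = best - 0.1
    post = combine_normal_summaries(NormalSummary(next_mean, math.sqrt(0.02)), NormalSummary(0.08, 0.1276))
    assert directional_probability(post, "greater") < 95.0


def test_reverse_bayes_decimal_anchoring():
    best, _ = reverse_bayes(
        NormalSummary(0.08, 0.1276), 0.02, "greater", start_mean=0.37, anchor="decimal"
    )
    assert best == pytest.approx(0.30)


@given(lik_mean=st.floats(0.0, 2.0), lik_sd=st.floats(0.05, 1.0), start=st.floats(0.0, 1.0))
@settings(deadline=None, max_examples=50)
def test_reverse_bayes_trace_monotone(lik_mean, lik_sd, start):
    # a tiny threshold keeps the walk going to the floor, exposing the full trace
    _, trace = reverse_bayes(
        NormalSummary(lik_mean, lik_sd), 0.02, "greater",
        threshold=1e-9, start_mean=start, floor=start - 1.0,
    )
    assert len(trace) >= 10
    probs = [p for _, p in trace]
    assert all(a >= b - 1e-9 for a, b in zip(probs, probs[1:]))
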