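"""Value functions, grid updating and adaptive session behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bayesdm.task_engine import (
    LOG_BETA_AXIS,
    AgentParams,
    PosteriorGrid,
    RenormalizationError,
    TaskConfig,
    TaskOffer,
    bayes_update,
    choice_probability,
    choices_to_frame,
    gamble_utility,
    offer_values,
    run_session,
    select_offer,
    subjective_value_delayed,
    subjective_value_probabilistic,
)


@pytest.mark.parametrize(
    "amount, delay, k, expected",
    [
        (10.00, 123, 0.0, 10.00),  # zero discounting: identity
        (10.00, 14, 0.1, 4.1667),  # 10 / (1 + 1.4)
        (5.00, 365, 0.01, 1.0753),  # 5 / (1 + 3.65)
    ],
)
def test_delayed_value(amount, delay, k, expected):
    assert subjective_value_delayed(amount, delay, k) == pytest.approx(expected, abs=1e-4)


@pytest.mark.parametrize(
    "amount, p, k, expected",
    [
        (10.00, 1.0, 3.7, 10.00),  # certainty identity
        (10.00, 0.5, 1.0, 5.00),  # odds against 1
        (-8.00, 0.2, 0.5, -2.6667),  # odds against 4, loss keeps its sign
    ],
)
def test_probabilistic_value(amount, p, k, expected):
    assert subjective_value_probabilistic(amount, p, k) == pytest.approx(expected, abs=1e-4)


@pytest.mark.parametrize(
    "gain, loss, lam, expected",
    [(10, 10, 1.0, 0.0), (40, 20, 2.0, 0.0), (20, 5, 1.5, 6.25)],
)
def test_gamble_utility(gain, loss, lam, expected):
    assert gamble_utility(gain, loss, lam) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize(
    "vb, va, beta, expected",
    [(3.3, 3.3, 7.0, 0.5), (1.0, 0.0, 0.0, 0.5), (2.0, 1.0, 1.0, 0.7311)],
)
def test_choice_probability(vb, va, beta, expected):
    assert choice_probability(vb, va, beta) == pytest.approx(expected, abs=1e-4)


def test_choice_probability_deterministic_limit():
    assert choice_probability(1.0, 0.0, 500.0) > 0.999999


@pytest.mark.parametrize(
    "fn, args",
    [
        (subjective_value_delayed, (10.0, -1, 0.1)),
        (subjective_value_delayed, (10.0, 5, -0.1)),
        (subjective_value_probabilistic, (10.0, 0.0, 0.1)),
        (subjective_value_probabilistic, (10.0, 1.2, 0.1)),
        (gamble_utility, (10.0, 5.0, 0.0)),
        (choice_probability, (1.0, 0.0, -1.0)),
    ],
)
def test_domain_errors(fn, args):
    with pytest.raises(ValueError):
        fn(*args)


@given(
    delay=st.integers(1, 365),
    k=st.floats(1e-4, 10.0),
    factor=st.floats(1.1, 5.0),
)
@settings(deadline=None, max_examples=50)
def test_value_monotone_in_delay_and_k(delay, k, factor):
    v = subjective_value_delayed(10.0, delay, k)
    assert v < 10.0
    assert subjective_value_delayed(10.0, delay * factor, k) < v
    assert subjective_value_delayed(10.0, delay, k * factor) < v


@given(p=st.sampled_from([2 / 3, 1 / 2, 1 / 3, 1 / 4, 1 / 5]), k=st.floats(1e-3, 10.0))
@settings(deadline=None, max_examples=30)
def test_probabilistic_value_increases_with_p(p, k):
    lower_p = p / 2
    assert subjective_value_probabilistic(10.0, p, k) > subjective_value_probabilistic(
        10.0, lower_p, k
    )


# ---------------------------------------------------------------------------
# Grid updating
# ---------------------------------------------------------------------------

def test_uninformative_trial_leaves_uniform_grid_unchanged():
    grid = PosteriorGrid.for_task("delay")
    offer = TaskOffer(option_a_amount=10.0, option_b_amount=10.0, delay_days=0)
    out = bayes_update(grid, offer, "b", "delay")
    np.testing.assert_allclose(out.mass, grid.mass, atol=1e-12)


def test_patient_choice_shifts_mass_to_low_k():
    # two candidate discount rates; choosing the delayed option favours k=0.001
    grid = PosteriorGrid.uniform(np.log([0.001, 10.0]), np.log([5.0]))
    offer = TaskOffer(option_a_amount=5.0, option_b_amount=10.0, delay_days=365)
    out = bayes_update(grid, offer, "b", "delay")
    assert out.mass[0, 0] > 0.999
    # hand Bayes: prior 0.5 each, likelihoods logistic(5*(Vb-5))
    p_low = choice_probability(10 / (1 + 0.001 * 365), 5.0, 5.0)
    p_high = choice_probability(10 / (1 + 10.0 * 365), 5.0, 5.0)
    assert out.mass[0, 0] == pytest.approx(p_low / (p_low + p_high), rel=1e-9)


def test_mass_normalized_after_every_update(rng):
    grid = PosteriorGrid.for_task("prob_gain")
    config = TaskConfig(task_kind="prob_gain")
    for _ in range(15):
        offer = select_offer(grid, config, rng)
        grid = bayes_update(grid, offer, "a" if rng.random() < 0.5 else "b", "prob_gain")
        assert grid.mass.min() >= 0
        assert grid.mass.sum() == pytest.approx(1.0, abs=1e-9)


def test_sequential_update_matches_joint_likelihood_oracle(rng):
    """On a 3x3 grid, trial-by-trial updating equals one-shot normalization."""
    param_axis = np.log([0.01, 0.1, 1.0])
    beta_axis = np.log([0.5, 2.0, 8.0])
    offers = [
        TaskOffer(option_a_amount=4.0, option_b_amount=10.0, delay_days=31),
        TaskOffer(option_a_amount=8.0, option_b_amount=10.0, delay_days=365),
        TaskOffer(option_a_amount=2.0, option_b_amount=10.0, delay_days=7),
    ]
    choices = ["b", "a", "b"]
    grid = PosteriorGrid.uniform(param_axis, beta_axis)
    for offer, choice in zip(offers, choices):
        grid = bayes_update(grid, offer, choice, "delay")
    # oracle: direct product of per-node likelihoods over all 9 nodes
    joint = np.ones((3, 3))
    for i, lk in enumerate(param_axis):
        for j, lb in enumerate(beta_axis):
            for offer, choice in zip(offers, choices):
                va, vb = offer_values(offer, "delay", math.exp(lk))
                p_b = choice_probability(vb, va, math.exp(lb))
                joint[i, j] *= p_b if choice == "b" else 1 - p_b
    np.testing.assert_allclose(grid.mass, joint / joint.sum(), atol=1e-12)


def test_renormalization_error_is_diagnosed():
    # a single near-deterministic node: choosing the dominated option has
    # likelihood that underflows to exactly zero, annihilating the mass
    grid = PosteriorGrid.uniform(np.log([1e-6]), np.log([1000.0]))
    offer = TaskOffer(option_a_amount=0.30, option_b_amount=10.0, delay_days=3)
    with pytest.raises(RenormalizationError):
        bayes_update(grid, offer, "a", "delay")


# ---------------------------------------------------------------------------
# Offer selection
# ---------------------------------------------------------------------------

def _point_mass_grid(log_param: float) -> PosteriorGrid:
    return PosteriorGrid.uniform(np.array([log_param]), LOG_BETA_AXIS)


def test_select_offer_at_indifference(rng):
    # k -> 0: no discounting, sooner amount clips to the 10 euro maximum
    offer = select_offer(_point_mass_grid(-30.0), TaskConfig(task_kind="delay"), rng)
    assert offer.option_a_amount == pytest.approx(10.0)
    # k = 0.1, delay 14: indifference at the hyperbolic value 4.17
    cfg = TaskConfig(task_kind="delay", delays=(14,))
    offer = select_offer(_point_mass_grid(math.log(0.1)), cfg, rng)
    assert offer.option_a_amount == pytest.approx(4.17)
    assert offer.option_b_amount == 10.0


def test_select_offer_mixed_gamble_gain_tracks_lambda(rng):
    # loss lattice collapses to the single value 10.0
    cfg = TaskConfig(task_kind="mixed_gamble", gamble_loss_range=(10.0, 10.4))
    offer = select_offer(_point_mass_grid(math.log(2.0)), cfg, rng)
    assert offer.loss == 10.0
    assert offer.gain == pytest.approx(20.0)


def test_select_offer_prob_loss_is_negative_framing(rng):
    cfg = TaskConfig(task_kind="prob_loss", probabilities=(0.5,))
    offer = select_offer(_point_mass_grid(math.log(1.0)), cfg, rng)
    assert offer.sign == "loss"
    assert offer.option_b_amount == -10.0
    assert offer.option_a_amount == pytest.approx(-5.0)  # -10/(1+1*1)


def test_offer_menus_and_ranges(rng):
    cfg = TaskConfig(task_kind="delay")
    grid = PosteriorGrid.for_task("delay")
    for _ in range(20):
        offer = select_offer(grid, cfg, rng)
        assert offer.delay_days in cfg.delays
        assert 0.30 <= offer.option_a_amount <= 10.0


def test_empty_menu_rejected():
    with pytest.raises(ValueError):
        TaskConfig(task_kind="delay", delays=())


# ---------------------------------------------------------------------------
# Sessions
# ---------------------------------------------------------------------------

def test_session_deterministic_replay():
    agent = AgentParams(log_k_delay=-2.0, beta=4.0)
    cfg = TaskConfig(task_kind="delay")
    a = run_session(agent, cfg, seed=42)
    b = run_session(agent, cfg, seed=42)
    assert a.choices == b.choices
    assert a.offers == b.offers
    assert a.posterior_mean == b.posterior_mean
    assert len(a.choices) == cfg.n_trials


def test_consistent_agent_recovers_parameter():
    agent = AgentParams(log_k_delay=-2.0, beta=8.0)
    errs = [
        abs(run_session(agent, TaskConfig(task_kind="delay"), seed=s).posterior_mean + 2.0)
        for s in range(10)
    ]
    assert np.median(errs) < 0.5


def test_mixed_gamble_recovers_log_lambda():
    agent = AgentParams(log_lambda=math.log(1.5), beta=8.0)
    errs = [
        abs(
            run_session(agent, TaskConfig(task_kind="mixed_gamble"), seed=s).posterior_mean
            - math.log(1.5)
        )
        for s in range(10)
    ]
    assert np.median(errs) < 0.3


def test_noise_agent_stays_uncertain():
    """beta=0 choices are uninformative: wide posterior, estimate near prior."""
    prior_mean = PosteriorGrid.for_task("delay").posterior_mean()

    def final_sd(r):
        m = r.final_grid.param_marginal
        mu = m @ r.final_grid.param_axis
        return math.sqrt(m @ (r.final_grid.param_axis - mu) ** 2)

    noise = [run_session(AgentParams(beta=0.0), TaskConfig(task_kind="delay"), seed=s) for s in range(8)]
    sharp = [
        run_session(AgentParams(log_k_delay=-2.0, beta=8.0), TaskConfig(task_kind="delay"), seed=s)
        for s in range(8)
    ]
    assert np.mean([abs(r.posterior_mean - prior_mean) for r in noise]) < 2.5
    assert np.mean([final_sd(r) for r in noise]) > np.mean([final_sd(r) for r in sharp])


def test_choice_log_schema():
    r = run_session(AgentParams(), TaskConfig(task_kind="prob_loss"), seed=3)
    df = choices_to_frame(r)
    assert list(df.columns) == [
        "trial", "task", "option_a_amount", "option_b_amount", "delay_days",
        "probability", "gain", "loss", "choice", "seed",
    ]
    assert len(df) == 30
    assert set(df["choice"]) <= {"a", "b"}
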