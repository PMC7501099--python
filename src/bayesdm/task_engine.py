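"""Adaptive Bayesian battery for value-based decision-making.

Four two-alternative forced-choice tasks measure distinct facets of
impulsive decision-making:

* ``delay`` — delay discounting: a smaller-sooner amount against a fixed
  larger amount delivered after a delay drawn from a fixed menu of days.
* ``prob_gain`` — probability discounting for gains: a smaller certain
  gain against a fixed probabilistic gain.
* ``prob_loss`` — probability discounting for losses: a smaller certain
  loss against a fixed probabilistic (larger) loss.
* ``mixed_gamble`` — 50/50 mixed gambles: accept or reject a gamble with
  a gain and a loss; loss aversion lambda weights losses against gains.

Delayed and probabilistic outcomes are valued with the hyperbolic
discounting model V = A / (1 + k*D), applied to probabilities through the
odds against winning theta = (1 - p) / p.  Mixed gambles use the linear
utility U = 0.5*gain - 0.5*lambda*loss.  Choices follow a logistic
(softmax) rule with an inverse temperature beta per task.

Estimation is sequential: a discrete joint posterior over (log parameter,
log beta) is updated after every trial, and the next offer is placed at
the indifference point implied by the current posterior mean, which keeps
trials maximally informative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

TaskKind = Literal["delay", "prob_gain", "prob_loss", "mixed_gamble"]

TASK_KINDS: tuple[str, ...] = ("delay", "prob_gain", "prob_loss", "mixed_gamble")

#: Delay menu in days.
DELAYS: tuple[int, ...] = (3, 7, 14, 31, 61, 180, 365)

#: Probability menu.
PROBABILITIES: tuple[float, ...] = (2 / 3, 1 / 2, 1 / 3, 1 / 4, 1 / 5)

#: Discrete grid defaults: log k, log lambda and log beta axes.
LOG_K_AXIS = np.linspace(-7.0, 2.0, 41)
LOG_LAMBDA_AXIS = np.linspace(-2.0, 2.0, 41)
LOG_BETA_AXIS = np.linspace(-3.0, 2.0, 11)


class RenormalizationError(RuntimeError):
    """Raised when a trial's likelihood annihilates the posterior mass."""


@dataclass(frozen=True)
class TaskConfig:
    """Configuration of one task of the battery.

    Defaults follow the battery's standard protocol: 30 trials for the
    discounting tasks and 40 for mixed gambles; amounts between 0.30 and
    10 euro for discounting, gains 1-40 and losses 5-20 euro for gambles.
    """

    task_kind: TaskKind
    n_trials: int | None = None
    amount_range: tuple[float, float] = (0.30, 10.00)
    delays: tuple[int, ...] = DELAYS
    probabilities: tuple[float, ...] = PROBABILITIES
    gamble_gain_range: tuple[float, float] = (1.0, 40.0)
    gamble_loss_range: tuple[float, float] = (5.0, 20.0)
    gamble_loss_step: float = 0.5
    endowment: float = 10.0  # bookkeeping only, no utility carryover
    fixed_amount: float = 10.0  # the non-adjusted delayed/probabilistic amount

    def __post_init__(self) -> None:
        if self.task_kind not in TASK_KINDS:
            raise ValueError(f"unknown task kind {self.task_kind!r}")
        if self.n_trials is None:
            object.__setattr__(
                self, "n_trials", 40 if self.task_kind == "mixed_gamble" else 30
            )
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        for lo, hi in (self.amount_range, self.gamble_gain_range, self.gamble_loss_range):
            if not lo < hi:
                raise ValueError("ranges must be ordered (lo < hi)")
        if self.task_kind == "delay" and not self.delays:
            raise ValueError("delay menu must be non-empty")
        if self.task_kind.startswith("prob") and not self.probabilities:
            raise ValueError("probability menu must be non-empty")

    @property
    def param_axis(self) -> np.ndarray:
        return LOG_LAMBDA_AXIS if self.task_kind == "mixed_gamble" else LOG_K_AXIS


@dataclass(frozen=True)
class TaskOffer:
    """A single two-option trial.

    For discounting tasks option A is the certain/sooner option and
    option B the delayed/probabilistic one (both negative in the loss
    task).  For mixed gambles option A is rejecting (status quo, value 0)
    and option B accepting the gamble.
    """

    option_a_amount: float = 0.0
    option_b_amount: float = 0.0
    delay_days: int | None = None
    probability: float | None = None
    gain: float | None = None
    loss: float | None = None
    sign: Literal["gain", "loss"] = "gain"


@dataclass(frozen=True)
class AgentParams:
    """True decision parameters of a simulated participant.

    ``beta`` is the inverse temperature of the logistic choice rule and
    may be one value for all tasks or a mapping per task kind.
    """

    log_k_delay: float = -3.0
    log_k_pgain: float = 0.0
    log_k_ploss: float = 0.0
    log_lambda: float = 0.3
    beta: float | Mapping[str, float] = 3.0

    def __post_init__(self) -> None:
        for name in ("log_k_delay", "log_k_pgain", "log_k_ploss", "log_lambda"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for b in self.betas().values():
            if b < 0:
                raise ValueError("beta must be >= 0")

    def betas(self) -> dict[str, float]:
        if isinstance(self.beta, Mapping):
            return {t: float(self.beta.get(t, 3.0)) for t in TASK_KINDS}
        return {t: float(self.beta) for t in TASK_KINDS}

    def log_param(self, task_kind: str) -> float:
        return {
            "delay": self.log_k_delay,
            "prob_gain": self.log_k_pgain,
            "prob_loss": self.log_k_ploss,
            "mixed_gamble": self.log_lambda,
        }[task_kind]


# ---------------------------------------------------------------------------
# Value functions and the choice rule
# ---------------------------------------------------------------------------

def subjective_value_delayed(amount, delay, k):
    """Hyperbolic subjective value of ``amount`` delivered after ``delay`` days.

    V = A / (1 + k*D).  Vectorized in ``k``.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("discount rate k must be >= 0")
    if delay < 0:
        raise ValueError("delay must be >= 0")
    if amount <= 0:
        raise ValueError("amount must be positive")
    out = amount / (1.0 + k * delay)
    return float(out) if out.ndim == 0 else out


def subjective_value_probabilistic(amount, p, k):
    """Hyperbolic value of ``amount`` with probability ``p``, via odds against.

    theta = (1-p)/p, V = A / (1 + k*theta).  Losses are passed as negative
    amounts and keep their sign.  Vectorized in ``k``.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("discount rate k must be >= 0")
    if not 0.0 < p <= 1.0:
        raise ValueError("probability must be in (0, 1]")
    if amount == 0:
        raise ValueError("amount must be non-zero")
    theta = (1.0 - p) / p
    out = amount / (1.0 + k * theta)
    return float(out) if out.ndim == 0 else out


def gamble_utility(gain, loss, lam):
    """Linear utility of a 50/50 mixed gamble: U = 0.5*gain - 0.5*lam*loss."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("loss aversion lambda must be > 0")
    if gain < 0 or loss < 0:
        raise ValueError("gain and loss magnitudes must be >= 0")
    out = 0.5 * gain - 0.5 * lam * loss
    return float(out) if out.ndim == 0 else out


def choice_probability(value_b, value_a, beta):
    """Logistic probability of choosing option B over A.

    P(B) = 1 / (1 + exp(-beta*(V_B - V_A))); 0.5 at indifference or beta=0.
    """
    value_b = np.asarray(value_b, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(beta < 0):
        raise ValueError("beta must be >= 0")
    if not (np.all(np.isfinite(value_b)) and np.all(np.isfinite(value_a))):
        raise ValueError("values must be finite")
    x = np.clip(beta * (value_b - value_a), -700.0, 700.0)
    out = 1.0 / (1.0 + np.exp(-x))
    return float(out) if out.ndim == 0 else out


def offer_values(offer: TaskOffer, task_kind: str, param):
    """Option values (V_A, V_B) under natural-scale parameter(s) ``param``.

    ``param`` is k for discounting tasks and lambda for mixed gambles; it
    may be an array, in which case V_B is vectorized over it.
    """
    if task_kind == "delay":
        return offer.option_a_amount, subjective_value_delayed(
            offer.option_b_amount, offer.delay_days, param
        )
    if task_kind == "prob_gain":
        return offer.option_a_amount, subjective_value_probabilistic(
            offer.option_b_amount, offer.probability, param
        )
    if task_kind == "prob_loss":
        return offer.option_a_amount, subjective_value_probabilistic(
            offer.option_b_amount, offer.probability, param
        )
    if task_kind == "mixed_gamble":
        return 0.0, gamble_utility(offer.gain, offer.loss, param)
    raise ValueError(f"unknown task kind {task_kind!r}")


# ---------------------------------------------------------------------------
# Posterior grid
# ---------------------------------------------------------------------------

@dataclass
class PosteriorGrid:
    """Discrete joint posterior over (log parameter, log beta).

    ``mass[i, j]`` is the probability of node (param_axis[i], beta_axis[j]).
    """

    param_axis: np.ndarray
    beta_axis: np.ndarray
    mass: np.ndarray

    @classmethod
    def uniform(cls, param_axis=LOG_K_AXIS, beta_axis=LOG_BETA_AXIS) -> "PosteriorGrid":
        param_axis = np.asarray(param_axis, dtype=float)
        beta_axis = np.asarray(beta_axis, dtype=float)
        mass = np.full((param_axis.size, beta_axis.size), 1.0 / (param_axis.size * beta_axis.size))
        return cls(param_axis, beta_axis, mass)

    @classmethod
    def for_task(cls, task_kind: str) -> "PosteriorGrid":
        axis = LOG_LAMBDA_AXIS if task_kind == "mixed_gamble" else LOG_K_AXIS
        return cls.uniform(axis, LOG_BETA_AXIS)

    def copy(self) -> "PosteriorGrid":
        return PosteriorGrid(self.param_axis, self.beta_axis, self.mass.copy())

    @property
    def param_marginal(self) -> np.ndarray:
        return self.mass.sum(axis=1)

    def posterior_mean(self) -> float:
        """Posterior mean of the log parameter (marginal over beta)."""
        return float(self.param_marginal @ self.param_axis)

    def map_estimate(self) -> float:
        """Log parameter of the highest-mass node; ties -> smallest value."""
        i, _ = np.unravel_index(int(np.argmax(self.mass)), self.mass.shape)
        return float(self.param_axis[i])


def bayes_update(
    grid: PosteriorGrid, offer: TaskOffer, choice: Literal["a", "b"], task_kind: str
) -> PosteriorGrid:
    """One sequential Bayes step: reweight grid nodes by the trial likelihood.

    Each node's likelihood is the logistic probability of the observed
    choice under that node's (parameter, beta); mass is renormalized to 1.
    """
    if choice not in ("a", "b"):
        raise ValueError("choice must be 'a' or 'b'")
    param = np.exp(grid.param_axis)  # (P,)
    beta = np.exp(grid.beta_axis)  # (B,)
    va, vb = offer_values(offer, task_kind, param)
    p_b = choice_probability(
        np.broadcast_to(np.asarray(vb, dtype=float).reshape(-1, 1), (param.size, beta.size)),
        np.asarray(va, dtype=float).reshape(-1, 1) if np.ndim(va) else va,
        beta.reshape(1, -1),
    )
    like = p_b if choice == "b" else 1.0 - p_b
    new_mass = grid.mass * like
    total = new_mass.sum()
    if not np.isfinite(total) or total <= 0.0:
        raise RenormalizationError(
            f"likelihood annihilated posterior mass (total={total!r}) for "
            f"offer {offer} / choice {choice!r}"
        )
    return PosteriorGrid(grid.param_axis, grid.beta_axis, new_mass / total)


# ---------------------------------------------------------------------------
# Adaptive offer construction
# ---------------------------------------------------------------------------

def _round_clip(x: float, lo: float, hi: float) -> float:
    return float(min(max(round(x, 2), lo), hi))


def select_offer(grid: PosteriorGrid, config: TaskConfig, rng: np.random.Generator) -> TaskOffer:
    """Construct the next offer at the current posterior-mean indifference point.

    The delay/probability (or gamble loss) is drawn uniformly from its
    menu; the adjustable amount is set so both options are value-equal
    under the posterior-mean parameter, rounded to 0.01 euro and clipped
    to the configured range.
    """
    param_hat = math.exp(grid.posterior_mean())
    lo, hi = config.amount_range
    kind = config.task_kind
    if kind == "delay":
        if not config.delays:
            raise ValueError("delay menu is empty")
        d = int(rng.choice(np.asarray(config.delays)))
        a = _round_clip(subjective_value_delayed(config.fixed_amount, d, param_hat), lo, hi)
        return TaskOffer(option_a_amount=a, option_b_amount=config.fixed_amount, delay_days=d)
    if kind in ("prob_gain", "prob_loss"):
        if not config.probabilities:
            raise ValueError("probability menu is empty")
        p = float(rng.choice(np.asarray(config.probabilities)))
        mag = _round_clip(
            abs(subjective_value_probabilistic(config.fixed_amount, p, param_hat)), lo, hi
        )
        if kind == "prob_gain":
            return TaskOffer(option_a_amount=mag, option_b_amount=config.fixed_amount, probability=p)
        return TaskOffer(
            option_a_amount=-mag,
            option_b_amount=-config.fixed_amount,
            probability=p,
            sign="loss",
        )
    if kind == "mixed_gamble":
        glo, ghi = config.gamble_loss_range
        lattice = np.arange(glo, ghi + 1e-9, config.gamble_loss_step)
        loss = float(rng.choice(lattice))
        gain = float(
            min(max(round(param_hat * loss, 2), config.gamble_gain_range[0]), config.gamble_gain_range[1])
        )
        return TaskOffer(gain=gain, loss=loss)
    raise ValueError(f"unknown task kind {kind!r}")


# ---------------------------------------------------------------------------
# Session simulation
# ---------------------------------------------------------------------------

@dataclass
class SessionResult:
    """Full record of one simulated task session."""

    task_kind: str
    offers: list[TaskOffer]
    choices: list[str]
    posterior_mean: float
    map_estimate: float
    final_grid: PosteriorGrid
    seed: int


def run_session(agent: AgentParams, config: TaskConfig, seed: int) -> SessionResult:
    """Simulate one adaptive session: offer -> agent choice -> grid update.

    The agent chooses stochastically via the logistic rule under its true
    parameters; the same seed yields a bit-identical session.
    """
    rng = np.random.default_rng(seed)
    grid = PosteriorGrid.for_task(config.task_kind)
    true_param = math.exp(agent.log_param(config.task_kind))
    beta = agent.betas()[config.task_kind]
    offers: list[TaskOffer] = []
    choices: list[str] = []
    for _ in range(config.n_trials):
        offer = select_offer(grid, config, rng)
        va, vb = offer_values(offer, config.task_kind, true_param)
        p_b = choice_probability(vb, va, beta)
        choice = "b" if rng.random() < p_b else "a"
        grid = bayes_update(grid, offer, choice, config.task_kind)
        offers.append(offer)
        choices.append(choice)
    return SessionResult(
        task_kind=config.task_kind,
        offers=offers,
        choices=choices,
        posterior_mean=grid.posterior_mean(),
        map_estimate=grid.map_estimate(),
        final_grid=grid,
        seed=seed,
    )


def run_battery(agent: AgentParams, seed: int) -> dict[str, SessionResult]:
    """Run all four tasks with per-task seeds derived from ``seed``."""
    out = {}
    for i, kind in enumerate(TASK_KINDS):
        out[kind] = run_session(agent, TaskConfig(task_kind=kind), seed=seed * 7919 % (2**31) + i)
    return out


def _choice_rows(result: SessionResult) -> list[dict]:
    rows = []
    for t, (offer, choice) in enumerate(zip(result.offers, result.choices), start=1):
        rows.append(
            {
                "trial": t,
                "task": result.task_kind,
                "option_a_amount": offer.option_a_amount,
                "option_b_amount": offer.option_b_amount,
                "delay_days": offer.delay_days,
                "probability": offer.probability,
                "gain": offer.gain,
                "loss": offer.loss,
                "choice": choice,
                "seed": result.seed,
            }
        )
    return rows


def choices_to_frame(result: SessionResult) -> pd.DataFrame:
    """Choice log as a tidy frame (the on-disk CSV schema)."""
    return pd.DataFrame(_choice_rows(result))


def write_choice_log(results: Iterable[SessionResult], path) -> None:
    rows = [row for r in results for row in _choice_rows(r)]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_choice_log(path) -> pd.DataFrame:
    return pd.read_csv(path)
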