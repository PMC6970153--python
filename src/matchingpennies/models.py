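"""Behavioral choice models: WRM, RL and QRE, with ML fitting and AIC.

WRM (winning-rate maximization) and RL are delta-rule value learners that
differ only in how the trial outcome is recoded into a reward signal:

* WRM: r = 1 on a win, 0 on a loss, regardless of the money involved.
* RL:  r = the monetary outcome rescaled onto [0, 1] — 1 for a HIGH win,
  1/3 for a LOW win (20/60), 0 for a loss — so that the softmax sensitivity
  beta is on the same scale for both models.

QRE (quantal response equilibrium) has no learning: the choice probability
is a logit response to the expected values of HIGH and LOW computed from the
opponent's empirical HIGH rate and the payoff matrix, so its only free
parameter is beta.

Log-likelihoods are accumulated trial by trial with values updated on the
*observed* choice; fitting is seeded multi-start quasi-Newton (L-BFGS-B)
under box bounds, and models are compared by AIC = 2k + 2 NLL.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .game import Choice, PayoffMatrix, DEFAULT_PAYOFF, TrialRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ModelKind",
    "LearnerParams",
    "ValueState",
    "FitConfig",
    "FitResult",
    "reward_recode",
    "update_values",
    "choice_prob",
    "qre_expected_values",
    "negative_log_likelihood",
    "fit_model",
    "aic",
    "posterior_predictive_match_rate",
    "model_comparison_table",
    "ValueLearnerAgent",
    "QreAgent",
]

LOG2 = math.log(2.0)


class ModelKind(str, Enum):
    WRM = "WRM"
    RL = "RL"
    QRE = "QRE"


def n_free_params(model: ModelKind) -> int:
    return 1 if model is ModelKind.QRE else 2


@dataclass(frozen=True)
class LearnerParams:
    """(alpha, beta) of a choice model; alpha is None for QRE."""

    alpha: float | None
    beta: float

    def __post_init__(self) -> None:
        if self.alpha is not None and not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.beta < 0.0:
            raise ValueError("beta must be non-negative")


@dataclass
class ValueState:
    """Learned subjective values of the two options."""

    v_high: float = 0.5
    v_low: float = 0.5


@dataclass(frozen=True)
class FitConfig:
    n_starts: int = 10
    seed: int = 0
    beta_max: float = 50.0
    tol: float = 1e-6
    v_init: float = 0.5
    payoff: PayoffMatrix = DEFAULT_PAYOFF


@dataclass
class FitResult:
    model: ModelKind
    params: LearnerParams
    nll: float
    aic: float
    n_trials: int
    n_starts: int
    converged: bool


def reward_recode(model: ModelKind, win: bool, choice: Choice) -> float:
    """Recode a trial outcome into the model's reward signal on [0, 1]."""
    if model is ModelKind.QRE:
        raise ValueError("QRE has no reward recoding (no learning)")
    if not win:
        return 0.0
    if model is ModelKind.WRM:
        return 1.0
    return 1.0 if choice is Choice.HIGH else 1.0 / 3.0


def update_values(
    state: ValueState, choice: Choice, r: float, alpha: float
) -> ValueState:
    """Delta-rule update: the chosen option's value moves toward r by alpha."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if choice is Choice.HIGH:
        return ValueState(state.v_high + alpha * (r - state.v_high), state.v_low)
    return ValueState(state.v_high, state.v_low + alpha * (r - state.v_low))


def choice_prob(v_high: float, v_low: float, beta: float) -> float:
    """Softmax (logistic) probability of choosing HIGH."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    z = beta * (v_high - v_low)
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-min(z, 700.0)))
    ez = math.exp(max(z, -700.0))
    return ez / (1.0 + ez)


def qre_expected_values(
    opponent_p_high: float, payoff: PayoffMatrix
) -> tuple[float, float]:
    """Expected values of HIGH and LOW against an opponent's empirical HIGH rate.

    The participant wins on a match, so EV(HIGH) = p_win_high * q and
    EV(LOW) = p_win_low * (1 - q). At the equilibrium rate q = 1/4 under the
    default payoffs both equal 15 JPY, which makes beta unidentifiable.
    """
    if not 0.0 <= opponent_p_high <= 1.0:
        raise ValueError("opponent_p_high must be a probability")
    return (
        payoff.p_win_high * opponent_p_high,
        payoff.p_win_low * (1.0 - opponent_p_high),
    )


def _empirical_opponent_p_high(trials: Sequence[TrialRecord]) -> float:
    return sum(t.opponent_choice is Choice.HIGH for t in trials) / len(trials)


def negative_log_likelihood(
    model: ModelKind,
    params: LearnerParams,
    trials: Sequence[TrialRecord],
    payoff: PayoffMatrix = DEFAULT_PAYOFF,
    v_init: float = 0.5,
) -> float:
    """NLL of the observed choice sequence under one model.

    WRM/RL: values start at ``v_init`` for both options and are updated after
    every trial using the observed choice and recoded reward (the first trial
    is included in the likelihood). QRE: a single constant choice probability
    from the opponent's empirical HIGH rate over the whole sequence.
    """
    if len(trials) == 0:
        raise ValueError("cannot compute a likelihood for an empty trial list")
    EPS = 1e-12
    if model is ModelKind.QRE:
        q = _empirical_opponent_p_high(trials)
        ev_h, ev_l = qre_expected_values(q, payoff)
        p_high = choice_prob(ev_h, ev_l, params.beta)
        n_high = sum(t.participant_choice is Choice.HIGH for t in trials)
        n_low = len(trials) - n_high
        return -(
            n_high * math.log(max(p_high, EPS))
            + n_low * math.log(max(1.0 - p_high, EPS))
        )

    if params.alpha is None:
        raise ValueError(f"{model.value} requires alpha")
    alpha, beta = params.alpha, params.beta
    vh = vl = v_init
    nll = 0.0
    for t in trials:
        z = beta * (vh - vl)
        # log P(observed choice) via the stable log-sigmoid
        if t.participant_choice is Choice.HIGH:
            nll += math.log1p(math.exp(-z)) if z > -700 else -z
        else:
            nll += math.log1p(math.exp(z)) if z < 700 else z
        r = reward_recode(model, t.win, t.participant_choice)
        if t.participant_choice is Choice.HIGH:
            vh += alpha * (r - vh)
        else:
            vl += alpha * (r - vl)
    return nll


def aic(nll: float, model: ModelKind) -> float:
    """Akaike information criterion, 2k + 2 NLL (k = 2 for WRM/RL, 1 for QRE)."""
    return 2.0 * n_free_params(model) + 2.0 * nll


def fit_model(
    model: ModelKind,
    trials: Sequence[TrialRecord],
    config: FitConfig = FitConfig(),
) -> FitResult:
    """Maximum-likelihood fit by seeded multi-start L-BFGS-B under box bounds.

    alpha is bounded to [0, 1] and beta to [0, beta_max]; the best of
    ``n_starts`` runs is returned. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    k = n_free_params(model)
    if k == 2:
        bounds = [(0.0, 1.0), (0.0, config.beta_max)]
        starts = [np.array([0.5, 1.0])]
    else:
        bounds = [(0.0, config.beta_max)]
        starts = [np.array([1.0])]
    for _ in range(config.n_starts - 1):
        starts.append(
            np.array([rng.uniform(lo, hi if hi < 10 else 10.0) for lo, hi in bounds])
        )

    def objective(theta: np.ndarray) -> float:
        if k == 2:
            params = LearnerParams(alpha=float(theta[0]), beta=float(theta[1]))
        else:
            params = LearnerParams(alpha=None, beta=float(theta[0]))
        return negative_log_likelihood(
            model, params, trials, payoff=config.payoff, v_init=config.v_init
        )

    best = None
    any_converged = False
    failures = []
    for x0 in starts:
        try:
            res = minimize(
                objective,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": config.tol, "gtol": 1e-8},
            )
        except (ValueError, FloatingPointError) as exc:  # pragma: no cover
            failures.append(str(exc))
            continue
        if best is None or res.fun < best.fun:
            best = res
        any_converged = any_converged or bool(res.success)
    if best is None:
        raise RuntimeError(
            f"all {config.n_starts} optimizer starts failed for {model.value}: "
            f"{failures}"
        )
    theta = best.x
    if k == 2:
        params = LearnerParams(alpha=float(theta[0]), beta=float(theta[1]))
    else:
        params = LearnerParams(alpha=None, beta=float(theta[0]))
    if params.beta >= config.beta_max - 1e-9:
        logger.warning(
            "%s fit hit the beta upper bound (%.1f); choices may be near-deterministic",
            model.value,
            config.beta_max,
        )
    nll = float(best.fun)
    return FitResult(
        model=model,
        params=params,
        nll=nll,
        aic=aic(nll, model),
        n_trials=len(trials),
        n_starts=config.n_starts,
        converged=any_converged,
    )


def posterior_predictive_match_rate(
    fit: FitResult,
    trials: Sequence[TrialRecord],
    reps: int,
    rng: np.random.Generator,
    payoff: PayoffMatrix = DEFAULT_PAYOFF,
    v_init: float = 0.5,
) -> float:
    """Fraction of observed choices reproduced by simulating from the fitted model.

    The model is run forward on the observed history (values updated with the
    observed choice and reward), a choice is drawn from its predicted
    probability at every trial, and the match rate is averaged over ``reps``
    simulated passes. Chance level is 0.5.
    """
    if reps <= 0:
        raise ValueError("reps must be positive")
    n = len(trials)
    if n == 0:
        raise ValueError("no trials")
    p = np.empty(n)
    if fit.model is ModelKind.QRE:
        q = _empirical_opponent_p_high(trials)
        ev_h, ev_l = qre_expected_values(q, payoff)
        p[:] = choice_prob(ev_h, ev_l, fit.params.beta)
    else:
        vh = vl = v_init
        for i, t in enumerate(trials):
            p[i] = choice_prob(vh, vl, fit.params.beta)
            r = reward_recode(fit.model, t.win, t.participant_choice)
            if t.participant_choice is Choice.HIGH:
                vh += fit.params.alpha * (r - vh)
            else:
                vl += fit.params.alpha * (r - vl)
    observed_high = np.array([t.participant_choice is Choice.HIGH for t in trials])
    draws = rng.random((reps, n)) < p  # simulated HIGH choices
    return float((draws == observed_high).mean())


def model_comparison_table(
    fits: Mapping[tuple[str, str, ModelKind], FitResult],
) -> pd.DataFrame:
    """Mean AIC per (condition, model) across participants, best model flagged.

    ``fits`` maps (participant, condition, model) to a FitResult; every
    participant must have all three models fit in every condition present.
    Returns a DataFrame with conditions as rows, one column per model, plus a
    ``best`` column naming the lowest-AIC model of each row.
    """
    participants = sorted({k[0] for k in fits})
    conditions = sorted({k[1] for k in fits})
    missing = [
        (p, c, m.value)
        for p in participants
        for c in conditions
        for m in ModelKind
        if (p, c, m) not in fits
    ]
    if missing:
        raise ValueError(f"missing fits for cells: {missing}")
    rows = {}
    for c in conditions:
        rows[c] = {
            m.value: float(np.mean([fits[(p, c, m)].aic for p in participants]))
            for m in ModelKind
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "condition"
    table["best"] = table[[m.value for m in ModelKind]].idxmin(axis=1)
    return table


class ValueLearnerAgent:
    """Generative WRM or RL agent usable as participant or opponent.

    In the opponent role it wins on a mismatch; WRM reward recoding (1 on own
    win, 0 otherwise) applies from its own perspective, which is how a human
    opponent's play is proxied in the synthetic cohort.
    """

    def __init__(
        self,
        model: ModelKind,
        alpha: float,
        beta: float,
        v_init: float = 0.5,
    ):
        if model is ModelKind.QRE:
            raise ValueError("use QreAgent for QRE")
        self.model = model
        self.alpha = alpha
        self.beta = beta
        self.state = ValueState(v_init, v_init)

    def choose(self, rng: np.random.Generator) -> Choice:
        p_high = choice_prob(self.state.v_high, self.state.v_low, self.beta)
        return Choice.HIGH if rng.random() < p_high else Choice.LOW

    def observe(
        self, own_choice: Choice, other_choice: Choice, own_won: bool, own_reward: float
    ) -> None:
        r = reward_recode(self.model, own_won, own_choice)
        self.state = update_values(self.state, own_choice, r, self.alpha)


class QreAgent:
    """Generative QRE agent: constant logit response to fixed expected values."""

    def __init__(
        self,
        beta: float,
        opponent_p_high: float,
        payoff: PayoffMatrix = DEFAULT_PAYOFF,
    ):
        ev_h, ev_l = qre_expected_values(opponent_p_high, payoff)
        self.p_high = choice_prob(ev_h, ev_l, beta)

    def choose(self, rng: np.random.Generator) -> Choice:
        return Choice.HIGH if rng.random() < self.p_high else Choice.LOW

    def observe(self, own_choice, other_choice, own_won, own_reward) -> None:
        pass
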