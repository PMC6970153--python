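"""Simulation studies validating the pipeline end to end.

These are the package's built-in checks that the machinery behaves as the
underlying theory predicts: the perceptron opponent exploits biased play at
the probability-matching asymptote, maximum-likelihood fitting recovers
generating parameters, model comparison recovers the generating model, and
the pattern-similarity contrast is calibrated under the null and powered
under the planted alternative. Each study is seeded and returns plain
numbers, so the same functions back both the test suite and the
reproduction script.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

from .agents import (
    HISTORY_LEN,
    N_FEATURES,
    FixAgent,
    LrnAgent,
    LrnState,
    ScriptedAgent,
    lrn_update,
    play_block,
    squared_error,
)
from .game import Choice, DEFAULT_PAYOFF, OpponentType, PayoffMatrix, ScheduleSpec
from .models import FitConfig, ModelKind, ValueLearnerAgent, fit_model
from .rsa import similarity_contrast
from .synth import BetaPatternSpec, generate_roi_betas, simulate_participant

__all__ = [
    "lrn_gradient_check",
    "lrn_exploitation_study",
    "alpha_recovery_study",
    "model_recovery_study",
    "rsa_rejection_rate",
]

_CONDS = ("HUM", "FIX", "LRN")


def lrn_gradient_check(n_states: int = 1000, seed: int = 0, h: float = 1e-6) -> float:
    """Max relative error between the analytic weight step and a central
    finite difference of the scaled squared error, over random states.

    The full 19-element step is compared in vector norm with a mixed
    tolerance: the reported statistic is
    ``||analytic - fd|| / (||fd|| + 5e-10 / 1e-5)``, so a value below rtol
    means ``||analytic - fd|| <= rtol * ||fd|| + 5e-10``. The 5e-10 absolute
    floor is the roundoff noise of a central difference at step 1e-6
    (eps / h times the error scale); on saturated-sigmoid states the true
    gradient falls below that floor and a bare ratio would only measure FD
    noise. Returns the worst mixed-tolerance discrepancy observed.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_states):
        n_hist = int(rng.integers(0, HISTORY_LEN + 1))
        hist = deque(
            [
                (
                    Choice.HIGH if rng.random() < 0.5 else Choice.LOW,
                    Choice.HIGH if rng.random() < 0.5 else Choice.LOW,
                    bool(rng.random() < 0.5),
                )
                for _ in range(n_hist)
            ],
            maxlen=HISTORY_LEN,
        )
        w = rng.normal(0, 2, N_FEATURES)
        a = 0.25
        target = Choice.LOW if rng.random() < 0.5 else Choice.HIGH
        state = LrnState(w=w.copy(), history=hist, a=a)
        delta = lrn_update(state, target).w - w
        fd_step = np.zeros(N_FEATURES)
        for i in range(N_FEATURES):
            wp, wm = w.copy(), w.copy()
            wp[i] += h
            wm[i] -= h
            fd = (
                squared_error(LrnState(w=wp, history=hist, a=a), target)
                - squared_error(LrnState(w=wm, history=hist, a=a), target)
            ) / (2 * h)
            fd_step[i] = -a * fd
        denom = float(np.linalg.norm(fd_step)) + 5e-10 / 1e-5
        worst = max(worst, float(np.linalg.norm(delta - fd_step)) / denom)
    return worst


def lrn_exploitation_study(
    n_seeds: int = 20,
    n_trials: int = 2000,
    tail: int = 500,
    opponent_bias: float = 0.8,
    payoff: PayoffMatrix = DEFAULT_PAYOFF,
    seed: int = 0,
) -> float:
    """Mean LRN win rate over the final trials against a constant-bias player.

    Probability matching predicts an asymptotic win rate of
    ``p^2 + (1-p)^2`` against a player choosing HIGH with probability p
    (0.68 at p = 0.8): LRN's HIGH rate converges to the player's LOW rate.
    """
    rates = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        recs = play_block(
            LrnAgent(), ScriptedAgent(opponent_bias), n_trials, payoff, rng
        )
        rates.append(np.mean([not r.win for r in recs[-tail:]]))
    return float(np.mean(rates))


def alpha_recovery_study(
    n_participants: int = 50,
    beta: float = 5.0,
    alpha_range: tuple[float, float] = (0.2, 0.5),
    schedule: ScheduleSpec = ScheduleSpec(),
    payoff: PayoffMatrix = DEFAULT_PAYOFF,
    seed: int = 0,
) -> dict:
    """Learning-rate recovery for WRM learners playing the full schedule.

    Each synthetic participant has one true learning rate drawn uniformly
    from ``alpha_range`` and plays 48 trials against each opponent; the WRM
    model is fit per condition and the participant-level estimate is the
    mean of the three condition fits. Returns the Pearson correlation of
    true vs fitted alpha and the median absolute error.
    """
    rng = np.random.default_rng(seed)
    true_a, fit_a = [], []
    for i in range(n_participants):
        a = float(rng.uniform(*alpha_range))
        session = simulate_participant(
            f"sim-{i:03d}",
            {c: a for c in _CONDS},
            {c: beta for c in _CONDS},
            schedule,
            payoff,
            seed=int(rng.integers(2**31 - 1)),
        )
        fits = [
            fit_model(
                ModelKind.WRM, session.trials_for(o), FitConfig(seed=3 * i + k)
            ).params.alpha
            for k, o in enumerate(OpponentType)
        ]
        true_a.append(a)
        fit_a.append(float(np.mean(fits)))
    true_arr, fit_arr = np.array(true_a), np.array(fit_a)
    return {
        "correlation": float(np.corrcoef(true_arr, fit_arr)[0, 1]),
        "median_abs_error": float(np.median(np.abs(true_arr - fit_arr))),
        "true_alpha": true_arr,
        "fitted_alpha": fit_arr,
    }


def model_recovery_study(
    generator: ModelKind,
    n_replicates: int = 25,
    n_participants: int = 8,
    trials_per_condition: int = 48,
    beta: float = 5.0,
    payoff: PayoffMatrix = DEFAULT_PAYOFF,
    seed: int = 0,
) -> float:
    """Fraction of replicate cohorts where the generating model wins on AIC.

    Each replicate simulates a cohort of delta-rule learners of the given
    kind playing against all three opponents, fits all three models to every
    participant x condition cell, and checks whether the generator has the
    lowest mean AIC.
    """
    if generator is ModelKind.QRE:
        raise ValueError("recovery cohorts are generated by the delta-rule models")
    hits = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed + 7919 * rep)
        aics = {m: [] for m in ModelKind}
        for i in range(n_participants):
            a = float(np.clip(rng.normal(0.35, 0.10), 0.05, 0.9))
            opponents = {
                "FIX": FixAgent(0.25),
                "LRN": LrnAgent(),
                "HUM": ValueLearnerAgent(ModelKind.WRM, 0.26, 5.0),
            }
            for cond, opp in opponents.items():
                part = ValueLearnerAgent(generator, a, beta)
                recs = play_block(opp, part, trials_per_condition, payoff, rng)
                for m in ModelKind:
                    aics[m].append(
                        fit_model(m, recs, FitConfig(seed=seed + rep * 100 + i)).aic
                    )
        means = {m: float(np.mean(v)) for m, v in aics.items()}
        if min(means, key=means.get) is generator:
            hits += 1
    return hits / n_replicates


def rsa_rejection_rate(
    lambda_shared: float,
    n_replicates: int,
    n_participants: int = 30,
    n_voxels: int = 200,
    sigma_choice: float = 0.5,
    sigma_noise: float = 1.0,
    alpha_level: float = 0.05,
    directional: bool = False,
    seed: int = 0,
) -> float:
    """Rejection rate of the paired Fisher-z contrast over replicate cohorts.

    With ``lambda_shared = 0`` this estimates the type-I error (nominal
    ``alpha_level``); with a positive loading and ``directional=True`` it
    estimates power for the planted HUM-LRN > HUM-FIX similarity.
    """
    rejections = 0
    for rep in range(n_replicates):
        spec = BetaPatternSpec(
            n_voxels=n_voxels,
            lambda_shared=lambda_shared,
            sigma_choice=sigma_choice,
            sigma_noise=sigma_noise,
            seed=seed + rep,
        )
        betas = generate_roi_betas(spec, n_participants)
        _, group = similarity_contrast(betas)
        if group.p < alpha_level and (not directional or group.mean_diff > 0):
            rejections += 1
    return rejections / n_replicates
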