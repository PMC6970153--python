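"""Synthetic study data: simulated behavioral cohorts and ROI activation patterns.

No behavioral or imaging data from the original competition experiment is
publicly deposited, so this module generates both inputs that the analysis
pipeline consumes:

* **Behavioral sessions.** Each synthetic participant is a WRM (winning-rate
  maximization) softmax learner playing the full 4-run x 3-block x 12-trial
  schedule against the three opponents: FIX at the Nash rate, the LRN
  perceptron, and a human proxy — an independent WRM learner playing the
  opponent role (it wins on mismatches) with a learning rate matching the
  value fitted to real human opponents (0.26).

* **ROI beta patterns.** Per participant, a 6 x n_voxels matrix of condition
  patterns — choice (high/low) x opponent (HUM/FIX/LRN) — built from an
  opponent-specific voxel component, an optional component *shared between
  HUM and LRN only* (loading ``lambda_shared``), a choice component, and
  Gaussian noise. ``lambda_shared = 0`` makes the three opponents
  exchangeable, the null of the downstream similarity contrast;
  ``lambda_shared > 0`` plants the HUM-LRN > HUM-FIX similarity structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agents import FixAgent, LrnAgent, play_block
from .game import (
    DEFAULT_PAYOFF,
    Choice,
    OpponentType,
    PayoffMatrix,
    ScheduleSpec,
    Session,
    block_order,
    make_schedule,
    nash_mixed_strategy,
)
from .models import ModelKind, ValueLearnerAgent

__all__ = [
    "CONDITION_ORDER",
    "CohortSpec",
    "BetaPatternSpec",
    "RoiBetas",
    "simulate_participant",
    "simulate_cohort",
    "generate_roi_betas",
]

#: fixed row order of every 6 x n_voxels beta-pattern matrix
CONDITION_ORDER = (
    "HUM-high",
    "HUM-low",
    "FIX-high",
    "FIX-low",
    "LRN-high",
    "LRN-low",
)

_CONDITIONS = tuple(o.value for o in OpponentType)


def _default_alpha_mean() -> dict[str, float]:
    return {"HUM": 0.34, "FIX": 0.34, "LRN": 0.40}


def _default_alpha_sd() -> dict[str, float]:
    return {"HUM": 0.15, "FIX": 0.15, "LRN": 0.15}


@dataclass
class CohortSpec:
    """Population the synthetic cohort is drawn from.

    Per-condition learning-rate means follow the fitted participant values
    (0.34 against HUM and FIX, 0.40 against LRN); the human proxy's learning
    rate defaults to the value fitted to real human opponents (0.26). The
    softmax sensitivity beta has no reported population account, so its
    distribution is chosen for healthy identifiability at 48 trials per
    condition.
    """

    n_participants: int = 30
    alpha_mean: dict[str, float] = field(default_factory=_default_alpha_mean)
    alpha_sd: dict[str, float] = field(default_factory=_default_alpha_sd)
    beta_mean: float = 5.0
    beta_sd: float = 1.5
    hum_proxy_alpha: float = 0.26
    hum_proxy_beta: float = 5.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if any(sd < 0 for sd in self.alpha_sd.values()) or self.beta_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        for cond in _CONDITIONS:
            if cond not in self.alpha_mean or cond not in self.alpha_sd:
                raise ValueError(f"alpha_mean/alpha_sd must cover condition {cond}")


@dataclass(frozen=True)
class BetaPatternSpec:
    """Generative recipe for synthetic condition x voxel activation patterns."""

    n_voxels: int = 200
    lambda_shared: float = 1.0
    sigma_choice: float = 0.5
    sigma_noise: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_voxels < 10:
            raise ValueError("n_voxels must be at least 10")
        if min(self.lambda_shared, self.sigma_choice, self.sigma_noise) < 0:
            raise ValueError("scales must be non-negative")


@dataclass
class RoiBetas:
    """One participant's 6 x n_voxels condition patterns in CONDITION_ORDER."""

    participant_id: str
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(CONDITION_ORDER):
            raise ValueError(
                f"data must be {len(CONDITION_ORDER)} x n_voxels, got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("beta patterns must be finite")

    def pattern(self, condition: str) -> np.ndarray:
        return self.data[CONDITION_ORDER.index(condition)]


def simulate_participant(
    participant_id: str,
    alphas: dict[str, float],
    betas: dict[str, float],
    schedule: ScheduleSpec,
    payoff: PayoffMatrix,
    seed: int,
    hum_proxy_alpha: float = 0.26,
    hum_proxy_beta: float = 5.0,
) -> Session:
    """Simulate one participant's full session against all three opponents.

    The participant is a WRM learner with condition-specific (alpha, beta);
    its value state, the LRN perceptron's weights/history, and the human
    proxy's values all persist across blocks and runs, mirroring continuous
    learning through the experiment.
    """
    rng = np.random.default_rng(seed)
    skeleton = make_schedule(
        ScheduleSpec(
            schedule.n_runs,
            schedule.blocks_per_run,
            schedule.trials_per_block,
            counterbalance_seed=seed,
        )
    )
    orders = block_order(skeleton)

    _, fix_rate = nash_mixed_strategy(payoff)
    participants = {
        cond: ValueLearnerAgent(ModelKind.WRM, alphas[cond], betas[cond])
        for cond in _CONDITIONS
    }
    opponents = {
        OpponentType.FIX: FixAgent(fix_rate),
        OpponentType.LRN: LrnAgent(),
        OpponentType.HUM: ValueLearnerAgent(
            ModelKind.WRM, hum_proxy_alpha, hum_proxy_beta
        ),
    }

    trials = []
    idx = 0
    for run, order in enumerate(orders, start=1):
        for block, opp in enumerate(order, start=1):
            trials.extend(
                play_block(
                    opponents[opp],
                    participants[opp.value],
                    schedule.trials_per_block,
                    payoff,
                    rng,
                    opponent_type=opp,
                    run=run,
                    block=block,
                    start_index=idx,
                )
            )
            idx += schedule.trials_per_block
    session = Session(
        participant_id=participant_id, trials=trials, schedule=schedule, seed=seed
    )
    session.validate()
    return session


def simulate_cohort(
    spec: CohortSpec,
    schedule: ScheduleSpec = ScheduleSpec(),
    payoff: PayoffMatrix = DEFAULT_PAYOFF,
) -> tuple[list[Session], pd.DataFrame]:
    """Simulate a cohort; returns the sessions and the true-parameter table.

    Per-participant seeds are spawned from ``master_seed``; the truth table
    (participant, condition, true_alpha, true_beta) is what parameter-recovery
    analyses compare fitted values against.
    """
    root = np.random.default_rng(spec.master_seed)
    sessions: list[Session] = []
    truth_rows = []
    for i in range(spec.n_participants):
        pid = f"sub-{i + 1:03d}"
        seed = int(root.integers(2**31 - 1))
        prng = np.random.default_rng(seed)
        alphas = {
            c: float(
                np.clip(prng.normal(spec.alpha_mean[c], spec.alpha_sd[c]), 0.0, 1.0)
            )
            for c in _CONDITIONS
        }
        betas = {
            c: float(max(prng.normal(spec.beta_mean, spec.beta_sd), 0.0))
            for c in _CONDITIONS
        }
        sessions.append(
            simulate_participant(
                pid,
                alphas,
                betas,
                schedule,
                payoff,
                seed=seed,
                hum_proxy_alpha=spec.hum_proxy_alpha,
                hum_proxy_beta=spec.hum_proxy_beta,
            )
        )
        for c in _CONDITIONS:
            truth_rows.append(
                {
                    "participant": pid,
                    "condition": c,
                    "true_alpha": alphas[c],
                    "true_beta": betas[c],
                }
            )
    return sessions, pd.DataFrame(truth_rows)


def generate_roi_betas(
    spec: BetaPatternSpec, n_participants: int
) -> list[RoiBetas]:
    """Generate per-participant 6 x n_voxels beta patterns with planted structure.

    pattern(opponent, choice) = u_opponent
                              + lambda_shared * s   (HUM and LRN rows only)
                              + sigma_choice * c_choice
                              + sigma_noise * eps

    where u_opponent, s, c_choice and eps are independent standard-normal
    voxel vectors drawn fresh for each participant. The shared component s
    is what makes HUM and LRN patterns correlate above the HUM-FIX baseline.
    """
    if n_participants <= 0:
        raise ValueError("n_participants must be positive")
    rng = np.random.default_rng(spec.seed)
    out: list[RoiBetas] = []
    for i in range(n_participants):
        u = {o: rng.standard_normal(spec.n_voxels) for o in OpponentType}
        s = rng.standard_normal(spec.n_voxels)
        c = {ch: rng.standard_normal(spec.n_voxels) for ch in Choice}
        rows = []
        for cond in CONDITION_ORDER:
            opp_name, choice_name = cond.split("-")
            opp = OpponentType(opp_name)
            ch = Choice.HIGH if choice_name == "high" else Choice.LOW
            shared = spec.lambda_shared * s if opp is not OpponentType.FIX else 0.0
            rows.append(
                u[opp]
                + shared
                + spec.sigma_choice * c[ch]
                + spec.sigma_noise * rng.standard_normal(spec.n_voxels)
            )
        out.append(RoiBetas(participant_id=f"sub-{i + 1:03d}", data=np.vstack(rows)))
    return out
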