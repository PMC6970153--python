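"""Asymmetric matching-pennies game: payoffs, Nash solution, trials, schedule.

The game is a two-player hide-and-seek competition. The *participant* wins a
trial when both players pick the same option; the *opponent* wins on a
mismatch. One option (HIGH) pays the participant more than the other (LOW) on
a match, and the opponent's mismatch payoffs are likewise unequal, so the
unique mixed-strategy Nash equilibrium is not 50/50 — rational play is
distinguishable from random choice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Choice",
    "OpponentType",
    "PayoffMatrix",
    "DEFAULT_PAYOFF",
    "TrialRecord",
    "ScheduleSpec",
    "Session",
    "nash_mixed_strategy",
    "resolve_trial",
    "make_schedule",
]


class Choice(str, Enum):
    """The two options: HIGH pays the participant more on a match."""

    HIGH = "H"
    LOW = "L"

    @property
    def other(self) -> "Choice":
        return Choice.LOW if self is Choice.HIGH else Choice.HIGH


class OpponentType(str, Enum):
    """HUM = human (or simulated proxy), FIX = equilibrium mixer, LRN = perceptron learner."""

    HUM = "HUM"
    FIX = "FIX"
    LRN = "LRN"


@dataclass(frozen=True)
class PayoffMatrix:
    """Win payoffs (JPY) for both players; the loser of a trial gets 0.

    ``p_win_high``/``p_win_low``: participant's payoff on a HIGH/LOW match.
    ``o_win_after_p_high``/``o_win_after_p_low``: opponent's payoff on a
    mismatch, indexed by the *participant's* choice. Indexing the opponent's
    payoff by the participant's symbol is what makes the participant's
    equilibrium HIGH rate 1/3 under the default 60/20/40/20 matrix.
    """

    p_win_high: float = 60.0
    p_win_low: float = 20.0
    o_win_after_p_high: float = 40.0
    o_win_after_p_low: float = 20.0

    def __post_init__(self) -> None:
        vals = (
            self.p_win_high,
            self.p_win_low,
            self.o_win_after_p_high,
            self.o_win_after_p_low,
        )
        if any(v <= 0 for v in vals):
            raise ValueError(f"all payoffs must be strictly positive, got {vals}")
        if self.p_win_high < self.p_win_low:
            raise ValueError(
                "p_win_high must be >= p_win_low (HIGH is the better-paying match)"
            )


DEFAULT_PAYOFF = PayoffMatrix()


def nash_mixed_strategy(payoff: PayoffMatrix) -> tuple[float, float]:
    """Mixed-strategy Nash equilibrium of the asymmetric game.

    Returns ``(participant_p_high, opponent_p_high)``.

    The opponent's mixing rate q makes the participant indifferent:
    ``p_win_high * q = p_win_low * (1 - q)``.  The participant's rate p makes
    the opponent indifferent: ``o_win_after_p_high * p = o_win_after_p_low * (1 - p)``.
    Under the default 60/20/40/20 payoffs this gives (1/3, 1/4).
    """
    q = payoff.p_win_low / (payoff.p_win_high + payoff.p_win_low)
    p = payoff.o_win_after_p_low / (payoff.o_win_after_p_high + payoff.o_win_after_p_low)
    return p, q


def resolve_trial(
    participant_choice: Choice, opponent_choice: Choice, payoff: PayoffMatrix
) -> tuple[bool, float, float]:
    """Resolve one trial: ``(participant_won, participant_reward, opponent_reward)``.

    The participant wins on a match and is paid by their chosen option; the
    opponent wins on a mismatch and is paid according to the participant's
    chosen option. Exactly one side is paid.
    """
    if participant_choice == opponent_choice:
        reward = (
            payoff.p_win_high if participant_choice is Choice.HIGH else payoff.p_win_low
        )
        return True, reward, 0.0
    reward = (
        payoff.o_win_after_p_high
        if participant_choice is Choice.HIGH
        else payoff.o_win_after_p_low
    )
    return False, 0.0, reward


@dataclass
class TrialRecord:
    trial_index: int
    run: int
    block: int
    opponent: OpponentType
    participant_choice: Choice
    opponent_choice: Choice
    win: bool
    participant_reward: float
    opponent_reward: float

    def validate(self) -> None:
        if self.win != (self.participant_choice == self.opponent_choice):
            raise ValueError("win flag inconsistent with choices")
        paid = (self.participant_reward > 0, self.opponent_reward > 0)
        if paid != (self.win, not self.win):
            raise ValueError("exactly the winning side must receive a reward")


@dataclass(frozen=True)
class ScheduleSpec:
    """Experiment layout: runs x blocks x trials, one opponent per block."""

    n_runs: int = 4
    blocks_per_run: int = 3
    trials_per_block: int = 12
    counterbalance_seed: int = 0

    @property
    def total_trials(self) -> int:
        return self.n_runs * self.blocks_per_run * self.trials_per_block


@dataclass
class Session:
    """One participant's ordered trials plus the schedule they conform to."""

    participant_id: str
    trials: list[TrialRecord]
    schedule: ScheduleSpec
    seed: int = 0

    def validate(self) -> None:
        if len(self.trials) != self.schedule.total_trials:
            raise ValueError(
                f"expected {self.schedule.total_trials} trials, got {len(self.trials)}"
            )
        last = -1
        for t in self.trials:
            if t.trial_index <= last:
                raise ValueError("trial_index must be strictly increasing")
            last = t.trial_index
            t.validate()
        # block-contiguity: opponent constant within each (run, block) cell
        for (run, block), group in itertools.groupby(
            self.trials, key=lambda t: (t.run, t.block)
        ):
            opps = {t.opponent for t in group}
            if len(opps) != 1:
                raise ValueError(f"run {run} block {block} mixes opponents: {opps}")

    def trials_for(self, opponent: OpponentType) -> list[TrialRecord]:
        return [t for t in self.trials if t.opponent is opponent]


def make_schedule(spec: ScheduleSpec) -> Session:
    """Build a session skeleton: opponent block order only, no choices yet.

    Block order is counterbalanced by a seeded draw from the 6 permutations of
    the three opponent types, with successive runs cycling through a Latin
    square (each run still contains every opponent exactly once).
    """
    opponents = list(OpponentType)
    if spec.blocks_per_run != len(opponents):
        raise ValueError(
            f"blocks_per_run must equal the number of opponent types "
            f"({len(opponents)}), got {spec.blocks_per_run}"
        )
    perms = sorted(itertools.permutations(opponents), key=lambda p: [o.value for o in p])
    rng = np.random.default_rng(spec.counterbalance_seed)
    base = list(perms[rng.integers(len(perms))])

    trials: list[TrialRecord] = []
    idx = 0
    for run in range(1, spec.n_runs + 1):
        rot = (run - 1) % len(base)
        order = base[rot:] + base[:rot]
        for block, opp in enumerate(order, start=1):
            for _ in range(spec.trials_per_block):
                trials.append(
                    TrialRecord(
                        trial_index=idx,
                        run=run,
                        block=block,
                        opponent=opp,
                        participant_choice=Choice.HIGH,  # placeholder slot
                        opponent_choice=Choice.HIGH,
                        win=True,
                        participant_reward=1.0,
                        opponent_reward=0.0,
                    )
                )
                idx += 1
    return Session(
        participant_id="", trials=trials, schedule=spec, seed=spec.counterbalance_seed
    )


def block_order(session: Session) -> list[list[OpponentType]]:
    """Opponent order per run, one entry per block."""
    orders: list[list[OpponentType]] = []
    for run in range(1, session.schedule.n_runs + 1):
        seen: list[OpponentType] = []
        for t in session.trials:
            if t.run == run and (not seen or seen[-1] is not t.opponent):
                if t.opponent not in seen:
                    seen.append(t.opponent)
        orders.append(seen)
    return orders
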