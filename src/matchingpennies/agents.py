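"""Computer opponents: equilibrium mixer (FIX) and online perceptron learner (LRN).

LRN is a single-layer perceptron with a sigmoid output that predicts, from
the last six trials, whether the participant will pick LOW next, and then
plays HIGH with exactly that predicted probability (probability matching,
which follows from the squared-error target/output coupling of its update
rule). Because the opponent wins on a mismatch, predicting "participant LOW"
and answering HIGH is how it exploits biased play.

Sign convention: the printed activation is ``f(x) = 1 / (1 + exp(w . x))``,
i.e. a sigmoid of *minus* the weighted sum — larger ``w . x`` means a LOWER
probability of LRN choosing HIGH. The update rule is the analytic gradient of
the squared error under exactly this convention.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Deque, Literal, Protocol

import numpy as np

from .game import Choice, PayoffMatrix, TrialRecord, OpponentType, resolve_trial

__all__ = [
    "N_FEATURES",
    "HISTORY_LEN",
    "LrnState",
    "FixPolicy",
    "ScriptedPolicy",
    "encode_features",
    "lrn_choice_prob",
    "lrn_update",
    "fix_choose",
    "play_block",
    "Agent",
    "ScriptedAgent",
    "FixAgent",
    "LrnAgent",
]

HISTORY_LEN = 6
# 3 binary inputs per remembered trial + 1 constant bias input
N_FEATURES = 3 * HISTORY_LEN + 1

HistoryTriple = tuple[Choice, Choice, bool]  # (participant, LRN, participant won)
Encoding = Literal["binary", "signed"]


@dataclass
class LrnState:
    """Perceptron weights, trial history and learning rate of the LRN opponent."""

    w: np.ndarray = field(default_factory=lambda: np.zeros(N_FEATURES))
    history: Deque[HistoryTriple] = field(
        default_factory=lambda: deque(maxlen=HISTORY_LEN)
    )
    a: float = 0.25
    encoding: Encoding = "binary"

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (N_FEATURES,):
            raise ValueError(f"w must have length {N_FEATURES}, got {self.w.shape}")
        if not isinstance(self.history, deque) or self.history.maxlen != HISTORY_LEN:
            self.history = deque(self.history, maxlen=HISTORY_LEN)
        if self.a <= 0:
            raise ValueError("learning rate must be positive")


@dataclass(frozen=True)
class FixPolicy:
    """Equilibrium mixer: constant HIGH probability, blind to the opponent."""

    p_high: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 < self.p_high < 1.0:
            raise ValueError("FIX p_high must be strictly inside (0, 1)")


@dataclass(frozen=True)
class ScriptedPolicy:
    """Constant-bias test opponent; unlike FIX, degenerate rates are allowed."""

    p_high: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_high <= 1.0:
            raise ValueError("p_high must be in [0, 1]")


def encode_features(
    history: Deque[HistoryTriple] | list[HistoryTriple], encoding: Encoding = "binary"
) -> np.ndarray:
    """Encode up to six remembered trials into the 19-element input vector.

    Each remembered trial contributes three slots (participant chose HIGH,
    LRN chose HIGH, participant won), most recent trial first; missing
    history (early trials) is zero. The final slot is the constant 1 whose
    learned weight absorbs the participant's average HIGH bias.

    ``binary`` maps HIGH/win to 1 and LOW/loss to 0; ``signed`` maps them to
    +1/-1 (missing history still 0).
    """
    if len(history) > HISTORY_LEN:
        raise ValueError(f"history longer than {HISTORY_LEN}")
    lo = 0.0 if encoding == "binary" else -1.0
    x = np.zeros(N_FEATURES)
    for k, (p_choice, l_choice, won) in enumerate(reversed(list(history))):
        base = 3 * k
        x[base] = 1.0 if p_choice is Choice.HIGH else lo
        x[base + 1] = 1.0 if l_choice is Choice.HIGH else lo
        x[base + 2] = 1.0 if won else lo
    x[-1] = 1.0
    return x


def _f(w: np.ndarray, x: np.ndarray) -> float:
    """Stable evaluation of f(x) = 1 / (1 + exp(w . x))."""
    z = float(np.dot(w, x))
    if z >= 0:
        return 1.0 / (1.0 + np.exp(min(z, 700.0)))
    ez = np.exp(max(z, -700.0))
    return 1.0 - ez / (1.0 + ez)


def lrn_choice_prob(state: LrnState) -> float:
    """LRN's probability of choosing HIGH given its current weights and history."""
    x = encode_features(state.history, state.encoding)
    return _f(state.w, x)


def lrn_update(
    state: LrnState,
    participant_choice: Choice,
    lrn_choice: Choice | None = None,
    participant_won: bool | None = None,
) -> LrnState:
    """One gradient step on the squared prediction error, then push history.

    The target is T = 1 if the participant chose LOW (the choice LRN should
    answer with HIGH), else 0. With E = (T - f)^2 and f a sigmoid of -w.x,
    the analytic step is dw_i = -a dE/dw_i = -2 a (T - f) f (1 - f) x_i.

    If ``lrn_choice`` and ``participant_won`` are given, the completed trial
    is appended to the history buffer (oldest of six evicted) so the state is
    ready for the next trial's prediction.
    """
    x = encode_features(state.history, state.encoding)
    f = _f(state.w, x)
    t = 1.0 if participant_choice is Choice.LOW else 0.0
    w_new = state.w - 2.0 * state.a * (t - f) * f * (1.0 - f) * x
    history = deque(state.history, maxlen=HISTORY_LEN)
    if lrn_choice is not None:
        if participant_won is None:
            raise ValueError("participant_won is required when pushing history")
        history.append((participant_choice, lrn_choice, participant_won))
    return LrnState(w=w_new, history=history, a=state.a, encoding=state.encoding)


def squared_error(state: LrnState, participant_choice: Choice) -> float:
    """E = (T - f(x))^2 for the current history; the objective of lrn_update."""
    t = 1.0 if participant_choice is Choice.LOW else 0.0
    return (t - lrn_choice_prob(state)) ** 2


def fix_choose(policy: FixPolicy | ScriptedPolicy, rng: np.random.Generator) -> Choice:
    """Draw one choice from a fixed-rate policy."""
    return Choice.HIGH if rng.random() < policy.p_high else Choice.LOW


class Agent(Protocol):
    """Anything that can play the game trial by trial."""

    def choose(self, rng: np.random.Generator) -> Choice: ...

    def observe(
        self, own_choice: Choice, other_choice: Choice, own_won: bool, own_reward: float
    ) -> None: ...


class ScriptedAgent:
    """Stateless constant-bias agent (testing and probe opponents)."""

    def __init__(self, p_high: float):
        self.policy = ScriptedPolicy(p_high)

    def choose(self, rng: np.random.Generator) -> Choice:
        return fix_choose(self.policy, rng)

    def observe(self, own_choice, other_choice, own_won, own_reward) -> None:
        pass


class FixAgent:
    """The FIX opponent: plays the equilibrium rate regardless of history."""

    def __init__(self, p_high: float = 0.25):
        self.policy = FixPolicy(p_high)

    def choose(self, rng: np.random.Generator) -> Choice:
        return fix_choose(self.policy, rng)

    def observe(self, own_choice, other_choice, own_won, own_reward) -> None:
        pass


class LrnAgent:
    """The LRN opponent: stateful wrapper running predict -> act -> learn."""

    def __init__(self, state: LrnState | None = None):
        self.state = state if state is not None else LrnState()

    def choose(self, rng: np.random.Generator) -> Choice:
        p_high = lrn_choice_prob(self.state)
        return Choice.HIGH if rng.random() < p_high else Choice.LOW

    def observe(
        self, own_choice: Choice, other_choice: Choice, own_won: bool, own_reward: float
    ) -> None:
        # other_choice is the participant's; the participant won iff LRN lost
        self.state = lrn_update(
            self.state,
            participant_choice=other_choice,
            lrn_choice=own_choice,
            participant_won=not own_won,
        )


def play_block(
    opponent_agent: Agent,
    participant_agent: Agent,
    n_trials: int,
    payoff: PayoffMatrix,
    rng: np.random.Generator,
    *,
    opponent_type: OpponentType = OpponentType.FIX,
    run: int = 1,
    block: int = 1,
    start_index: int = 0,
) -> list[TrialRecord]:
    """Play ``n_trials`` trials between a participant agent and an opponent agent.

    Both agents draw simultaneously, the trial is resolved, and both observe
    the outcome (LRN performs its weight update inside ``observe``).
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    records: list[TrialRecord] = []
    for t in range(n_trials):
        p_choice = participant_agent.choose(rng)
        o_choice = opponent_agent.choose(rng)
        win, p_rew, o_rew = resolve_trial(p_choice, o_choice, payoff)
        participant_agent.observe(p_choice, o_choice, win, p_rew)
        opponent_agent.observe(o_choice, p_choice, not win, o_rew)
        records.append(
            TrialRecord(
                trial_index=start_index + t,
                run=run,
                block=block,
                opponent=opponent_type,
                participant_choice=p_choice,
                opponent_choice=o_choice,
                win=win,
                participant_reward=p_rew,
                opponent_reward=o_rew,
            )
        )
    return records
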