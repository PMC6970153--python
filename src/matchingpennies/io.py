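"""Plain-text serialization of sessions, fits, beta patterns and RDMs."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .game import Choice, OpponentType, ScheduleSpec, Session, TrialRecord
from .models import FitResult
from .rsa import RDM
from .synth import CONDITION_ORDER, RoiBetas

SESSION_COLUMNS = [
    "participant_id",
    "trial_index",
    "run",
    "block",
    "opponent",
    "participant_choice",
    "opponent_choice",
    "win",
    "participant_reward",
    "opponent_reward",
]


def session_to_frame(session: Session) -> pd.DataFrame:
    rows = [
        {
            "participant_id": session.participant_id,
            "trial_index": t.trial_index,
            "run": t.run,
            "block": t.block,
            "opponent": t.opponent.value,
            "participant_choice": t.participant_choice.value,
            "opponent_choice": t.opponent_choice.value,
            "win": int(t.win),
            "participant_reward": t.participant_reward,
            "opponent_reward": t.opponent_reward,
        }
        for t in session.trials
    ]
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def write_session_csv(session: Session, path: str | Path) -> None:
    session_to_frame(session).to_csv(path, index=False)


def read_session_csv(path: str | Path, schedule: ScheduleSpec | None = None) -> Session:
    df = pd.read_csv(path)
    missing = set(SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"session CSV missing columns: {sorted(missing)}")
    trials = [
        TrialRecord(
            trial_index=int(r.trial_index),
            run=int(r.run),
            block=int(r.block),
            opponent=OpponentType(r.opponent),
            participant_choice=Choice(r.participant_choice),
            opponent_choice=Choice(r.opponent_choice),
            win=bool(r.win),
            participant_reward=float(r.participant_reward),
            opponent_reward=float(r.opponent_reward),
        )
        for r in df.itertuples()
    ]
    pid = str(df["participant_id"].iloc[0]) if len(df) else ""
    if schedule is None:
        n_runs = int(df["run"].max())
        blocks = int(df["block"].max())
        per_block = len(df) // max(n_runs * blocks, 1)
        schedule = ScheduleSpec(n_runs, blocks, per_block)
    return Session(participant_id=pid, trials=trials, schedule=schedule)


def fit_to_dict(participant: str, opponent: str, fit: FitResult) -> dict:
    return {
        "participant": participant,
        "opponent": opponent,
        "model": fit.model.value,
        "alpha": fit.params.alpha,
        "beta": fit.params.beta,
        "nll": fit.nll,
        "aic": fit.aic,
        "n_starts": fit.n_starts,
        "converged": fit.converged,
    }


def write_fits_json(records: Sequence[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(list(records), indent=2))


def write_betas_csv(betas: RoiBetas, path: str | Path) -> None:
    """One numeric CSV (rows = conditions) plus a JSON sidecar naming the rows."""
    path = Path(path)
    pd.DataFrame(betas.data).to_csv(path, index=False, header=False)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {"participant_id": betas.participant_id, "conditions": list(CONDITION_ORDER)}
        )
    )


def read_betas_csv(path: str | Path) -> RoiBetas:
    path = Path(path)
    data = pd.read_csv(path, header=None).to_numpy(dtype=float)
    sidecar = path.with_suffix(".json")
    pid = ""
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pid = meta.get("participant_id", "")
        if tuple(meta.get("conditions", CONDITION_ORDER)) != CONDITION_ORDER:
            raise ValueError("beta CSV condition order does not match the fixed order")
    return RoiBetas(participant_id=pid, data=data)


def write_rdm_csv(rdm: RDM, path: str | Path) -> None:
    pd.DataFrame(rdm.values, index=rdm.labels, columns=rdm.labels).to_csv(path)
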