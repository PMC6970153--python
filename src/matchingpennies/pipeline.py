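"""Descriptive behavioral statistics and end-to-end pipeline orchestration.

``run_pipeline`` reproduces the full analysis sequence on synthetic data:
simulate a cohort -> fit all three choice models per participant and
opponent condition -> AIC comparison table -> posterior predictive check of
the winning model -> generate ROI beta patterns -> pattern-similarity
contrast. Every stage is seeded from the run configuration, so a rerun with
the same config is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import io as mp_io
from .game import (
    DEFAULT_PAYOFF,
    Choice,
    OpponentType,
    PayoffMatrix,
    ScheduleSpec,
    Session,
)
from .models import (
    FitConfig,
    FitResult,
    ModelKind,
    fit_model,
    model_comparison_table,
    posterior_predictive_match_rate,
)
from .rsa import similarity_contrast
from .synth import BetaPatternSpec, CohortSpec, generate_roi_betas, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "high_choice_rate",
    "behavior_summary",
    "planned_contrast",
    "cross_condition_correlations",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    schedule: ScheduleSpec = field(default_factory=ScheduleSpec)
    payoff: PayoffMatrix = field(default_factory=PayoffMatrix)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    betas: BetaPatternSpec = field(default_factory=BetaPatternSpec)
    fit: FitConfig = field(default_factory=FitConfig)
    seed: int = 0
    ppc_reps: int = 200
    output_dir: str = "pipeline_output"

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls.from_dict(raw)
        if seed is not None:
            cfg.seed = seed
            cfg.cohort.master_seed = seed
            cfg.betas = BetaPatternSpec(
                n_voxels=cfg.betas.n_voxels,
                lambda_shared=cfg.betas.lambda_shared,
                sigma_choice=cfg.betas.sigma_choice,
                sigma_noise=cfg.betas.sigma_noise,
                seed=seed + 1,
            )
        return cfg

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = {}
        if "schedule" in raw:
            kwargs["schedule"] = ScheduleSpec(**raw["schedule"])
        if "payoff" in raw:
            kwargs["payoff"] = PayoffMatrix(**raw["payoff"])
        if "cohort" in raw:
            kwargs["cohort"] = CohortSpec(**raw["cohort"])
        if "betas" in raw:
            kwargs["betas"] = BetaPatternSpec(**raw["betas"])
        if "fit" in raw:
            kwargs["fit"] = FitConfig(**raw["fit"])
        for key in ("seed", "ppc_reps", "output_dir"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "schedule": {
                "n_runs": self.schedule.n_runs,
                "blocks_per_run": self.schedule.blocks_per_run,
                "trials_per_block": self.schedule.trials_per_block,
                "counterbalance_seed": self.schedule.counterbalance_seed,
            },
            "payoff": {
                "p_win_high": self.payoff.p_win_high,
                "p_win_low": self.payoff.p_win_low,
                "o_win_after_p_high": self.payoff.o_win_after_p_high,
                "o_win_after_p_low": self.payoff.o_win_after_p_low,
            },
            "cohort": {
                "n_participants": self.cohort.n_participants,
                "alpha_mean": self.cohort.alpha_mean,
                "alpha_sd": self.cohort.alpha_sd,
                "beta_mean": self.cohort.beta_mean,
                "beta_sd": self.cohort.beta_sd,
                "hum_proxy_alpha": self.cohort.hum_proxy_alpha,
                "hum_proxy_beta": self.cohort.hum_proxy_beta,
                "master_seed": self.cohort.master_seed,
            },
            "betas": {
                "n_voxels": self.betas.n_voxels,
                "lambda_shared": self.betas.lambda_shared,
                "sigma_choice": self.betas.sigma_choice,
                "sigma_noise": self.betas.sigma_noise,
                "seed": self.betas.seed,
            },
            "fit": {
                "n_starts": self.fit.n_starts,
                "seed": self.fit.seed,
                "beta_max": self.fit.beta_max,
                "tol": self.fit.tol,
                "v_init": self.fit.v_init,
            },
            "seed": self.seed,
            "ppc_reps": self.ppc_reps,
            "output_dir": self.output_dir,
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def high_choice_rate(
    session: Session, granularity: Literal["per-run", "per-condition"] = "per-condition"
) -> pd.DataFrame:
    """Fraction of HIGH choices per run or per opponent condition."""
    df = mp_io.session_to_frame(session)
    df["high"] = (df["participant_choice"] == Choice.HIGH.value).astype(float)
    key = "run" if granularity == "per-run" else "opponent"
    grouped = df.groupby(key)["high"].agg(["mean", "count"])
    if (grouped["count"] == 0).any():
        raise ValueError("empty cell in high-choice-rate table")
    grouped = grouped.rename(columns={"mean": "high_rate", "count": "n_trials"})
    return grouped.reset_index()


def behavior_summary(cohort: Sequence[Session]) -> pd.DataFrame:
    """Per-participant win rate, total earnings, and per-condition HIGH rates."""
    rows = []
    for session in cohort:
        if not session.trials:
            raise ValueError(f"session {session.participant_id} has no trials")
        df = mp_io.session_to_frame(session)
        row = {
            "participant": session.participant_id,
            "win_rate": df["win"].mean(),
            "earnings": df["participant_reward"].sum(),
        }
        for opp in OpponentType:
            sub = df[df["opponent"] == opp.value]
            row[f"high_rate_{opp.value}"] = (
                sub["participant_choice"] == Choice.HIGH.value
            ).mean()
            row[f"win_rate_{opp.value}"] = sub["win"].mean()
            row[f"earnings_{opp.value}"] = sub["participant_reward"].sum()
        rows.append(row)
    return pd.DataFrame(rows)


def planned_contrast(summary: pd.DataFrame, column_prefix: str = "high_rate") -> dict:
    """One-sample t test of mean(HUM, LRN) - FIX across participants."""
    if len(summary) < 2:
        raise ValueError("the contrast needs at least 2 participants")
    vals = (
        0.5 * (summary[f"{column_prefix}_HUM"] + summary[f"{column_prefix}_LRN"])
        - summary[f"{column_prefix}_FIX"]
    ).to_numpy()
    if np.allclose(vals, vals.mean()) and np.isclose(vals.mean(), 0.0):
        return {"mean": 0.0, "t": 0.0, "df": len(vals) - 1, "p": 1.0}
    res = stats.ttest_1samp(vals, 0.0)
    return {
        "mean": float(vals.mean()),
        "t": float(res.statistic),
        "df": len(vals) - 1,
        "p": float(res.pvalue),
    }


def cross_condition_correlations(summary: pd.DataFrame) -> dict:
    """Pearson r of per-participant HIGH rates between opponent conditions."""
    out = {}
    for a, b in (("HUM", "LRN"), ("HUM", "FIX"), ("FIX", "LRN")):
        r, p = stats.pearsonr(
            summary[f"high_rate_{a}"], summary[f"high_rate_{b}"]
        )
        out[f"{a}_{b}"] = {"r": float(r), "p": float(p)}
    return out


def fit_cohort(
    cohort: Sequence[Session],
    fit_config: FitConfig,
) -> dict[tuple[str, str, ModelKind], FitResult]:
    """Fit all three models per participant per opponent condition."""
    fits: dict[tuple[str, str, ModelKind], FitResult] = {}
    for session in cohort:
        for opp in OpponentType:
            trials = session.trials_for(opp)
            for model in ModelKind:
                fits[(session.participant_id, opp.value, model)] = fit_model(
                    model, trials, fit_config
                )
    return fits


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic-data analysis; write artifacts, return a report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.config_hash(), "stages": {}}

    current_stage = "setup"

    def stage(name):
        nonlocal current_stage
        current_stage = name
        logger.info("stage %s starting (seed=%d)", name, config.seed)
        return time.time()

    try:
        t0 = stage("simulate")
        cohort, truth = simulate_cohort(config.cohort, config.schedule, config.payoff)
        for session in cohort:
            mp_io.write_session_csv(session, out / f"{session.participant_id}.csv")
        truth.to_csv(out / "truth.csv", index=False)
        report["stages"]["simulate"] = {
            "n_participants": len(cohort),
            "elapsed_s": round(time.time() - t0, 2),
        }

        t0 = stage("behavior")
        summary = behavior_summary(cohort)
        summary.to_csv(out / "behavior_summary.csv", index=False)
        report["behavior"] = {
            "mean_win_rate": float(summary["win_rate"].mean()),
            "planned_contrast": planned_contrast(summary),
            "correlations": cross_condition_correlations(summary)
            if len(summary) > 2
            else {},
        }
        report["stages"]["behavior"] = {"elapsed_s": round(time.time() - t0, 2)}

        t0 = stage("fit")
        fits = fit_cohort(cohort, config.fit)
        mp_io.write_fits_json(
            [mp_io.fit_to_dict(p, o, f) for (p, o, m), f in fits.items()],
            out / "fits.json",
        )
        table = model_comparison_table(fits)
        table.to_csv(out / "model_comparison.csv")
        report["model_comparison"] = {
            cond: row["best"] for cond, row in table.iterrows()
        }
        report["stages"]["fit"] = {
            "n_fits": len(fits),
            "elapsed_s": round(time.time() - t0, 2),
        }

        t0 = stage("ppc")
        rng = np.random.default_rng(config.seed + 17)
        ppc_rates = []
        for session in cohort:
            for opp in OpponentType:
                fit = fits[(session.participant_id, opp.value, ModelKind.WRM)]
                ppc_rates.append(
                    posterior_predictive_match_rate(
                        fit,
                        session.trials_for(opp),
                        reps=config.ppc_reps,
                        rng=rng,
                        payoff=config.payoff,
                        v_init=config.fit.v_init,
                    )
                )
        report["ppc"] = {"mean_match_rate_wrm": float(np.mean(ppc_rates))}
        report["stages"]["ppc"] = {"elapsed_s": round(time.time() - t0, 2)}

        t0 = stage("betas")
        betas = generate_roi_betas(config.betas, config.cohort.n_participants)
        for b in betas:
            mp_io.write_betas_csv(b, out / f"betas_{b.participant_id}.csv")
        report["stages"]["betas"] = {"elapsed_s": round(time.time() - t0, 2)}

        t0 = stage("rsa")
        contrasts, group = similarity_contrast(betas)
        (out / "rsa_contrast.json").write_text(
            json.dumps(
                {
                    "per_participant": [
                        {
                            "participant": c.participant_id,
                            "z_hum_lrn": c.z_hum_lrn,
                            "z_hum_fix": c.z_hum_fix,
                        }
                        for c in contrasts
                    ],
                    "group": {
                        "mean_diff": group.mean_diff,
                        "t": group.t,
                        "df": group.df,
                        "p": group.p,
                    },
                },
                indent=2,
            )
        )
        report["rsa"] = {
            "mean_diff": group.mean_diff,
            "t": group.t,
            "df": group.df,
            "p": group.p,
        }
        report["stages"]["rsa"] = {"elapsed_s": round(time.time() - t0, 2)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{current_stage}' failed: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
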