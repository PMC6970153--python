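"""Representational similarity analysis on condition x voxel patterns.

Distances between condition patterns are 1 minus Spearman's rank correlation
of the voxel values, collected into a symmetric representational distance
matrix (RDM). The headline contrast collapses high/low choices within each
opponent (voxelwise mean of the two maps), then compares the Fisher
z-transformed HUM-LRN correlation against the HUM-FIX correlation with a
paired t test across participants: a positive difference means the neural
pattern evoked by the human opponent resembles the adaptive learner more
than the fixed-strategy opponent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .synth import CONDITION_ORDER, RoiBetas

__all__ = [
    "RDM",
    "SimilarityContrast",
    "GroupContrast",
    "spearman_rho",
    "compute_rdm",
    "collapse_choice",
    "similarity_contrast",
]

COLLAPSED_ORDER = ("HUM", "FIX", "LRN")


@dataclass
class RDM:
    """Symmetric distance matrix (1 - Spearman rho) over labeled conditions."""

    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"expected a {n} x {n} matrix, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("RDM diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 2.0 + 1e-12:
            raise ValueError("RDM entries must lie in [0, 2]")
        self.values = v


@dataclass(frozen=True)
class SimilarityContrast:
    """Per-participant Fisher-z similarities of HUM-LRN and HUM-FIX."""

    participant_id: str
    z_hum_lrn: float
    z_hum_fix: float

    @property
    def difference(self) -> float:
        return self.z_hum_lrn - self.z_hum_fix


@dataclass(frozen=True)
class GroupContrast:
    mean_diff: float
    t: float
    df: int
    p: float


def spearman_rho(pattern_a: np.ndarray, pattern_b: np.ndarray) -> float:
    """Spearman rank correlation of two voxel patterns (average ranks on ties)."""
    a = np.asarray(pattern_a, dtype=float)
    b = np.asarray(pattern_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("patterns must be equal-length 1-D vectors of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("rank correlation is undefined for a constant pattern")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def compute_rdm(
    betas: RoiBetas | np.ndarray, labels: Sequence[str] = CONDITION_ORDER
) -> RDM:
    """Pairwise 1 - Spearman rho over condition patterns (6 x 6 by default)."""
    data = betas.data if isinstance(betas, RoiBetas) else np.asarray(betas, float)
    n = data.shape[0]
    if n != len(labels):
        raise ValueError("one label per condition row is required")
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - spearman_rho(data[i], data[j])
            values[i, j] = values[j, i] = d
    return RDM(values=values, labels=tuple(labels))


def collapse_choice(betas: RoiBetas) -> np.ndarray:
    """Average the high- and low-choice maps within each opponent.

    Returns a 3 x n_voxels array in COLLAPSED_ORDER (HUM, FIX, LRN). Choices
    are collapsed on the beta maps *before* any correlation is taken.
    """
    data = betas.data
    out = np.empty((3, data.shape[1]))
    for k, opp in enumerate(COLLAPSED_ORDER):
        hi = CONDITION_ORDER.index(f"{opp}-high")
        lo = CONDITION_ORDER.index(f"{opp}-low")
        out[k] = 0.5 * (data[hi] + data[lo])
    return out


def _fisher_z(rho: float) -> float:
    if abs(rho) >= 1.0:
        raise ValueError("Fisher z is infinite at |rho| = 1")
    return math.atanh(rho)


def similarity_contrast(
    cohort_betas: Sequence[RoiBetas],
    method: Literal["average_patterns", "average_correlations"] = "average_patterns",
) -> tuple[list[SimilarityContrast], GroupContrast]:
    """HUM-LRN vs HUM-FIX pattern-similarity contrast across a cohort.

    Per participant, choices are collapsed and the Spearman correlations of
    the HUM pattern with the LRN and FIX patterns are Fisher z-transformed;
    the group statistic is a paired t test of z(HUM-LRN) against z(HUM-FIX).
    ``average_correlations`` instead averages the four choice-level
    correlations of each opponent pair before the z transform.
    """
    if len(cohort_betas) < 2:
        raise ValueError("the group test needs at least 2 participants")
    contrasts: list[SimilarityContrast] = []
    for betas in cohort_betas:
        if method == "average_patterns":
            collapsed = collapse_choice(betas)
            hum, fix, lrn = collapsed
            z_hl = _fisher_z(spearman_rho(hum, lrn))
            z_hf = _fisher_z(spearman_rho(hum, fix))
        else:
            z_hl = _fisher_z(_mean_pairwise_rho(betas, "HUM", "LRN"))
            z_hf = _fisher_z(_mean_pairwise_rho(betas, "HUM", "FIX"))
        contrasts.append(
            SimilarityContrast(
                participant_id=betas.participant_id, z_hum_lrn=z_hl, z_hum_fix=z_hf
            )
        )
    z_hl_arr = np.array([c.z_hum_lrn for c in contrasts])
    z_hf_arr = np.array([c.z_hum_fix for c in contrasts])
    diff = z_hl_arr - z_hf_arr
    if np.allclose(diff, 0.0):
        group = GroupContrast(mean_diff=0.0, t=0.0, df=len(diff) - 1, p=1.0)
    else:
        res = stats.ttest_rel(z_hl_arr, z_hf_arr)
        group = GroupContrast(
            mean_diff=float(diff.mean()),
            t=float(res.statistic),
            df=len(diff) - 1,
            p=float(res.pvalue),
        )
    return contrasts, group


def _mean_pairwise_rho(betas: RoiBetas, opp_a: str, opp_b: str) -> float:
    rhos = [
        spearman_rho(betas.pattern(f"{opp_a}-{ca}"), betas.pattern(f"{opp_b}-{cb}"))
        for ca in ("high", "low")
        for cb in ("high", "low")
    ]
    return float(np.mean(rhos))
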