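"""Synthetic longitudinal PHQ-9 cohort generator.

Stands in for the private EHR extract the preparation chain was designed
around: three latent risk groups, twelve monthly scores per patient and
roughly 38% missing observations.  Generation operates directly on the
pair-state Markov chain (the generating transition matrices are the exact
ground truth downstream estimators should recover); the PHQ-9 score is a
noisy decoration of the latent severity level, clamped to that level's score
interval.  Missingness is completely at random, with re-masking to guarantee
the six observed scores the filtering step requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort_prep import TrajectoryRecord, TransitionMatrix
from .model_core import ALL_PAIRS, PAIR_CODES, PAIR_INDEX, SeverityLevel

__all__ = ["SyntheticCohortSpec", "CohortTruth", "default_spec", "generate_cohort"]

#: inclusive PHQ-9 score interval for each severity level.
LEVEL_INTERVALS = {"H": (0.0, 4.0), "M": (5.0, 9.0), "S": (10.0, 27.0)}
LEVELS = ("H", "M", "S")


@dataclass
class SyntheticCohortSpec:
    """Generating truth for a synthetic cohort.

    ``group_pair_matrices`` are the per-group 9x9 pair-state chains;
    ``group_score_means`` gives the mean emitted PHQ-9 score per (group,
    level); ``group_initial_pairs`` defaults to each chain's stationary
    distribution.
    """

    n_patients: int
    group_weights: tuple[float, float, float]
    group_pair_matrices: tuple[TransitionMatrix, ...]
    group_score_means: tuple[dict[str, float], ...]
    score_noise_sd: float
    missing_fraction: float
    seed: int
    female_fraction: float = 0.69
    mean_age: float = 45.0
    group_initial_pairs: tuple[np.ndarray, ...] | None = None

    def validate(self) -> None:
        errors: list[str] = []
        if self.n_patients < 1:
            errors.append("n_patients must be >= 1")
        w = np.asarray(self.group_weights, dtype=float)
        if len(w) != 3 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            errors.append("group_weights must be 3 non-negative reals summing to 1")
        if len(self.group_pair_matrices) != 3:
            errors.append("need 3 group_pair_matrices")
        if len(self.group_score_means) != 3:
            errors.append("need 3 group_score_means")
        for g, means in enumerate(self.group_score_means):
            for lvl in LEVELS:
                lo, hi = LEVEL_INTERVALS[lvl]
                if lvl not in means or not (lo <= means[lvl] <= hi):
                    errors.append(
                        f"group {g} level {lvl} score mean must lie in [{lo}, {hi}]"
                    )
        if self.score_noise_sd < 0:
            errors.append("score_noise_sd must be >= 0")
        if not (0.0 <= self.missing_fraction < 1.0):
            errors.append("missing_fraction must be in [0, 1)")
        if not (0.0 <= self.female_fraction <= 1.0):
            errors.append("female_fraction must be in [0, 1]")
        if self.group_initial_pairs is not None:
            for g, d in enumerate(self.group_initial_pairs):
                d = np.asarray(d, float)
                if d.shape != (9,) or np.any(d < 0) or abs(d.sum() - 1) > 1e-9:
                    errors.append(f"group {g} initial pair distribution invalid")
        if errors:
            raise ValueError("invalid SyntheticCohortSpec: " + "; ".join(errors))


@dataclass
class CohortTruth:
    """Latent generating state, for tests and audits only."""

    group_labels: np.ndarray
    group_matrices: tuple[TransitionMatrix, ...]
    level_sequences: np.ndarray  # (n, 13) int level codes 0/1/2

    def to_json_dict(self) -> dict:
        return {
            "group_labels": self.group_labels.tolist(),
            "group_matrices": [m.to_dict() for m in self.group_matrices],
            "level_sequences": self.level_sequences.tolist(),
        }


def _momentum_pair_matrix(kernel: np.ndarray, delta: float = 0.05) -> TransitionMatrix:
    """Embed a 3x3 level kernel into the 9x9 pair chain with trend momentum.

    Row for pair (a, b) is the kernel row for level b, nudged by ``delta``
    toward further improvement when the patient improved (a worse than b) and
    toward further worsening when they worsened.
    """
    values = np.zeros((9, 9))
    rank = {"H": 0, "M": 1, "S": 2}
    for i, pair in enumerate(ALL_PAIRS):
        a, b = rank[pair.prev.value], rank[pair.curr.value]
        row3 = kernel[b].copy()
        if a > b:  # improving trend: shift mass from worst to best next level
            move = min(delta, row3[2])
            row3[2] -= move
            row3[0] += move
        elif a < b:  # worsening trend
            move = min(delta, row3[0])
            row3[0] -= move
            row3[2] += move
        row3 = row3 / row3.sum()
        for c_idx, c in enumerate(LEVELS):
            values[i, PAIR_INDEX[pair.curr.value + c]] = row3[c_idx]
    return TransitionMatrix(values)


def _stationary(matrix: TransitionMatrix) -> np.ndarray:
    # solve pi P = pi, sum(pi) = 1 as a least-squares system
    A = np.vstack([matrix.values.T - np.eye(9), np.ones(9)])
    b = np.zeros(10)
    b[-1] = 1.0
    v, *_ = np.linalg.lstsq(A, b, rcond=None)
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def default_spec(n_patients: int = 444, seed: int = 12345) -> SyntheticCohortSpec:
    """Three-group cohort emulating the study data's scale and structure.

    Group weights are proportional to 128:192:124 (high:medium:low), the
    missing fraction is 0.38 and the level kernels place the groups at
    clearly different chronic severities so all nine pair states occur.
    """
    k_high = np.array([[0.45, 0.35, 0.20], [0.25, 0.40, 0.35], [0.15, 0.25, 0.60]])
    k_med = np.array([[0.55, 0.30, 0.15], [0.30, 0.45, 0.25], [0.20, 0.35, 0.45]])
    k_low = np.array([[0.65, 0.25, 0.10], [0.40, 0.40, 0.20], [0.25, 0.40, 0.35]])
    matrices = tuple(_momentum_pair_matrix(k) for k in (k_high, k_med, k_low))
    weights = np.array([128.0, 192.0, 124.0])
    weights = weights / weights.sum()
    return SyntheticCohortSpec(
        n_patients=n_patients,
        group_weights=tuple(weights),
        group_pair_matrices=matrices,
        group_score_means=(
            {"H": 3.5, "M": 8.0, "S": 17.0},
            {"H": 3.0, "M": 7.0, "S": 13.0},
            {"H": 2.0, "M": 6.0, "S": 11.0},
        ),
        score_noise_sd=1.2,
        missing_fraction=0.38,
        seed=seed,
    )


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[list[TrajectoryRecord], CohortTruth]:
    """Draw a synthetic cohort; deterministic given the spec (incl. seed).

    Per patient: a latent risk group, then 13 monthly severity levels from the
    group's pair chain (months 2-13 are emitted as the 12 monthly scores, so
    each emitted month has a defined previous level), Gaussian score noise
    clamped to the level interval, and MCAR masking re-drawn until at least 6
    scores remain observed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    groups = rng.choice(3, size=n, p=np.asarray(spec.group_weights, float))
    initials = (
        spec.group_initial_pairs
        if spec.group_initial_pairs is not None
        else tuple(_stationary(m) for m in spec.group_pair_matrices)
    )
    level_rank = {"H": 0, "M": 1, "S": 2}
    # level_sequences[i, t] = level at month t (t = 0..12, 13 levels)
    levels = np.zeros((n, 13), dtype=int)
    for i in range(n):
        g = groups[i]
        P = spec.group_pair_matrices[g].values
        pair = rng.choice(9, p=np.asarray(initials[g], float))
        code = PAIR_CODES[pair]
        levels[i, 0] = level_rank[code[0]]
        levels[i, 1] = level_rank[code[1]]
        for t in range(2, 13):
            pair = rng.choice(9, p=P[pair])
            levels[i, t] = level_rank[PAIR_CODES[pair][1]]

    records: list[TrajectoryRecord] = []
    sexes = np.where(rng.random(n) < spec.female_fraction, "female", "male")
    ages = np.clip(rng.normal(spec.mean_age, 10.0, size=n), 18, 80)
    for i in range(n):
        g = groups[i]
        means = spec.group_score_means[g]
        scores = np.empty(12)
        for m in range(12):
            lvl = LEVELS[levels[i, m + 1]]
            lo, hi = LEVEL_INTERVALS[lvl]
            s = means[lvl] + (
                rng.normal(0.0, spec.score_noise_sd) if spec.score_noise_sd > 0 else 0.0
            )
            scores[m] = min(max(s, lo), hi)
        # MCAR mask, re-drawn until >= 6 observed
        for _ in range(1000):
            mask = rng.random(12) >= spec.missing_fraction  # True = observed
            if mask.sum() >= 6:
                break
        else:  # pragma: no cover - astronomically unlikely fallback
            mask[np.argsort(rng.random(12))[:6]] = True
        obs = [(float(m + 1), float(scores[m])) for m in range(12) if mask[m]]
        records.append(
            TrajectoryRecord(
                patient_id=f"P{i:05d}",
                observations=obs,
                sex=str(sexes[i]),
                age=float(round(ages[i], 1)),
            )
        )
    truth = CohortTruth(
        group_labels=groups,
        group_matrices=tuple(spec.group_pair_matrices),
        level_sequences=levels,
    )
    return records, truth


def severity_sequences_from_truth(truth: CohortTruth) -> list[list[SeverityLevel]]:
    """Latent 12-month severity sequences (months 2-13), for recovery tests."""
    out = []
    for row in truth.level_sequences:
        out.append([SeverityLevel(LEVELS[v]) for v in row[1:]])
    return out
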