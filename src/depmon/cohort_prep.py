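"""Longitudinal PHQ-9 preparation: from raw records to risk-group profiles.

The chain mirrors a measurement-based-care data workflow:

1. keep patients with at least six recorded scores in the observation window;
2. split each patient's observation span into 12 equal monthly segments and
   average the scores within each segment;
3. impute missing months with an exponentially weighted moving average;
4. k-means cluster the 12-dimensional trajectories into risk groups
   (ordered high -> medium -> low by mean score);
5. estimate a 9x9 pair-state transition matrix and an initial pair
   distribution per group from the imputed severity sequences.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .model_core import (
    ALL_PAIRS,
    FEASIBLE_MASK,
    PAIR_CODES,
    PAIR_INDEX,
    SeverityLevel,
    classify_severity,
)

__all__ = [
    "TrajectoryRecord",
    "TransitionMatrix",
    "RiskGroupProfile",
    "PrepReport",
    "filter_min_observations",
    "segment_monthly",
    "ewma_impute",
    "cluster_risk_groups",
    "estimate_transition_matrix",
    "estimate_initial_distribution",
    "prepare_cohort",
    "read_trajectories_csv",
    "write_trajectories_csv",
    "profiles_to_json",
    "profiles_from_json",
]

N_MONTHS = 12
GROUP_NAMES = ("high", "medium", "low")


@dataclass
class TrajectoryRecord:
    """One patient's longitudinal PHQ-9 observations.

    ``observations`` is a list of ``(time, score)`` pairs, time being either an
    integer day offset or a month index (1-12); times must be sorted and
    non-negative and scores in [0, 27].
    """

    patient_id: str
    observations: list[tuple[float, float]]
    sex: str | None = None
    age: float | None = None

    def __post_init__(self) -> None:
        times = [t for t, _ in self.observations]
        if any(t < 0 for t in times):
            raise ValueError(f"patient {self.patient_id}: negative observation time")
        if times != sorted(times):
            raise ValueError(f"patient {self.patient_id}: observation times not sorted")
        for _, s in self.observations:
            if not (0.0 <= s <= 27.0):
                raise ValueError(
                    f"patient {self.patient_id}: PHQ-9 score {s!r} outside [0, 27]"
                )


@dataclass
class TransitionMatrix:
    """Row-stochastic 9x9 matrix over the pair states, feasibility-masked."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (9, 9):
            raise ValueError(f"transition matrix must be 9x9, got {v.shape}")
        if np.any(v < -1e-15):
            raise ValueError("transition matrix has negative entries")
        if np.any(np.abs(v[~FEASIBLE_MASK]) > 0):
            raise ValueError("transition matrix has mass on infeasible entries")
        rows = v.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-12):
            raise ValueError(f"transition matrix rows must sum to 1, got {rows}")
        self.values = v

    def to_dict(self) -> dict[str, dict[str, float]]:
        return {
            a: {b: float(self.values[i, j]) for j, b in enumerate(PAIR_CODES)}
            for i, a in enumerate(PAIR_CODES)
        }

    @classmethod
    def from_dict(cls, d: dict[str, dict[str, float]]) -> "TransitionMatrix":
        v = np.zeros((9, 9))
        for a, row in d.items():
            for b, p in row.items():
                v[PAIR_INDEX[a], PAIR_INDEX[b]] = p
        return cls(v)


@dataclass
class RiskGroupProfile:
    """Everything the cohort engine needs for one risk group."""

    name: str
    transition: TransitionMatrix
    initial_distribution: np.ndarray
    mean_trajectory: np.ndarray
    n_patients: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.initial_distribution, dtype=float)
        if d.shape != (9,):
            raise ValueError("initial_distribution must have 9 entries")
        if np.any(d < -1e-15) or abs(d.sum() - 1.0) > 1e-12:
            raise ValueError("initial_distribution must be non-negative and sum to 1")
        self.initial_distribution = d
        self.mean_trajectory = np.asarray(self.mean_trajectory, dtype=float)


@dataclass
class PrepReport:
    """Audit counts for the preparation chain."""

    n_input: int
    n_retained: int
    missing_fraction: float
    group_sizes: dict[str, int]
    silhouette_by_k: dict[int, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("n_input", self.n_input),
            ("n_retained", self.n_retained),
            ("n_omitted", self.n_input - self.n_retained),
            ("missing_fraction", self.missing_fraction),
        ]
        rows += [(f"group_size_{g}", n) for g, n in self.group_sizes.items()]
        rows += [(f"silhouette_k{k}", s) for k, s in sorted(self.silhouette_by_k.items())]
        return pd.DataFrame(rows, columns=["quantity", "value"])


def filter_min_observations(
    records: Sequence[TrajectoryRecord], min_count: int = 6
) -> list[TrajectoryRecord]:
    """Keep records with at least ``min_count`` observations (order preserved)."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return [r for r in records if len(r.observations) >= min_count]


def segment_monthly(record: TrajectoryRecord) -> np.ndarray:
    """Average a record's scores over 12 equal segments of its observation span.

    Returns a length-12 float array with ``nan`` for empty segments.  A record
    whose times all lie in [1, 12] and are integral is treated as already
    month-indexed.  A degenerate (zero-width) span puts everything in month 1.
    """
    if not record.observations:
        raise ValueError(f"patient {record.patient_id}: no observations")
    times = np.array([t for t, _ in record.observations], dtype=float)
    scores = np.array([s for _, s in record.observations], dtype=float)
    out = np.full(N_MONTHS, np.nan)

    month_indexed = np.all((times >= 1) & (times <= 12) & (times == np.round(times)))
    if month_indexed:
        seg = times.astype(int) - 1
    else:
        span = times[-1] - times[0]
        if span <= 0:
            seg = np.zeros(len(times), dtype=int)
        else:
            seg = np.minimum(
                (N_MONTHS * (times - times[0]) / span).astype(int), N_MONTHS - 1
            )
    for m in range(N_MONTHS):
        sel = seg == m
        if sel.any():
            out[m] = scores[sel].mean()
    return out


def ewma_impute(series: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Fill missing months with an exponentially weighted moving average.

    A forward pass maintains the EWMA of the *observed* values seen so far
    (``s <- alpha * x + (1 - alpha) * s``) and writes the current ``s`` into
    each missing slot; a symmetric backward pass fills leading gaps before the
    first observation.  Observed values are never modified, and imputed values
    are convex combinations of observed ones, so they stay inside the observed
    range.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    x = np.asarray(series, dtype=float)
    if x.shape != (N_MONTHS,):
        raise ValueError(f"series must have length {N_MONTHS}")
    obs = ~np.isnan(x)
    if not obs.any():
        raise ValueError("cannot impute empty series")
    out = x.copy()
    s = None
    for i in range(N_MONTHS):
        if obs[i]:
            s = x[i] if s is None else alpha * x[i] + (1 - alpha) * s
        elif s is not None:
            out[i] = s
    s = None
    for i in range(N_MONTHS - 1, -1, -1):
        if obs[i]:
            s = x[i] if s is None else alpha * x[i] + (1 - alpha) * s
        elif np.isnan(out[i]):
            out[i] = s
    return out


def cluster_risk_groups(
    matrix: np.ndarray,
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 20,
    k_range: Sequence[int] = (2, 3, 4, 5, 6),
) -> tuple[np.ndarray, dict[int, float]]:
    """k-means on raw 12-dimensional trajectories (Euclidean distance).

    Returns labels relabeled so cluster 0 has the highest mean score
    (high risk) and a silhouette score for each candidate k that fits the
    sample size.  Raises on degenerate (constant) input or n < k.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] != N_MONTHS:
        raise ValueError("matrix must be n x 12")
    if np.isnan(x).any():
        raise ValueError("clustering input must have no missing entries")
    n = x.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} patients, got {n}")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate clustering input")
    if k == 1:
        return np.zeros(n, dtype=int), {}

    silhouettes: dict[int, float] = {}
    for kk in k_range:
        if not (2 <= kk <= n - 1):
            continue
        km = KMeans(n_clusters=kk, n_init=n_restarts, random_state=seed)
        lab = km.fit_predict(x)
        if len(np.unique(lab)) > 1:
            silhouettes[kk] = float(silhouette_score(x, lab))

    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(x)
    # relabel by descending cluster mean score: 0 = highest risk
    means = np.array([x[raw == c].mean() for c in range(k)])
    order = np.argsort(-means)
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[raw], silhouettes


def _severity_codes(seq: Sequence[SeverityLevel]) -> list[str]:
    return [f"{a.value}{b.value}" for a, b in zip(seq[:-1], seq[1:])]


def estimate_transition_matrix(
    severity_sequences: Sequence[Sequence[SeverityLevel]],
    zero_row_fallback: str = "self_loop",
) -> TransitionMatrix:
    """Frequency-count estimate of the 9x9 pair-state transition matrix.

    Each length-T severity sequence yields T-2 pair-to-pair transitions; entry
    (a -> b) is the count of a followed by b over the count of a observed with
    a successor.  Rows never observed get all mass on the (curr, curr)
    self-loop successor (``zero_row_fallback="self_loop"``) or a uniform split
    over the three feasible successors (``"uniform"``).
    """
    if not severity_sequences:
        raise ValueError("no severity sequences supplied")
    if zero_row_fallback not in ("self_loop", "uniform"):
        raise ValueError(f"unknown zero_row_fallback {zero_row_fallback!r}")
    counts = np.zeros((9, 9))
    for seq in severity_sequences:
        if len(seq) < 3:
            raise ValueError("severity sequences must have length >= 3")
        codes = _severity_codes(list(seq))
        for a, b in zip(codes[:-1], codes[1:]):
            counts[PAIR_INDEX[a], PAIR_INDEX[b]] += 1
    values = np.zeros((9, 9))
    for i, pair in enumerate(ALL_PAIRS):
        row = counts[i]
        total = row.sum()
        if total > 0:
            values[i] = row / total
        elif zero_row_fallback == "self_loop":
            values[i, PAIR_INDEX[pair.curr.value * 2]] = 1.0
        else:
            values[i, FEASIBLE_MASK[i]] = 1.0 / 3.0
    return TransitionMatrix(values)


def estimate_initial_distribution(
    severity_sequences: Sequence[Sequence[SeverityLevel]],
) -> np.ndarray:
    """Empirical frequency of each (month-1, month-2) severity pair."""
    if not severity_sequences:
        raise ValueError("no severity sequences supplied")
    counts = np.zeros(9)
    for seq in severity_sequences:
        if len(seq) < 2:
            raise ValueError("severity sequences must have length >= 2")
        counts[PAIR_INDEX[f"{seq[0].value}{seq[1].value}"]] += 1
    return counts / counts.sum()


def prepare_cohort(
    records: Sequence[TrajectoryRecord],
    min_observations: int = 6,
    ewma_alpha: float = 0.5,
    n_clusters: int = 3,
    seed: int = 0,
    n_restarts: int = 20,
    zero_row_fallback: str = "self_loop",
) -> tuple[list[RiskGroupProfile], PrepReport, np.ndarray]:
    """Run the full preparation chain.

    Returns the risk-group profiles (ordered high, medium, low), an audit
    report and the per-patient group labels (aligned with the retained,
    filtered records).
    """
    kept = filter_min_observations(records, min_observations)
    if not kept:
        raise ValueError("no records left after filtering")
    raw = np.stack([segment_monthly(r) for r in kept])
    missing_fraction = float(np.isnan(raw).mean())
    imputed = np.stack([ewma_impute(row, ewma_alpha) for row in raw])
    labels, silhouettes = cluster_risk_groups(
        imputed, k=n_clusters, seed=seed, n_restarts=n_restarts
    )
    sequences = [
        [classify_severity(v) for v in row] for row in imputed
    ]
    profiles: list[RiskGroupProfile] = []
    sizes: dict[str, int] = {}
    for g in range(n_clusters):
        name = GROUP_NAMES[g] if g < len(GROUP_NAMES) else f"group{g}"
        sel = labels == g
        group_seqs = [s for s, keep in zip(sequences, sel) if keep]
        profiles.append(
            RiskGroupProfile(
                name=name,
                transition=estimate_transition_matrix(
                    group_seqs, zero_row_fallback=zero_row_fallback
                ),
                initial_distribution=estimate_initial_distribution(group_seqs),
                mean_trajectory=imputed[sel].mean(axis=0),
                n_patients=int(sel.sum()),
            )
        )
        sizes[name] = int(sel.sum())
    report = PrepReport(
        n_input=len(records),
        n_retained=len(kept),
        missing_fraction=missing_fraction,
        group_sizes=sizes,
        silhouette_by_k=silhouettes,
    )
    return profiles, report, labels


# ---------------------------------------------------------------------------
# I/O


def read_trajectories_csv(path) -> list[TrajectoryRecord]:
    """Read long-format trajectories (patient_id, time, phq9, sex, age)."""
    df = pd.read_csv(path)
    required = {"patient_id", "time", "phq9"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    records: list[TrajectoryRecord] = []
    for pid, grp in df.groupby("patient_id", sort=False):
        grp = grp.sort_values("time")
        obs = [
            (float(t), float(s))
            for t, s in zip(grp["time"], grp["phq9"])
            if not (isinstance(s, float) and math.isnan(s))
        ]
        sex = grp["sex"].iloc[0] if "sex" in grp.columns else None
        age = float(grp["age"].iloc[0]) if "age" in grp.columns else None
        records.append(
            TrajectoryRecord(
                patient_id=str(pid),
                observations=obs,
                sex=None if pd.isna(sex) else sex,
                age=None if age is not None and math.isnan(age) else age,
            )
        )
    return records


def write_trajectories_csv(records: Sequence[TrajectoryRecord], path) -> None:
    rows = []
    for r in records:
        for t, s in r.observations:
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "time": t,
                    "phq9": s,
                    "sex": r.sex,
                    "age": r.age,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def profiles_to_json(profiles: Sequence[RiskGroupProfile], path=None) -> str:
    payload = [
        {
            "name": p.name,
            "n_patients": p.n_patients,
            "transition": p.transition.to_dict(),
            "initial_distribution": {
                c: float(v) for c, v in zip(PAIR_CODES, p.initial_distribution)
            },
            "mean_trajectory": [float(v) for v in p.mean_trajectory],
        }
        for p in profiles
    ]
    text = json.dumps(payload, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def profiles_from_json(source) -> list[RiskGroupProfile]:
    if isinstance(source, str) and source.lstrip().startswith("["):
        payload = json.loads(source)
    else:
        with open(source) as fh:
            payload = json.load(fh)
    return [
        RiskGroupProfile(
            name=item["name"],
            transition=TransitionMatrix.from_dict(item["transition"]),
            initial_distribution=np.array(
                [item["initial_distribution"][c] for c in PAIR_CODES]
            ),
            mean_trajectory=np.array(item["mean_trajectory"]),
            n_patients=int(item.get("n_patients", 0)),
        )
        for item in payload
    ]
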