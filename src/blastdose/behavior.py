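"""Behavioral phenotype quantification from plate-tracking activity exports.

After injury, larvae are recorded in a 96-well plate and the tracking
software exports distance moved per time bin per well.  From those traces
this module quantifies the phenotypes used downstream as dose responses:

* mean (and total) locomotor activity per larva;
* high-activity bouts — candidate behavioural seizures — as runs of bins
  above 64% of the highest single-bin activity seen anywhere in the
  uninjured control group;
* inactivity bouts of at least one minute and the cumulative inactive
  time, the readout that separates "stunned" from merely quiet larvae;
* a candidate-dead flag (zero movement over the whole recording); dead
  larvae are excluded from group statistics only once confirmed by the
  floating/heartbeat check, never silently;
* manually scored seizure stages (ingested as data, never inferred) and
  fin-poke stimulus-response rates on the 5-min observation grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "ActivityTrace",
    "Bout",
    "SeizureScore",
    "FinPokeRecord",
    "SEIZURE_STAGES",
    "FIN_POKE_TIMEPOINTS",
    "mean_activity",
    "total_activity",
    "high_activity_threshold",
    "detect_high_activity_bouts",
    "detect_inactivity",
    "classify_dead",
    "response_rate",
    "seizure_proportions",
    "read_activity_csv",
    "write_activity_csv",
    "read_seizure_scores",
    "read_fin_poke_records",
    "larva_metrics",
]

SEIZURE_STAGES = ("none", "stage_I", "stage_II_III")
FIN_POKE_TIMEPOINTS = (5, 10, 15, 20, 25, 30)


@dataclass(frozen=True)
class ActivityTrace:
    """Per-larva binned activity (distance moved per bin).

    Bins must be contiguous and non-overlapping; activity is nonnegative.
    The nominal recording is 30 min but any duration is accepted.
    """

    larva_id: str
    group: str
    well: str
    t_start_s: np.ndarray
    t_end_s: np.ndarray
    activity: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "t_start_s", np.asarray(self.t_start_s, dtype=float))
        object.__setattr__(self, "t_end_s", np.asarray(self.t_end_s, dtype=float))
        object.__setattr__(self, "activity", np.asarray(self.activity, dtype=float))
        n = len(self.activity)
        if n == 0:
            raise ValueError(f"larva {self.larva_id}: empty activity trace")
        if len(self.t_start_s) != n or len(self.t_end_s) != n:
            raise ValueError(f"larva {self.larva_id}: bin arrays of unequal length")
        if np.any(self.t_end_s <= self.t_start_s):
            raise ValueError(f"larva {self.larva_id}: bins must have positive width")
        if not np.allclose(self.t_start_s[1:], self.t_end_s[:-1]):
            raise ValueError(f"larva {self.larva_id}: bins not contiguous")
        if np.any(self.activity < 0):
            raise ValueError(f"larva {self.larva_id}: negative activity")

    def __len__(self) -> int:
        return len(self.activity)

    @property
    def duration_s(self) -> float:
        return float(self.t_end_s[-1] - self.t_start_s[0])


@dataclass(frozen=True)
class Bout:
    """A maximal run of bins in one state (high activity or inactive)."""

    kind: str  # "high_activity" | "inactive"
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.kind not in ("high_activity", "inactive"):
            raise ValueError(f"unknown bout kind {self.kind!r}")
        if self.end_s <= self.start_s:
            raise ValueError("bout must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class SeizureScore:
    """Blinded manual seizure-stage call for one larva.

    Stage I: distinct hyperactive movements with slight convulsive
    behaviour and minor loss of posture (larva still moving).  Stage
    II/III: whirlpool movements, clonic events, full loss of posture with
    inactivity over 1 s.
    """

    larva_id: str
    stage: str
    observer_id: str = ""
    blinded: bool = True

    def __post_init__(self) -> None:
        if self.stage not in SEIZURE_STAGES:
            raise ValueError(f"stage must be one of {SEIZURE_STAGES}, got {self.stage!r}")


@dataclass(frozen=True)
class FinPokeRecord:
    """Stimulus-response observation at one point on the 5-min grid."""

    larva_id: str
    group: str
    timepoint_min: int
    responded: bool
    heartbeat_verified: bool = True

    def __post_init__(self) -> None:
        if self.timepoint_min not in FIN_POKE_TIMEPOINTS:
            raise ValueError(
                f"timepoint_min must be in {FIN_POKE_TIMEPOINTS}, got {self.timepoint_min}"
            )


def mean_activity(trace: ActivityTrace) -> float:
    """Arithmetic mean of per-bin activity (the locomotor-activity metric)."""
    return float(np.mean(trace.activity))


def total_activity(trace: ActivityTrace) -> float:
    """Total distance moved over the recording."""
    return float(np.sum(trace.activity))


def high_activity_threshold(controls: Sequence[ActivityTrace]) -> float:
    """Seizure-candidate threshold: 64% of the uninjured group's maximum.

    The maximum is the highest single-bin activity over the pooled control
    group of the session.  An all-zero control group yields threshold 0
    (every positive bin would qualify); a warning is emitted.
    """
    if len(controls) == 0:
        raise ValueError("need at least one control trace")
    group_max = max(float(np.max(tr.activity)) for tr in controls)
    threshold = 0.64 * group_max
    if threshold == 0:
        warnings.warn(
            "control group has zero activity everywhere; high-activity "
            "threshold is 0 and every positive bin will qualify",
            stacklevel=2,
        )
    return threshold


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first_index, last_index) pairs."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def detect_high_activity_bouts(trace: ActivityTrace, threshold: float) -> list[Bout]:
    """Maximal runs of consecutive bins with activity strictly above threshold.

    Bout boundaries are the bin boundaries of the first and last bin in the
    run.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return [
        Bout("high_activity", float(trace.t_start_s[i]), float(trace.t_end_s[j]))
        for i, j in _runs(trace.activity > threshold)
    ]


def detect_inactivity(
    trace: ActivityTrace,
    min_duration_s: float = 60.0,
    epsilon: float = 0.0,
) -> tuple[list[Bout], float]:
    """Inactivity bouts of at least ``min_duration_s`` and their total time.

    A bin is inactive when activity <= ``epsilon`` (default 0: strict
    absence of movement).  Only maximal inactive runs lasting at least the
    one-minute default count; shorter pauses are normal quiescence.
    Returns ``(bouts, total_inactive_s)``.
    """
    if min_duration_s <= 0:
        raise ValueError("min_duration_s must be > 0")
    bouts = []
    for i, j in _runs(trace.activity <= epsilon):
        start, end = float(trace.t_start_s[i]), float(trace.t_end_s[j])
        if end - start >= min_duration_s:
            bouts.append(Bout("inactive", start, end))
    return bouts, float(sum(b.duration_s for b in bouts))


def classify_dead(trace: ActivityTrace, epsilon: float = 0.0) -> bool:
    """Advisory candidate-dead flag: no movement over the whole recording.

    Death calls additionally require the floating/heartbeat check, which
    the activity table cannot see, so this flag never excludes a larva by
    itself.
    """
    return bool(total_activity(trace) <= epsilon)


def response_rate(records: Iterable[FinPokeRecord], timepoint_min: int) -> float:
    """Proportion of heartbeat-verified larvae responding at a timepoint.

    Records without heartbeat verification are excluded (dead larvae are
    removed from quantification).
    """
    included = [
        r for r in records if r.timepoint_min == timepoint_min and r.heartbeat_verified
    ]
    if not included:
        raise ValueError(f"no heartbeat-verified records at timepoint {timepoint_min} min")
    return sum(r.responded for r in included) / len(included)


def seizure_proportions(scores: Sequence[SeizureScore]) -> dict[str, float]:
    """Fraction of larvae at each seizure stage; fractions sum to 1.

    Raises on duplicate larva IDs (one stage call per larva per session).
    """
    if len(scores) == 0:
        raise ValueError("need at least one seizure score")
    ids = [s.larva_id for s in scores]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate larva_id in seizure scores: {dup}")
    n = len(scores)
    return {
        stage: sum(s.stage == stage for s in scores) / n for stage in SEIZURE_STAGES
    }


# ---------------------------------------------------------------------------
# CSV dialects (EthoVision-style export and companion score tables)

def read_activity_csv(path: Union[str, Path]) -> list[ActivityTrace]:
    """Read a plate-tracking activity export.

    Expected columns: ``larva_id,group,well,t_start_s,t_end_s,activity``;
    one row per larva per bin.  Rows are grouped by larva in file order.
    """
    df = pd.read_csv(path, comment="#")
    required = {"larva_id", "group", "well", "t_start_s", "t_end_s", "activity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    traces = []
    for larva_id, sub in df.groupby("larva_id", sort=False):
        sub = sub.sort_values("t_start_s")
        traces.append(
            ActivityTrace(
                larva_id=str(larva_id),
                group=str(sub["group"].iloc[0]),
                well=str(sub["well"].iloc[0]),
                t_start_s=sub["t_start_s"].to_numpy(),
                t_end_s=sub["t_end_s"].to_numpy(),
                activity=sub["activity"].to_numpy(),
            )
        )
    return traces


def write_activity_csv(traces: Sequence[ActivityTrace], path: Union[str, Path]) -> None:
    """Write traces in the same dialect :func:`read_activity_csv` reads."""
    frames = [
        pd.DataFrame(
            {
                "larva_id": tr.larva_id,
                "group": tr.group,
                "well": tr.well,
                "t_start_s": tr.t_start_s,
                "t_end_s": tr.t_end_s,
                "activity": tr.activity,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_seizure_scores(path: Union[str, Path]) -> list[SeizureScore]:
    """Read a manual score table ``larva_id,stage[,observer_id,blinded]``."""
    df = pd.read_csv(path, comment="#")
    if not {"larva_id", "stage"} <= set(df.columns):
        raise ValueError(f"{path}: need columns larva_id,stage")
    return [
        SeizureScore(
            larva_id=str(row.larva_id),
            stage=str(row.stage),
            observer_id=str(getattr(row, "observer_id", "")),
            blinded=bool(getattr(row, "blinded", True)),
        )
        for row in df.itertuples(index=False)
    ]


def read_fin_poke_records(path: Union[str, Path]) -> list[FinPokeRecord]:
    """Read a fin-poke table ``larva_id,group,timepoint_min,responded[,heartbeat_verified]``."""
    df = pd.read_csv(path, comment="#")
    required = {"larva_id", "group", "timepoint_min", "responded"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    return [
        FinPokeRecord(
            larva_id=str(row.larva_id),
            group=str(row.group),
            timepoint_min=int(row.timepoint_min),
            responded=bool(row.responded),
            heartbeat_verified=bool(getattr(row, "heartbeat_verified", True)),
        )
        for row in df.itertuples(index=False)
    ]


def larva_metrics(
    traces: Sequence[ActivityTrace],
    control_group: str,
    threshold: float | None = None,
    inactivity_min_s: float = 60.0,
    epsilon: float = 0.0,
) -> pd.DataFrame:
    """Per-larva behavioral metric table for a session.

    When ``threshold`` is None it is derived from the pooled
    ``control_group`` traces by the 64% rule.  Columns: larva_id, group,
    mean_activity, total_activity, n_high_bouts, total_inactive_s,
    candidate_dead.
    """
    if threshold is None:
        controls = [tr for tr in traces if tr.group == control_group]
        if not controls:
            raise ValueError(f"no traces in control group {control_group!r}")
        threshold = high_activity_threshold(controls)
    rows = []
    for tr in traces:
        _, total_inactive = detect_inactivity(tr, inactivity_min_s, epsilon)
        rows.append(
            {
                "larva_id": tr.larva_id,
                "group": tr.group,
                "mean_activity": mean_activity(tr),
                "total_activity": total_activity(tr),
                "n_high_bouts": len(detect_high_activity_bouts(tr, threshold)),
                "total_inactive_s": total_inactive,
                "candidate_dead": classify_dead(tr, epsilon),
            }
        )
    return pd.DataFrame(rows)
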