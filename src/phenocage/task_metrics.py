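"""Task-level metrics: discrimination indices, alternation, serial
reversal learning curves and probe-trial quadrant metrics.

Learning in the 3-choice cognition-wall task is measured per amount of
entries, not per time: every entry is classified against the current
day's target as correct, perseverative (the previous day's target) or
neutral (the remaining hole), and class fractions are computed over
consecutive, non-overlapping bins of 50 entries.  On the first day no
previous target exists, so all errors there are neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ArenaGeometry, Zone
from .tracking_events import (
    InteractionSummary,
    KeypointTrace,
    SegmentationConfig,
    TrackingTrace,
    distance_to_first_entry,
    score_interactions,
    zone_metrics,
)

__all__ = [
    "TargetSchedule",
    "EntryLog",
    "LearningCurve",
    "ProbeMetrics",
    "discrimination_index",
    "alternation",
    "classify_entries",
    "learning_curves",
    "group_learning_curves",
    "replay_reward_schedule",
    "probe_metrics",
]

HOLES = ("left", "middle", "right")

# the study's serial-reversal pattern: 2 discrimination days on the left
# hole, then daily switches right, left, middle, right, left
DEFAULT_SCHEDULE_TARGETS = ("left", "left", "right", "left", "middle", "right", "left")


@dataclass(frozen=True)
class TargetSchedule:
    """Per-day target hole for the cognition-wall task."""

    targets: tuple[str, ...] = DEFAULT_SCHEDULE_TARGETS
    day_length_s: float = 86400.0

    def __post_init__(self) -> None:
        if any(t not in HOLES for t in self.targets):
            raise ValueError(f"targets must be in {HOLES}")
        if self.day_length_s <= 0:
            raise ValueError("day_length_s must be positive")

    @property
    def n_days(self) -> int:
        return len(self.targets)

    def day_of(self, t_s: float) -> int:
        return int(t_s // self.day_length_s)

    def target_at(self, t_s: float) -> str:
        day = self.day_of(t_s)
        if day < 0 or day >= self.n_days:
            raise ValueError(f"no scheduled target for time {t_s} s (day {day})")
        return self.targets[day]

    def previous_target(self, day: int) -> str | None:
        return self.targets[day - 1] if day >= 1 else None


@dataclass
class EntryLog:
    """Ordered cognition-wall entries with their daily target schedule."""

    entries: pd.DataFrame  # columns time_s, hole
    schedule: TargetSchedule

    def __post_init__(self) -> None:
        need = {"time_s", "hole"}
        if not need <= set(self.entries.columns):
            raise ValueError("entry table needs columns time_s and hole")
        ent = self.entries.sort_values("time_s", kind="stable").reset_index(drop=True)
        if len(ent) and not ent["hole"].isin(HOLES).all():
            raise ValueError(f"holes must be in {HOLES}")
        if len(ent):
            days = (ent["time_s"] // self.schedule.day_length_s).astype(int)
            if (days < 0).any() or (days >= self.schedule.n_days).any():
                raise ValueError("entry on a day with no scheduled target")
        self.entries = ent

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class LearningCurve:
    """Per-bin class fractions for one animal (bins of ``bin_size`` entries)."""

    bins: pd.DataFrame  # day, bin_index, n_entries, frac_correct/perseverative/neutral
    bin_size: int = 50


def discrimination_index(novel_seconds: float,
                         familiar_seconds) -> tuple[float, bool]:
    """DI = novel / (novel + sum of familiar); chance level 0.5.

    ``familiar_seconds`` may be a scalar or a sequence (several familiar
    objects).  Returns (value, defined); the value is NaN and ``defined``
    is False when total interaction time is zero.
    """
    fam = np.atleast_1d(np.asarray(familiar_seconds, dtype=float))
    if novel_seconds < 0 or (fam < 0).any():
        raise ValueError("interaction times must be non-negative")
    total = float(novel_seconds + fam.sum())
    if total == 0:
        return float("nan"), False
    return float(novel_seconds) / total, True


def alternation(first_entries, target_arm: str) -> float:
    """Percentage of animals whose first test-trial entry is the target arm."""
    choices = list(first_entries)
    if not choices:
        raise ValueError("no animals")
    return 100.0 * sum(c == target_arm for c in choices) / len(choices)


def classify_entries(log: EntryLog) -> pd.DataFrame:
    """Entry table with day, target and class columns.

    class is correct / perseverative / neutral; perseverative requires a
    previous day whose target differs from the current one.
    """
    ent = log.entries.copy()
    sched = log.schedule
    days = (ent["time_s"] // sched.day_length_s).astype(int)
    ent["day"] = days
    ent["target"] = [sched.targets[d] for d in days]
    prev = [sched.previous_target(d) for d in days]
    cls = []
    for hole, tgt, pv in zip(ent["hole"], ent["target"], prev):
        if hole == tgt:
            cls.append("correct")
        elif pv is not None and pv != tgt and hole == pv:
            cls.append("perseverative")
        else:
            cls.append("neutral")
    ent["class"] = cls
    return ent


def learning_curves(log: EntryLog, bin_size: int = 50,
                    per_day: bool = True) -> LearningCurve:
    """Class fractions over consecutive bins of ``bin_size`` entries.

    With ``per_day`` (the default) binning restarts at each daily target
    switch, matching per-day reversal curves; otherwise bins run over
    the whole log.  A trailing partial bin is reported with its size.
    """
    if len(log) == 0:
        raise ValueError("empty entry log")
    ent = classify_entries(log)
    group_keys = ent["day"] if per_day else np.zeros(len(ent), dtype=int)
    rows = []
    for day, grp in ent.groupby(group_keys, sort=True):
        grp = grp.reset_index(drop=True)
        for b0 in range(0, len(grp), bin_size):
            chunk = grp.iloc[b0:b0 + bin_size]
            n = len(chunk)
            counts = chunk["class"].value_counts()
            rows.append(
                {
                    "day": int(day),
                    "bin_index": b0 // bin_size,
                    "n_entries": n,
                    "frac_correct": counts.get("correct", 0) / n,
                    "frac_perseverative": counts.get("perseverative", 0) / n,
                    "frac_neutral": counts.get("neutral", 0) / n,
                }
            )
    return LearningCurve(bins=pd.DataFrame(rows), bin_size=bin_size)


def group_learning_curves(curves: dict[str, LearningCurve],
                          min_n: int = 3) -> pd.DataFrame:
    """Average per-bin fractions over animals.

    ``n_animals`` counts the animals contributing to each (day, bin);
    rows are flagged ``display`` only while more than ``min_n`` animals
    contribute, the convention for plotting group curves.
    """
    frames = []
    for animal, c in curves.items():
        df = c.bins.copy()
        df["animal"] = animal
        frames.append(df)
    allb = pd.concat(frames, ignore_index=True)
    agg = (
        allb.groupby(["day", "bin_index"])
        .agg(
            n_animals=("animal", "nunique"),
            frac_correct=("frac_correct", "mean"),
            frac_perseverative=("frac_perseverative", "mean"),
            frac_neutral=("frac_neutral", "mean"),
        )
        .reset_index()
    )
    agg["display"] = agg["n_animals"] > min_n
    return agg


def replay_reward_schedule(log: EntryLog, per_correct: int = 5,
                           reset_daily: bool = True) -> pd.DataFrame:
    """Pellet events from replaying the reward rule over an entry log.

    One pellet per ``per_correct`` cumulative correct entries through the
    day's target; correct entries need not be consecutive.  The counter
    resets at each daily target switch by default (``reset_daily=False``
    carries it over).
    """
    ent = classify_entries(log)
    rows = []
    counter = 0
    current_day = None
    for i, (t, day, cls) in enumerate(zip(ent["time_s"], ent["day"], ent["class"])):
        if reset_daily and day != current_day:
            counter = 0
            current_day = day
        if cls == "correct":
            counter += 1
            if counter % per_correct == 0:
                rows.append({"time_s": t, "day": int(day), "entry_index": i})
    return pd.DataFrame(rows, columns=["time_s", "day", "entry_index"])


@dataclass
class ProbeMetrics:
    """Probe-trial summary: quadrant shares, path to target, interactions."""

    quadrants: pd.DataFrame  # zone_metrics table over the quadrant partition
    target_quadrant: str
    distance_to_target_cm: float
    target_reached: bool
    interactions: InteractionSummary | None = None

    @property
    def target_relative_distance(self) -> float:
        return float(self.quadrants.loc[self.target_quadrant, "relative_distance"])

    @property
    def target_time_fraction(self) -> float:
        return float(self.quadrants.loc[self.target_quadrant, "time_fraction"])


def probe_metrics(
    trace: TrackingTrace,
    geometry: ArenaGeometry,
    target_quadrant: str,
    target_zone: str = "platform",
    keypoints: KeypointTrace | None = None,
    hole_targets: dict[str, Zone] | None = None,
    cfg: SegmentationConfig | None = None,
) -> ProbeMetrics:
    """Quadrant occupancy, distance to first target entry and (optionally)
    target-hole interaction times for a probe trial."""
    quadrant_names = [q for q in ("NW", "NE", "SE", "SW") if q in geometry.zones]
    if target_quadrant not in quadrant_names:
        raise ValueError(f"unknown target quadrant {target_quadrant!r}")
    quads = {q: geometry.zones[q] for q in quadrant_names}
    qm = zone_metrics(trace, quads)
    dist, reached = distance_to_first_entry(trace, geometry.zone(target_zone))
    inter = None
    if keypoints is not None and hole_targets:
        inter = score_interactions(keypoints, hole_targets, cfg)
    return ProbeMetrics(
        quadrants=qm,
        target_quadrant=target_quadrant,
        distance_to_target_cm=dist,
        target_reached=reached,
        interactions=inter,
    )
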