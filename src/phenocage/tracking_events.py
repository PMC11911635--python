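"""Behavioral event extraction from tracking and pose tables.

A :class:`TrackingTrace` is a uniformly sampled 2-D position track.  Each
sample *i* owns the frame ``[i/rate, (i+1)/rate)``, so a trace of *n*
samples covers ``n/rate`` seconds and per-layer event times tile the
trace exactly.  Per-sample speed is the forward-difference displacement
times the sample rate (the last sample inherits the previous step).

Three event layers are derived from a home-cage trace:

* shelter  — maximal runs of samples inside the shelter zone;
* locomotor — outside the shelter, *movements* (speed above ``v_move``
  sustained for at least ``min_move_dur``, merged across short gaps) and
  *arrests* (the complement of movements within non-shelter time);
* activity — movements merged across gaps up to ``activity_merge_gap``;
  activity bouts never span a shelter visit.

Steps that cross the shelter boundary are assigned speed zero so that
movement events live strictly outside the shelter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import ArenaGeometry, DiscZone, LightCycle, QuadrantZone, RectZone, Zone

__all__ = [
    "TrackingTrace",
    "KeypointTrace",
    "EventLog",
    "SegmentationConfig",
    "InteractionSummary",
    "QCError",
    "segment_events",
    "detect_freezing",
    "zone_metrics",
    "distance_to_first_entry",
    "score_interactions",
    "qc_check",
]

BODYPARTS = ("nose", "head", "ear_left", "ear_right", "shoulders", "back", "tail")

EVENT_COLUMNS = ["layer", "kind", "start", "end", "distance"]


class QCError(ValueError):
    """Raised when a trace fails quality control."""


@dataclass
class TrackingTrace:
    """Uniformly sampled 2-D position with optional zone labels."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sample_rate: float
    zone: np.ndarray | None = None
    arena: ArenaGeometry | None = None
    lightcycle: LightCycle | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise ValueError("times, x and y must have equal length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if np.any(np.abs(dt - 1.0 / self.sample_rate) > 0.05 / self.sample_rate):
                raise ValueError("times must lie on a uniform grid of 1/sample_rate")

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        """Trace duration in seconds (each sample owns one frame)."""
        return self.n_samples / self.sample_rate

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.x) & np.isfinite(self.y)

    def step_lengths(self) -> np.ndarray:
        """Per-step displacement (cm), length n-1; NaN where a sample is lost."""
        return np.hypot(np.diff(self.x), np.diff(self.y))

    def speeds(self) -> np.ndarray:
        """Per-sample speed (cm/s); the last sample repeats the last step."""
        if self.n_samples < 2:
            return np.zeros(self.n_samples)
        s = self.step_lengths() * self.sample_rate
        return np.concatenate([s, s[-1:]])


@dataclass
class KeypointTrace:
    """Per-frame body-part coordinates with detection confidences."""

    coords: dict[str, np.ndarray]  # bodypart -> (n, 2) cm
    confidence: dict[str, np.ndarray]  # bodypart -> (n,) in [0, 1]
    sample_rate: float

    def __post_init__(self) -> None:
        lengths = set()
        for part, xy in self.coords.items():
            xy = np.asarray(xy, dtype=float)
            if xy.ndim != 2 or xy.shape[1] != 2:
                raise ValueError(f"coords[{part!r}] must be (n, 2)")
            self.coords[part] = xy
            lengths.add(len(xy))
            conf = np.asarray(self.confidence.get(part, np.ones(len(xy))), dtype=float)
            if np.any((conf < 0) | (conf > 1)):
                raise ValueError("confidence must lie in [0, 1]")
            self.confidence[part] = conf
            lengths.add(len(conf))
        if len(lengths) > 1:
            raise ValueError("all body parts must have the same frame count")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.coords.values()))) if self.coords else 0

    def body_center(self) -> np.ndarray:
        """Centroid of shoulders/back keypoints, (n, 2)."""
        parts = [p for p in ("shoulders", "back") if p in self.coords]
        if not parts:
            raise ValueError("body_center needs shoulders and/or back keypoints")
        return np.mean([self.coords[p] for p in parts], axis=0)


@dataclass
class EventLog:
    """Ordered behavioral events over the layers locomotor/shelter/activity."""

    events: pd.DataFrame
    sample_rate: float | None = None

    def __post_init__(self) -> None:
        ev = self.events
        missing = [c for c in EVENT_COLUMNS if c not in ev.columns]
        if missing:
            raise ValueError(f"event table lacks columns {missing}")
        if len(ev):
            if not (ev["end"] > ev["start"]).all():
                raise ValueError("events must have end > start")
            for _, grp in ev.groupby("layer"):
                s = grp.sort_values("start")
                if (s["start"].values[1:] < s["end"].values[:-1] - 1e-9).any():
                    raise ValueError("events overlap within a layer")
        self.events = ev.sort_values(["start", "layer"], kind="stable").reset_index(drop=True)

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.events[self.events["kind"] == kind].reset_index(drop=True)

    def durations(self, kind: str) -> np.ndarray:
        ev = self.of_kind(kind)
        return (ev["end"] - ev["start"]).to_numpy()

    def distances(self, kind: str = "movement") -> np.ndarray:
        return self.of_kind(kind)["distance"].to_numpy()

    def total_time(self, kind: str) -> float:
        return float(self.durations(kind).sum())

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds for event segmentation; all in cm/s and seconds.

    The tracking-software thresholds behind published home-cage studies
    are not public; these defaults are conventional for mouse tracking
    and every derived metric takes the config explicitly.
    """

    v_move: float = 2.0
    v_freeze: float = 1.0
    min_move_dur: float = 0.5
    min_freeze_dur: float = 1.0
    merge_gap: float = 0.5
    activity_merge_gap: float = 5.0
    proximity_radius: float = 2.0
    min_conf: float = 0.6
    min_conf_fraction: float = 0.2
    max_gap: float = 1.0
    max_missing: float = 0.2


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index intervals [start, stop)."""
    if mask.size == 0:
        return []
    m = mask.astype(np.int8)
    d = np.diff(m)
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        stops.append(len(m))
    return list(zip(starts, stops))


def _merge_runs(runs: list[tuple[int, int]], max_gap_frames: int,
                barrier: np.ndarray | None = None) -> list[tuple[int, int]]:
    """Merge runs separated by <= max_gap_frames, never across a barrier sample."""
    if not runs:
        return []
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        gap = s - merged[-1][1]
        blocked = barrier is not None and bool(barrier[merged[-1][1]:s].any())
        if gap <= max_gap_frames and not blocked:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def qc_check(trace: TrackingTrace, cfg: SegmentationConfig) -> dict:
    """Missing-frame summary; raises :class:`QCError` above ``max_missing``."""
    valid = trace.valid_mask()
    lost = ~valid
    gaps = _runs(lost)
    frac = float(lost.mean()) if len(lost) else 0.0
    spans = [(s / trace.sample_rate, e / trace.sample_rate) for s, e in gaps]
    if frac > cfg.max_missing:
        raise QCError(
            f"{frac:.1%} of frames lost (max {cfg.max_missing:.1%}); "
            f"offending spans (s): {spans}"
        )
    return {"lost_fraction": frac, "n_gaps": len(gaps), "gap_spans_s": spans}


def _shelter_mask(trace: TrackingTrace, shelter_zone_name: str = "shelter") -> np.ndarray:
    if trace.zone is not None:
        return np.asarray(trace.zone) == shelter_zone_name
    if trace.arena is not None and shelter_zone_name in trace.arena.zones:
        z = trace.arena.zones[shelter_zone_name]
        return np.asarray(z.contains(trace.x, trace.y))
    return np.zeros(trace.n_samples, dtype=bool)


def segment_events(trace: TrackingTrace, cfg: SegmentationConfig | None = None,
                   shelter_zone: str = "shelter") -> EventLog:
    """Segment a home-cage trace into shelter / locomotor / activity layers."""
    cfg = cfg or SegmentationConfig()
    qc_check(trace, cfg)
    rate = trace.sample_rate
    n = trace.n_samples
    if n == 0:
        raise ValueError("empty trace")
    valid = trace.valid_mask()
    shelter = _shelter_mask(trace, shelter_zone) & valid
    outside = valid & ~shelter

    # per-sample locomotor speed; boundary-crossing or invalid steps -> 0
    speed = np.zeros(n)
    if n > 1:
        step = trace.step_lengths() * rate
        ok = outside[:-1] & outside[1:] & np.isfinite(step)
        speed[:-1] = np.where(ok, step, 0.0)
        speed[-1] = speed[-2] if outside[-1] else 0.0

    rows: list[tuple] = []
    for s, e in _runs(shelter):
        rows.append(("shelter", "shelter_visit", s / rate, e / rate, np.nan))

    min_move_frames = max(1, int(round(cfg.min_move_dur * rate)))
    merge_frames = int(round(cfg.merge_gap * rate))
    act_merge_frames = int(round(cfg.activity_merge_gap * rate))
    step_len = trace.step_lengths() if n > 1 else np.zeros(0)

    move_runs_all: list[tuple[int, int]] = []
    for a, b in _runs(outside):
        moving = outside.copy()
        moving[:] = False
        moving[a:b] = speed[a:b] >= cfg.v_move
        runs = _runs(moving)
        runs = _merge_runs(runs, merge_frames)
        runs = [(s, e) for s, e in runs if (e - s) >= min_move_frames]
        move_runs_all.extend(runs)
        # arrests: complement of movements within this outside run
        cursor = a
        for s, e in runs:
            dist = float(np.nansum(step_len[s:e])) if e > s else 0.0
            rows.append(("locomotor", "movement", s / rate, e / rate, dist))
            if s > cursor:
                rows.append(("locomotor", "arrest", cursor / rate, s / rate, np.nan))
            cursor = e
        if b > cursor:
            rows.append(("locomotor", "arrest", cursor / rate, b / rate, np.nan))

    move_runs_all.sort()
    for s, e in _merge_runs(move_runs_all, act_merge_frames, barrier=shelter):
        rows.append(("activity", "activity_bout", s / rate, e / rate, np.nan))

    ev = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return EventLog(ev, sample_rate=rate)


def detect_freezing(trace: TrackingTrace, cfg: SegmentationConfig | None = None,
                    bin_s: float = 60.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Freezing intervals and percent time frozen per 60-s bin.

    Freezing is speed below ``v_freeze`` sustained for at least
    ``min_freeze_dur``.  The trailing partial bin is reported with its
    own duration.
    """
    cfg = cfg or SegmentationConfig()
    if trace.n_samples == 0:
        raise ValueError("empty trace")
    if trace.duration < bin_s:
        raise ValueError("trace must cover at least one bin")
    rate = trace.sample_rate
    frozen = trace.speeds() < cfg.v_freeze
    min_frames = max(1, int(round(cfg.min_freeze_dur * rate)))
    runs = [(s, e) for s, e in _runs(frozen) if (e - s) >= min_frames]
    intervals = pd.DataFrame(
        [(s / rate, e / rate) for s, e in runs], columns=["start", "end"]
    )

    total = trace.duration
    edges = np.arange(0.0, total, bin_s)
    starts = edges
    ends = np.minimum(edges + bin_s, total)
    frozen_in_bin = np.zeros(len(starts))
    for s, e in runs:
        t0, t1 = s / rate, e / rate
        lo = np.maximum(starts, t0)
        hi = np.minimum(ends, t1)
        frozen_in_bin += np.clip(hi - lo, 0.0, None)
    bins = pd.DataFrame(
        {
            "bin_start": starts,
            "bin_duration": ends - starts,
            "percent_frozen": 100.0 * frozen_in_bin / (ends - starts),
        }
    )
    return intervals, bins


def _zone_masks(trace: TrackingTrace, zones: dict[str, Zone]) -> dict[str, np.ndarray]:
    if trace.arena is not None:
        for name, z in zones.items():
            cx, cy = z.center
            if not bool(trace.arena.contains(cx, cy)):
                raise ValueError(f"zone {name!r} lies outside the arena")
    return {name: np.asarray(z.contains(trace.x, trace.y)) for name, z in zones.items()}


def zone_metrics(trace: TrackingTrace, zones: dict[str, Zone],
                 v_move: float = 2.0) -> pd.DataFrame:
    """Per-zone occupancy and locomotion metrics.

    Time is counted per sample; the displacement of step *i* is
    attributed to the zone of sample *i*.  ``relative_distance`` is the
    zone distance over total trace distance, so it sums to one over a
    partition of the arena.
    """
    n = trace.n_samples
    if n == 0:
        raise ValueError("empty trace")
    rate = trace.sample_rate
    steps = trace.step_lengths() if n > 1 else np.zeros(0)
    steps = np.nan_to_num(steps)
    total_dist = float(steps.sum())
    speed = trace.speeds()
    out = []
    for name, mask in _zone_masks(trace, zones).items():
        time_s = mask.sum() / rate
        dist = float(steps[mask[:-1]].sum()) if n > 1 else 0.0
        entries = int((mask[1:] & ~mask[:-1]).sum() + (1 if mask[0] else 0))
        sp = speed[mask]
        out.append(
            {
                "zone": name,
                "time_s": time_s,
                "time_fraction": time_s / trace.duration,
                "distance_cm": dist,
                "relative_distance": dist / total_dist if total_dist > 0 else np.nan,
                "entries": entries,
                "mean_speed_cms": float(sp.mean()) if sp.size else np.nan,
                "moving_fraction": float((sp >= v_move).mean()) if sp.size else np.nan,
            }
        )
    return pd.DataFrame(out).set_index("zone")


def distance_to_first_entry(trace: TrackingTrace, target: Zone) -> tuple[float, bool]:
    """Cumulative path length until the first sample inside ``target``.

    Returns total path length with ``reached=False`` when the target is
    never visited.
    """
    inside = np.asarray(target.contains(trace.x, trace.y))
    steps = np.nan_to_num(trace.step_lengths()) if trace.n_samples > 1 else np.zeros(0)
    hits = np.flatnonzero(inside)
    if hits.size == 0:
        return float(steps.sum()), False
    k = int(hits[0])
    return float(steps[:k].sum()), True


def _distance_to_zone(z: Zone, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Euclidean distance from points to the zone boundary (0 inside)."""
    if isinstance(z, (DiscZone, QuadrantZone)):
        d = np.hypot(x - z.cx, y - z.cy) - z.radius
        return np.clip(d, 0.0, None)
    if isinstance(z, RectZone):
        dx = np.clip(np.maximum(z.x0 - x, x - z.x1), 0.0, None)
        dy = np.clip(np.maximum(z.y0 - y, y - z.y1), 0.0, None)
        return np.hypot(dx, dy)
    raise TypeError(f"unsupported zone type {type(z).__name__}")


@dataclass
class InteractionSummary:
    """Per-target nose-proximity interaction times."""

    seconds: dict[str, float]
    frames: dict[str, int]
    valid_fraction: float
    sample_rate: float


def score_interactions(kp: KeypointTrace, targets: dict[str, Zone],
                       cfg: SegmentationConfig | None = None) -> InteractionSummary:
    """Interaction time per target: nose within ``proximity_radius`` of the
    target boundary.  Frames with nose confidence below ``min_conf`` are
    excluded from both numerator and denominator."""
    cfg = cfg or SegmentationConfig()
    if "nose" not in kp.coords:
        raise ValueError("keypoint trace lacks a nose")
    names = list(targets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ax, ay = targets[a].center
            if bool(targets[b].contains(ax, ay)):
                raise ValueError(f"target zones {a!r} and {b!r} overlap")
    nose = kp.coords["nose"]
    conf = kp.confidence["nose"]
    ok = conf >= cfg.min_conf
    frac = float(ok.mean()) if ok.size else 0.0
    if frac < cfg.min_conf_fraction:
        raise QCError(
            f"only {frac:.1%} of frames have nose confidence >= {cfg.min_conf}"
        )
    seconds: dict[str, float] = {}
    frames: dict[str, int] = {}
    for name, z in targets.items():
        d = _distance_to_zone(z, nose[:, 0], nose[:, 1])
        near = ok & (d <= cfg.proximity_radius)
        frames[name] = int(near.sum())
        seconds[name] = frames[name] / kp.sample_rate
    return InteractionSummary(seconds, frames, frac, kp.sample_rate)
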