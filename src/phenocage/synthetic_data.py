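"""Synthetic behavior with exact ground truth.

The generator emulates the statistical structure home-cage phenotyping
assumes, without claiming biomechanical realism:

* activity bouts as a Poisson process per light/dark phase (lognormal
  durations), with multiplicative rate modulation in the two hours
  before and after each light switch;
* shelter-visit durations drawn from a 3-component Gaussian mixture on
  the log2-seconds scale, movement distances from a 2-component mixture
  on log2-centimetres, and within-bout arrest gaps from a lognormal;
* positions rendered on the exact frame grid: a bounded random walk
  during movements, constant position during arrests and shelter visits.

All event boundaries are snapped to frames, so event segmentation can be
validated exactly against the returned ground-truth log.  Every
simulation takes an explicit seed; there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import ArenaGeometry, DiscZone, LightCycle, RectZone, Zone, phenotyper_arena, water_maze_arena
from .task_metrics import EntryLog, TargetSchedule
from .tracking_events import (
    EVENT_COLUMNS,
    EventLog,
    KeypointTrace,
    SegmentationConfig,
    TrackingTrace,
)

__all__ = [
    "Log2Mixture",
    "HomecageSimSpec",
    "AgentSpec",
    "CohortSpec",
    "SimSpecError",
    "simulate_homecage_events",
    "simulate_homecage_trace",
    "sample_shelter_visits",
    "simulate_entry_log",
    "simulate_interaction_session",
    "simulate_cohort",
    "simulate_random_walk_trace",
]

HOLES = ("left", "middle", "right")


class SimSpecError(ValueError):
    """Raised for invalid simulation specifications."""


@dataclass(frozen=True)
class Log2Mixture:
    """Gaussian mixture on a log2-transformed scale."""

    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]

    def __post_init__(self) -> None:
        k = len(self.weights)
        if not (len(self.means) == len(self.sds) == k and k >= 1):
            raise SimSpecError("mixture fields must have equal length >= 1")
        if abs(sum(self.weights) - 1.0) > 1e-9 or any(w < 0 for w in self.weights):
            raise SimSpecError("mixture weights must be non-negative and sum to 1")
        if any(s <= 0 for s in self.sds):
            raise SimSpecError("mixture sds must be positive")

    @property
    def k(self) -> int:
        return len(self.weights)

    def sample(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """n raw-scale draws and their generating component indices."""
        comp = rng.choice(self.k, size=n, p=np.asarray(self.weights))
        log2v = rng.normal(np.asarray(self.means)[comp], np.asarray(self.sds)[comp])
        return np.power(2.0, log2v), comp


# Defaults describe a nocturnal mouse in a 30x30 cm automated home cage:
# most activity in the dark phase, long day-time shelter stays, activity
# ramping up before dark onset and dropping after lights-on.
DEFAULT_SHELTER_MIXTURE = Log2Mixture((0.3, 0.4, 0.3), (4.0, 7.0, 11.0), (0.5, 0.5, 0.5))
DEFAULT_MOVEMENT_MIXTURE = Log2Mixture((0.5, 0.5), (2.0, 5.0), (0.5, 0.5))


@dataclass(frozen=True)
class HomecageSimSpec:
    """Conditions for a continuous home-cage simulation."""

    seed: int
    duration_days: int = 3
    sample_rate: float = 20.0
    lightcycle: LightCycle = field(default_factory=LightCycle)
    activity_bout_rate_per_phase: dict[str, float] = field(
        default_factory=lambda: {"dark": 20.0, "light": 4.0}
    )  # bouts per hour
    activity_bout_duration: tuple[float, float] = (math.log(40.0), 0.5)  # lognormal (s)
    anticipation_response_modulation: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "to_dark": {"anticipation": 1.5, "response": 1.8},
            "to_light": {"anticipation": 1.2, "response": 0.6},
        }
    )
    shelter_visit_log2_mixture: Log2Mixture = DEFAULT_SHELTER_MIXTURE
    movement_log2_mixture: Log2Mixture = DEFAULT_MOVEMENT_MIXTURE
    arrest_duration: tuple[float, float] = (math.log(2.0), 0.6)  # lognormal (s)
    shelter_visit_rate_per_phase: dict[str, float] = field(
        default_factory=lambda: {"dark": 2.0, "light": 5.0}
    )  # entries per hour of time spent outside
    move_speed: float = 8.0  # cm/s along the rendered path
    position_jitter: float = 0.0  # cm of noise on resting positions

    def __post_init__(self) -> None:
        if self.duration_days < 1:
            raise SimSpecError("duration_days must be >= 1")
        if self.sample_rate <= 0:
            raise SimSpecError("sample_rate must be positive")
        for d in (self.activity_bout_rate_per_phase, self.shelter_visit_rate_per_phase):
            if set(d) != {"dark", "light"} or any(v < 0 for v in d.values()):
                raise SimSpecError("per-phase rates need non-negative dark and light entries")
        for sw in ("to_dark", "to_light"):
            m = self.anticipation_response_modulation.get(sw, {})
            if any(v < 0 for v in m.values()):
                raise SimSpecError("modulation factors must be non-negative")
        if self.move_speed <= 0:
            raise SimSpecError("move_speed must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_days * 86400 * self.sample_rate))

    @property
    def arena(self) -> ArenaGeometry:
        return phenotyper_arena()


def _modulation(spec: HomecageSimSpec, t_s: float) -> float:
    """Bout-rate factor at time t: anticipation/response windows around switches."""
    lc = spec.lightcycle
    h = float(lc.clock_hour(t_s))
    mod = spec.anticipation_response_modulation
    on, off = lc.lights_on, lc.lights_off
    if (h - on) % 24.0 < 2.0:
        return mod.get("to_light", {}).get("response", 1.0)
    if (on - h) % 24.0 <= 2.0:
        return mod.get("to_light", {}).get("anticipation", 1.0)
    if (h - off) % 24.0 < 2.0:
        return mod.get("to_dark", {}).get("response", 1.0)
    if (off - h) % 24.0 <= 2.0:
        return mod.get("to_dark", {}).get("anticipation", 1.0)
    return 1.0


def _fill_bout_movements(spec: HomecageSimSpec, s: int, e: int,
                         rng: np.random.Generator,
                         seg_cfg: SegmentationConfig) -> list[tuple[int, int, float, int]]:
    """Movements (start_f, end_f, distance_cm, component) inside bout frames [s, e)."""
    rate = spec.sample_rate
    min_frames = int(round(seg_cfg.min_move_dur * rate)) + 1
    gap_lo = int(math.floor(seg_cfg.merge_gap * rate)) + 2
    gap_hi = max(gap_lo, int(math.floor(seg_cfg.activity_merge_gap * rate)) - 2)
    out = []
    f = s
    while f < e:
        d, comp = spec.movement_log2_mixture.sample(1, rng)
        d = float(d[0])
        # keep per-frame speed above the movement threshold at the floor duration
        d_min = seg_cfg.v_move * (min_frames + 1) / rate
        d = max(d, d_min)
        nf = int(round(max(d / spec.move_speed, (min_frames) / rate) * rate))
        nf = min(nf, int(math.floor(d * rate / seg_cfg.v_move)) - 1)
        nf = max(nf, min_frames)
        if f + nf > e:
            break
        out.append((f, f + nf, d, int(comp[0])))
        gap = int(round(rng.lognormal(*spec.arrest_duration) * rate))
        gap = int(np.clip(gap, gap_lo, gap_hi))
        f += nf + gap
    return out


def simulate_homecage_events(spec: HomecageSimSpec,
                             seg_cfg: SegmentationConfig | None = None) -> EventLog:
    """Ground-truth event log for a home-cage simulation.

    The returned log carries ``component`` (generating mixture component
    for shelter visits and movements) and ``truncated`` columns in
    addition to the standard event fields.
    """
    seg_cfg = seg_cfg or SegmentationConfig()
    rng = np.random.default_rng(spec.seed)
    rate = spec.sample_rate
    T = spec.n_samples
    bout_gap = int(math.ceil(seg_cfg.activity_merge_gap * rate)) + 2

    mods = [
        v
        for m in spec.anticipation_response_modulation.values()
        for v in m.values()
    ] or [1.0]
    max_bout_rate = max(spec.activity_bout_rate_per_phase.values()) * max(mods + [1.0])

    shelter_rows: list[tuple[int, int, int, bool]] = []  # (s, e, comp, truncated)
    outside_segments: list[tuple[int, int]] = []

    f = 0
    while f < T:
        phase = str(spec.lightcycle.phase(f / rate))
        sh_rate = spec.shelter_visit_rate_per_phase[phase]
        if sh_rate > 0:
            wait_s = rng.exponential(3600.0 / sh_rate)
            w = max(1, int(round(wait_s * rate)))
        else:
            w = T - f
        seg_end = min(f + w, T)
        if seg_end > f:
            outside_segments.append((f, seg_end))
        f = seg_end
        if f >= T:
            break
        dur, comp = spec.shelter_visit_log2_mixture.sample(1, rng)
        nf = max(1, int(round(float(dur[0]) * rate)))
        end = min(f + nf, T)
        shelter_rows.append((f, end, int(comp[0]), end < f + nf))
        f = end

    movements: list[tuple[int, int, float, int]] = []
    bouts: list[tuple[int, int]] = []
    for a, b in outside_segments:
        if max_bout_rate <= 0:
            continue
        f = a
        while f < b:
            wait_s = rng.exponential(3600.0 / max_bout_rate)
            f += max(1, int(round(wait_s * rate)))
            if f >= b:
                break
            lam = (
                spec.activity_bout_rate_per_phase[str(spec.lightcycle.phase(f / rate))]
                * _modulation(spec, f / rate)
            )
            if rng.uniform() >= lam / max_bout_rate:
                continue
            dur_s = rng.lognormal(*spec.activity_bout_duration)
            bout_end = min(f + max(1, int(round(dur_s * rate))), b)
            mv = _fill_bout_movements(spec, f, bout_end, rng, seg_cfg)
            if mv:
                movements.extend(mv)
                bouts.append((mv[0][0], mv[-1][1]))
            f = bout_end + bout_gap

    rows: list[dict] = []
    for s, e, comp, trunc in shelter_rows:
        rows.append(
            dict(layer="shelter", kind="shelter_visit", start=s / rate, end=e / rate,
                 distance=np.nan, component=comp, truncated=trunc)
        )
    for a, b in outside_segments:
        cursor = a
        for s, e, d, comp in [m for m in movements if a <= m[0] < b]:
            if s > cursor:
                rows.append(dict(layer="locomotor", kind="arrest", start=cursor / rate,
                                 end=s / rate, distance=np.nan, component=-1,
                                 truncated=False))
            rows.append(dict(layer="locomotor", kind="movement", start=s / rate,
                             end=e / rate, distance=d, component=comp, truncated=False))
            cursor = e
        if b > cursor:
            rows.append(dict(layer="locomotor", kind="arrest", start=cursor / rate,
                             end=b / rate, distance=np.nan, component=-1,
                             truncated=False))
    for s, e in bouts:
        rows.append(dict(layer="activity", kind="activity_bout", start=s / rate,
                         end=e / rate, distance=np.nan, component=-1, truncated=False))

    ev = pd.DataFrame(rows, columns=EVENT_COLUMNS + ["component", "truncated"])
    return EventLog(ev, sample_rate=rate)


def _render_movement(pos: np.ndarray, nf: int, dist: float, rng: np.random.Generator,
                     lo: float, hi_x: float, hi_y: float,
                     shelter: RectZone) -> np.ndarray:
    """Random-walk path of ``nf`` equal steps totalling ``dist`` cm.

    Stays inside [lo, hi] x [lo, hi] and outside the shelter rectangle.
    """
    step = dist / nf
    path = np.empty((nf, 2))
    # fast path: accept a free walk if it never leaves the allowed region
    ang = rng.uniform(0, 2 * np.pi, size=nf)
    trial = pos + np.cumsum(
        np.column_stack([np.cos(ang), np.sin(ang)]) * step, axis=0
    )
    ok = (
        (trial[:, 0] >= lo).all()
        and (trial[:, 0] <= hi_x).all()
        and (trial[:, 1] >= lo).all()
        and (trial[:, 1] <= hi_y).all()
        and not bool(shelter.contains(trial[:, 0], trial[:, 1]).any())
    )
    if ok:
        return trial
    p = pos.copy()
    for i in range(nf):
        a = rng.uniform(0, 2 * np.pi)
        for attempt in range(64):
            q = p + step * np.array([math.cos(a), math.sin(a)])
            if (
                lo <= q[0] <= hi_x
                and lo <= q[1] <= hi_y
                and not bool(shelter.contains(q[0], q[1]))
            ):
                break
            a += 2.399963  # golden-angle scan of directions
        p = q
        path[i] = p
    return path


def simulate_homecage_trace(
    spec: HomecageSimSpec, seg_cfg: SegmentationConfig | None = None
) -> tuple[TrackingTrace, EventLog]:
    """Render a full position trace plus its ground-truth event log."""
    seg_cfg = seg_cfg or SegmentationConfig()
    events = simulate_homecage_events(spec, seg_cfg)
    rate = spec.sample_rate
    n = spec.n_samples
    arena = spec.arena
    shelter = arena.zones["shelter"]
    assert isinstance(shelter, RectZone)
    scx, scy = shelter.center
    margin = 1.0
    lo = margin
    hi_x = arena.bounds.x1 - margin  # type: ignore[union-attr]
    hi_y = arena.bounds.y1 - margin  # type: ignore[union-attr]

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1]))
    x = np.empty(n)
    y = np.empty(n)
    # rest position well away from the shelter corner
    pos = np.array([arena.bounds.x1 * 0.6, arena.bounds.y1 * 0.4])  # type: ignore[union-attr]
    cursor = 0

    def hold(upto: int) -> None:
        nonlocal cursor
        if upto > cursor:
            x[cursor:upto] = pos[0]
            y[cursor:upto] = pos[1]
            cursor = upto

    ev = events.events.sort_values("start", kind="stable")
    for row in ev.itertuples():
        s = int(round(row.start * rate))
        e = int(round(row.end * rate))
        if row.kind == "shelter_visit":
            hold(s)
            x[s:e] = scx
            y[s:e] = scy
            cursor = e  # resting position outside is restored on exit
        elif row.kind == "movement":
            hold(s)
            path = _render_movement(pos, e - s, float(row.distance), rng,
                                    lo, hi_x, hi_y, shelter)
            x[s:e] = path[:, 0]
            y[s:e] = path[:, 1]
            pos = path[-1].copy()
            cursor = e
    hold(n)

    if spec.position_jitter > 0:
        jitter = rng.normal(0.0, spec.position_jitter, size=(n, 2))
        x = np.clip(x + jitter[:, 0], 0.0, arena.bounds.x1)  # type: ignore[union-attr]
        y = np.clip(y + jitter[:, 1], 0.0, arena.bounds.y1)  # type: ignore[union-attr]

    trace = TrackingTrace(
        times=np.arange(n) / rate,
        x=x,
        y=y,
        sample_rate=rate,
        arena=arena,
        lightcycle=spec.lightcycle,
    )
    return trace, events


def sample_shelter_visits(spec: HomecageSimSpec, n_visits: int,
                          seed: int | None = None) -> pd.DataFrame:
    """Draw shelter-visit durations directly from the spec's mixture.

    Convenience sampler for estimator studies that need many visits
    without rendering days of trace.  Columns: duration_s,
    log2_duration, component.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    vals, comp = spec.shelter_visit_log2_mixture.sample(n_visits, rng)
    return pd.DataFrame(
        {"duration_s": vals, "log2_duration": np.log2(vals), "component": comp}
    )


@dataclass(frozen=True)
class AgentSpec:
    """Stochastic policy for the 3-choice cognition-wall task."""

    seed: int
    p_correct: float = 0.7
    perseveration_weight: float = 0.5
    entries_per_hour_profile: float | tuple[float, ...] = 12.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_correct <= 1.0:
            raise SimSpecError("p_correct must lie in [0, 1]")
        if not 0.0 <= self.perseveration_weight <= 1.0:
            raise SimSpecError("perseveration_weight must lie in [0, 1]")

    def rate_at_hour(self, hour_of_day: int) -> float:
        p = self.entries_per_hour_profile
        if isinstance(p, (int, float)):
            return float(p)
        return float(p[hour_of_day % len(p)])


def simulate_entry_log(agent: AgentSpec, schedule: TargetSchedule,
                       duration_s: float | None = None) -> EntryLog:
    """Entry log for a simulated agent under a daily target schedule."""
    if not schedule.targets:
        raise SimSpecError("empty target schedule")
    rng = np.random.default_rng(agent.seed)
    total = schedule.n_days * schedule.day_length_s if duration_s is None else duration_s
    if total > schedule.n_days * schedule.day_length_s + 1e-9:
        raise SimSpecError("schedule does not cover the simulated span")
    times: list[float] = []
    holes: list[str] = []
    n_hours = int(math.ceil(total / 3600.0))
    for h in range(n_hours):
        t0 = h * 3600.0
        t1 = min(t0 + 3600.0, total)
        lam = agent.rate_at_hour(h % 24) * (t1 - t0) / 3600.0
        k = rng.poisson(lam)
        ts = np.sort(rng.uniform(t0, t1, size=k))
        for t in ts:
            day = min(int(t // schedule.day_length_s), schedule.n_days - 1)
            target = schedule.targets[day]
            prev = schedule.previous_target(day)
            if rng.uniform() < agent.p_correct:
                hole = target
            else:
                others = [hh for hh in HOLES if hh != target]
                if prev is not None and prev != target:
                    neutral = [hh for hh in others if hh != prev]
                    if rng.uniform() < agent.perseveration_weight:
                        hole = prev
                    else:
                        hole = neutral[0] if neutral else prev
                else:
                    hole = others[int(rng.integers(len(others)))]
            times.append(float(t))
            holes.append(hole)
    entries = pd.DataFrame({"time_s": times, "hole": holes})
    return EntryLog(entries, schedule)


def simulate_interaction_session(
    targets: dict[str, Zone],
    script: list[tuple[float, float, str]],
    duration_s: float = 300.0,
    sample_rate: float = 20.0,
    seed: int = 0,
    cfg: SegmentationConfig | None = None,
) -> tuple[KeypointTrace, dict[str, float]]:
    """Keypoint session with scripted nose-at-target approaches.

    ``script`` is a list of (start_s, end_s, target_name); outside
    scripted windows the nose sits at a neutral point beyond every
    proximity radius.  Returns the trace and the frame-quantized
    ground-truth interaction seconds per target.
    """
    cfg = cfg or SegmentationConfig()
    names = list(targets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ax, ay = targets[a].center
            if bool(targets[b].contains(ax, ay)):
                raise SimSpecError(f"target zones {a!r} and {b!r} overlap")
    n = int(round(duration_s * sample_rate))
    for s, e, name in script:
        if not (0 <= s < e <= duration_s + 1e-9):
            raise SimSpecError("script window outside the session")
        if name not in targets:
            raise SimSpecError(f"unknown script target {name!r}")

    xs = np.array([z.center[0] for z in targets.values()] or [0.0])
    ys = np.array([z.center[1] for z in targets.values()] or [0.0])
    neutral = np.array([xs.max() + 100.0, ys.max() + 100.0])

    nose = np.tile(neutral, (n, 1))
    truth = {name: 0.0 for name in targets}
    for s, e, name in script:
        fs, fe = int(round(s * sample_rate)), int(round(e * sample_rate))
        cx, cy = targets[name].center
        nose[fs:fe] = (cx, cy)
        truth[name] += (fe - fs) / sample_rate

    rng = np.random.default_rng(seed)
    coords = {"nose": nose}
    conf = {"nose": np.ones(n)}
    heading = rng.uniform(0, 2 * np.pi)
    offsets = {
        "head": 1.0, "ear_left": 1.3, "ear_right": 1.3,
        "shoulders": 2.0, "back": 3.5, "tail": 6.0,
    }
    for part, off in offsets.items():
        coords[part] = nose + off * np.array([-math.cos(heading), -math.sin(heading)])
        conf[part] = np.ones(n)
    kp = KeypointTrace(coords=coords, confidence=conf, sample_rate=sample_rate)
    return kp, truth


@dataclass(frozen=True)
class CohortSpec:
    """Multi-group cohort: (label, n, per-parameter offsets) over a base spec."""

    seed: int
    base_spec: HomecageSimSpec
    groups: tuple[tuple[str, int, dict[str, float]], ...]

    def __post_init__(self) -> None:
        labels = [g[0] for g in self.groups]
        if len(set(labels)) != len(labels):
            raise SimSpecError("group labels must be unique")
        if any(g[1] < 1 for g in self.groups):
            raise SimSpecError("each group needs n >= 1")


_OFFSET_KNOBS = frozenset(
    {
        "activity_bout_rate_dark",
        "activity_bout_rate_light",
        "shelter_rate_dark",
        "shelter_rate_light",
        "bout_duration_mu",
        "arrest_mu",
        "shelter_mu1",
        "shelter_mu2",
        "shelter_mu3",
        "movement_mu1",
        "movement_mu2",
        "mod_to_dark_anticipation",
        "mod_to_dark_response",
        "mod_to_light_anticipation",
        "mod_to_light_response",
    }
)


def apply_offsets(base: HomecageSimSpec, offsets: dict[str, float],
                  seed: int) -> HomecageSimSpec:
    """Additive offsets on named generator knobs, new seed."""
    unknown = set(offsets) - _OFFSET_KNOBS
    if unknown:
        raise SimSpecError(f"unknown offset knobs: {sorted(unknown)}")
    bout = dict(base.activity_bout_rate_per_phase)
    sh_rate = dict(base.shelter_visit_rate_per_phase)
    bout["dark"] = max(0.0, bout["dark"] + offsets.get("activity_bout_rate_dark", 0.0))
    bout["light"] = max(0.0, bout["light"] + offsets.get("activity_bout_rate_light", 0.0))
    sh_rate["dark"] = max(0.0, sh_rate["dark"] + offsets.get("shelter_rate_dark", 0.0))
    sh_rate["light"] = max(0.0, sh_rate["light"] + offsets.get("shelter_rate_light", 0.0))
    bd = (base.activity_bout_duration[0] + offsets.get("bout_duration_mu", 0.0),
          base.activity_bout_duration[1])
    ar = (base.arrest_duration[0] + offsets.get("arrest_mu", 0.0),
          base.arrest_duration[1])
    sm = base.shelter_visit_log2_mixture
    sh_mix = Log2Mixture(
        sm.weights,
        tuple(
            m + offsets.get(f"shelter_mu{i + 1}", 0.0) for i, m in enumerate(sm.means)
        ),
        sm.sds,
    )
    mm = base.movement_log2_mixture
    mv_mix = Log2Mixture(
        mm.weights,
        tuple(
            m + offsets.get(f"movement_mu{i + 1}", 0.0) for i, m in enumerate(mm.means)
        ),
        mm.sds,
    )
    mod = {sw: dict(w) for sw, w in base.anticipation_response_modulation.items()}
    for sw in ("to_dark", "to_light"):
        for win in ("anticipation", "response"):
            key = f"mod_{sw}_{win}"
            if key in offsets:
                mod.setdefault(sw, {})[win] = max(
                    0.0, mod.get(sw, {}).get(win, 1.0) + offsets[key]
                )
    return replace(
        base,
        seed=seed,
        activity_bout_rate_per_phase=bout,
        shelter_visit_rate_per_phase=sh_rate,
        activity_bout_duration=bd,
        arrest_duration=ar,
        shelter_visit_log2_mixture=sh_mix,
        movement_log2_mixture=mv_mix,
        anticipation_response_modulation=mod,
    )


@dataclass
class CohortAnimal:
    animal_id: str
    group: str
    spec: HomecageSimSpec
    offsets: dict[str, float]
    events: EventLog
    trace: TrackingTrace | None = None


def simulate_cohort(spec: CohortSpec, render_traces: bool = False) -> list[CohortAnimal]:
    """One simulated animal per cohort slot, with recorded true offsets.

    Per-animal seeds are spawned deterministically from the cohort seed.
    Set ``render_traces`` to also produce full position traces (slower);
    the ground-truth event logs are always returned.
    """
    ss = np.random.SeedSequence(spec.seed)
    animals: list[CohortAnimal] = []
    children = ss.spawn(sum(g[1] for g in spec.groups))
    i = 0
    for label, n, offsets in spec.groups:
        for j in range(n):
            child_seed = int(children[i].generate_state(1)[0] % (2**31))
            i += 1
            a_spec = apply_offsets(spec.base_spec, offsets, seed=child_seed)
            if render_traces:
                trace, events = simulate_homecage_trace(a_spec)
            else:
                trace, events = None, simulate_homecage_events(a_spec)
            animals.append(
                CohortAnimal(
                    animal_id=f"{label}_{j + 1:02d}",
                    group=label,
                    spec=a_spec,
                    offsets=dict(offsets),
                    events=events,
                    trace=trace,
                )
            )
    return animals


def simulate_random_walk_trace(
    duration_s: float = 60.0,
    sample_rate: float = 20.0,
    seed: int = 0,
    arena: ArenaGeometry | None = None,
    speed_cms: float = 20.0,
) -> TrackingTrace:
    """Unbiased random walk in a circular arena with a reflective boundary.

    Fresh isotropic direction every frame; a step that would leave the
    disc is folded back radially.  Used for chance-level probe-trial
    studies: by symmetry, expected per-quadrant occupancy and path share
    are 0.25 each.
    """
    arena = arena or water_maze_arena()
    bounds = arena.bounds
    if not isinstance(bounds, DiscZone):
        raise SimSpecError("random-walk arena must be circular")
    R = bounds.radius
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    step = speed_cms / sample_rate
    ang = rng.uniform(0, 2 * np.pi, size=n)
    dx = np.cos(ang) * step
    dy = np.sin(ang) * step
    x = np.empty(n)
    y = np.empty(n)
    px, py = bounds.cx, bounds.cy
    for i in range(n):
        qx, qy = px + dx[i], py + dy[i]
        r = math.hypot(qx - bounds.cx, qy - bounds.cy)
        if r > R:
            fold = (2 * R - r) / r
            qx = bounds.cx + (qx - bounds.cx) * fold
            qy = bounds.cy + (qy - bounds.cy) * fold
        px, py = qx, qy
        x[i] = px
        y[i] = py
    return TrackingTrace(
        times=np.arange(n) / sample_rate, x=x, y=y,
        sample_rate=sample_rate, arena=arena,
    )
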