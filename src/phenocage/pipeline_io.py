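"""File I/O, run configuration and end-to-end orchestration.

All interchange is plain CSV with documented headers:

* trace:      time_s, x_cm, y_cm [, zone]
* keypoints:  frame, bodypart, x_cm, y_cm, confidence (tidy long format)
* entry log:  time_s, hole

Run configuration is a TOML file; ground truth from the simulator is
written as JSON sidecars.  ``run_pipeline`` takes a cohort of traces to
a phenotype table, group statistics with FDR and pooled-control filter
decisions, recording per-animal stage failures without aborting the
remaining animals.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import (
    ArenaGeometry,
    LightCycle,
    barnes_arena,
    open_field_arena,
    phenotyper_arena,
    water_maze_arena,
)
from .group_stats import StatsConfig, compare_groups, fdr_adjust, wt_consistency_filter
from .spontaneous_params import PhenotypeConfig, compute_phenotype_vector
from .synthetic_data import CohortSpec, HomecageSimSpec, simulate_cohort, simulate_homecage_trace
from .task_metrics import EntryLog, TargetSchedule, learning_curves
from .tracking_events import (
    EventLog,
    KeypointTrace,
    SegmentationConfig,
    TrackingTrace,
    qc_check,
    segment_events,
)

__all__ = [
    "ConfigError",
    "RunConfig",
    "RunReport",
    "read_trace",
    "write_trace",
    "read_keypoints",
    "write_keypoints",
    "read_entry_log",
    "write_entry_log",
    "read_run_config",
    "run_pipeline",
    "generate_fixtures",
]

log = logging.getLogger("phenocage")


class ConfigError(ValueError):
    """Raised for invalid run configuration."""


_ARENA_FACTORIES = {
    "phenotyper": phenotyper_arena,
    "open_field": open_field_arena,
    "barnes": barnes_arena,
    "water_maze": water_maze_arena,
}


def _arena_from_config(d: dict) -> ArenaGeometry:
    kind = d.get("kind")
    if kind not in _ARENA_FACTORIES:
        raise ConfigError(
            f"arena.kind must be one of {sorted(_ARENA_FACTORIES)}, got {kind!r}"
        )
    kwargs = {k: v for k, v in d.items() if k != "kind"}
    return _ARENA_FACTORIES[kind](**kwargs)


def write_trace(trace: TrackingTrace, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": trace.times, "x_cm": trace.x, "y_cm": trace.y})
    if trace.zone is not None:
        df["zone"] = trace.zone
    df.to_csv(path, index=False, float_format="%.4f")


def read_trace(path: str | Path, arena: ArenaGeometry | None = None,
               lightcycle: LightCycle | None = None,
               cfg: SegmentationConfig | None = None) -> tuple[TrackingTrace, dict]:
    """Read and QC a trace CSV; returns (trace, qc_summary).

    Frames lost by the tracker may appear as empty x/y cells; gaps up to
    ``cfg.max_gap`` are linearly interpolated, longer gaps are left
    missing (they split events downstream) and counted in the summary.
    """
    cfg = cfg or SegmentationConfig()
    df = pd.read_csv(path)
    need = {"time_s", "x_cm", "y_cm"}
    if not need <= set(df.columns):
        raise ConfigError(f"trace {path} lacks columns {sorted(need - set(df.columns))}")
    times = df["time_s"].to_numpy(dtype=float)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        raise ConfigError(f"trace {path} has non-monotone time_s")
    rate = 1.0 / float(np.median(np.diff(times))) if len(times) > 1 else 1.0
    x = df["x_cm"].to_numpy(dtype=float)
    y = df["y_cm"].to_numpy(dtype=float)
    max_gap_frames = int(round(cfg.max_gap * rate))
    lost = ~(np.isfinite(x) & np.isfinite(y))
    if lost.any() and not lost.all():
        idx = np.arange(len(x))
        for arr in (x, y):
            bad = ~np.isfinite(arr)
            # interpolate short gaps only
            d = np.diff(bad.astype(np.int8))
            starts = list(np.flatnonzero(d == 1) + 1)
            stops = list(np.flatnonzero(d == -1) + 1)
            if bad[0]:
                starts.insert(0, 0)
            if bad[-1]:
                stops.append(len(bad))
            for s, e in zip(starts, stops):
                if e - s <= max_gap_frames and s > 0 and e < len(arr):
                    arr[s:e] = np.interp(idx[s:e], [s - 1, e], [arr[s - 1], arr[e]])
    zone = df["zone"].to_numpy() if "zone" in df.columns else None
    trace = TrackingTrace(
        times=times, x=x, y=y,
        sample_rate=round(rate, 6), zone=zone, arena=arena, lightcycle=lightcycle,
    )
    qc = qc_check(trace, cfg)
    if arena is not None:
        valid = trace.valid_mask()
        qc["out_of_bounds"] = int((~arena.contains(x, y) & valid).sum())
    return trace, qc


def write_keypoints(kp: KeypointTrace, path: str | Path) -> None:
    rows = []
    for part, xy in kp.coords.items():
        conf = kp.confidence[part]
        rows.append(
            pd.DataFrame(
                {
                    "frame": np.arange(len(xy)),
                    "bodypart": part,
                    "x_cm": xy[:, 0],
                    "y_cm": xy[:, 1],
                    "confidence": conf,
                }
            )
        )
    pd.concat(rows).to_csv(path, index=False, float_format="%.4f")


def read_keypoints(path: str | Path, sample_rate: float) -> KeypointTrace:
    df = pd.read_csv(path)
    need = {"frame", "bodypart", "x_cm", "y_cm", "confidence"}
    if not need <= set(df.columns):
        raise ConfigError(f"keypoint file {path} lacks columns {sorted(need - set(df.columns))}")
    coords, conf = {}, {}
    for part, grp in df.groupby("bodypart"):
        grp = grp.sort_values("frame")
        coords[str(part)] = grp[["x_cm", "y_cm"]].to_numpy(dtype=float)
        conf[str(part)] = grp["confidence"].to_numpy(dtype=float)
    return KeypointTrace(coords=coords, confidence=conf, sample_rate=sample_rate)


def write_entry_log(logg: EntryLog, path: str | Path) -> None:
    logg.entries[["time_s", "hole"]].to_csv(path, index=False, float_format="%.3f")


def read_entry_log(path: str | Path, schedule: TargetSchedule) -> EntryLog:
    df = pd.read_csv(path)
    if not {"time_s", "hole"} <= set(df.columns):
        raise ConfigError(f"entry log {path} needs columns time_s, hole")
    return EntryLog(df[["time_s", "hole"]], schedule)


def write_events(events: EventLog, path: str | Path) -> None:
    events.events.to_csv(path, index=False, float_format="%.4f")


@dataclass
class RunConfig:
    """Validated end-to-end run configuration."""

    seed: int
    out_dir: Path
    animals: list[dict]  # id, group, wt_subgroup, trace (path)
    arena: ArenaGeometry
    lightcycle: LightCycle
    segmentation: SegmentationConfig
    phenotype: PhenotypeConfig
    stats: StatsConfig
    entry_logs: list[dict] = field(default_factory=list)  # id, group, path
    schedule: TargetSchedule | None = None
    raw: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_run_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    base = path.parent
    try:
        arena = _arena_from_config(raw.get("arena", {"kind": "phenotyper"}))
        lightcycle = LightCycle(**raw.get("lightcycle", {}))
        seg = SegmentationConfig(**raw.get("segmentation", {}))
        phen = PhenotypeConfig(**raw.get("phenotype", {}))
        stats_cfg = StatsConfig(**raw.get("stats", {}))
        schedule = (
            TargetSchedule(
                targets=tuple(raw["schedule"]["targets"]),
                day_length_s=raw["schedule"].get("day_length_s", 86400.0),
            )
            if "schedule" in raw
            else None
        )
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    animals = raw.get("animals", [])
    for a in animals:
        if not {"id", "group", "trace"} <= set(a):
            raise ConfigError("each [[animals]] entry needs id, group and trace")
        a["trace"] = str(base / a["trace"])
        if not Path(a["trace"]).exists():
            raise ConfigError(f"trace file {a['trace']} does not exist")
        a.setdefault("wt_subgroup", a["group"])
    entry_logs = raw.get("entry_logs", [])
    for e in entry_logs:
        e["path"] = str(base / e["path"])
        if not Path(e["path"]).exists():
            raise ConfigError(f"entry log {e['path']} does not exist")
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        out_dir=base / raw.get("out_dir", "out"),
        animals=animals,
        arena=arena,
        lightcycle=lightcycle,
        segmentation=seg,
        phenotype=phen,
        stats=stats_cfg,
        entry_logs=entry_logs,
        schedule=schedule,
        raw=raw,
    )


@dataclass
class RunReport:
    phenotypes: pd.DataFrame
    statistics: pd.DataFrame
    filter_decisions: pd.DataFrame
    learning_curves: pd.DataFrame
    errors: list[dict]
    provenance: dict


def run_pipeline(config: RunConfig, write: bool = True) -> RunReport:
    """Raw tables to phenotype/statistics report, deterministic given
    config and seed.  Per-animal stage failures are recorded with stage
    name and animal id; remaining animals are still processed."""
    t0 = time.time()
    errors: list[dict] = []
    pheno_frames: list[pd.DataFrame] = []
    groups: dict[str, str] = {}
    wt_subgroups: dict[str, str] = {}

    for a in config.animals:
        aid = a["id"]
        groups[aid] = a["group"]
        wt_subgroups[aid] = a.get("wt_subgroup", a["group"])
        try:
            stage = "read_trace"
            trace, qc = read_trace(
                a["trace"], arena=config.arena, lightcycle=config.lightcycle,
                cfg=config.segmentation,
            )
            stage = "segment_events"
            events = segment_events(trace, config.segmentation)
            stage = "phenotype"
            vec = compute_phenotype_vector(
                events, config.lightcycle, config.phenotype, strict=False
            )
            pheno_frames.append(vec.to_frame(animal=aid))
            log.info("animal %s processed (%d events)", aid, len(events))
        except Exception as exc:  # noqa: BLE001 - per-animal isolation
            errors.append({"animal": aid, "stage": stage, "error": str(exc)})
            log.warning("animal %s failed at %s: %s", aid, stage, exc)

    phenotypes = (
        pd.concat(pheno_frames, ignore_index=True)
        if pheno_frames
        else pd.DataFrame(
            columns=["animal", "parameter", "value", "units", "phase",
                     "missing", "registry_completed"]
        )
    )

    stat_rows = []
    filter_rows = []
    if len(phenotypes):
        wide = phenotypes[~phenotypes["missing"]]
        for param, sub in wide.groupby("parameter"):
            by_group: dict[str, np.ndarray] = {}
            for g in sorted(set(groups.values())):
                vals = sub.loc[sub["animal"].map(groups) == g, "value"].to_numpy()
                if len(vals) >= config.stats.min_n:
                    by_group[g] = vals
            if len(by_group) < 2:
                continue
            try:
                res = compare_groups(by_group, config.stats)
            except ValueError as exc:
                errors.append({"animal": "-", "stage": f"stats:{param}", "error": str(exc)})
                continue
            stat_rows.append(
                {
                    "parameter": param,
                    "path": res.path,
                    "transform": res.transform,
                    "omnibus_p": res.omnibus_p,
                    "n_pairwise": len(res.pairwise),
                    "pairwise": res.pairwise.to_dict("records"),
                }
            )
        # consistency filter when control subgroup structure is available
        wt_table = wide.copy()
        wt_table["group"] = wt_table["animal"].map(groups)
        wt_table["wt_subgroup"] = wt_table["animal"].map(wt_subgroups)
        n_sub = wt_table.loc[
            wt_table["group"] == config.stats.control, "wt_subgroup"
        ].nunique()
        if n_sub >= 2:
            counts = wt_table.groupby(["parameter", "group"])["value"].count()
            ok_params = [
                p for p, c in counts.groupby("parameter")
                if (c >= config.stats.min_n).all() and len(c) >= 2
            ]
            try:
                decisions = wt_consistency_filter(
                    wt_table[wt_table["parameter"].isin(ok_params)], config.stats
                )
                filter_rows = [
                    {
                        "parameter": d.parameter,
                        "wt_subgroups_differ": d.wt_subgroups_differ,
                        "pooled_significant": d.pooled_significant,
                        "own_wt_significant": d.own_wt_significant,
                        "decision": d.decision,
                    }
                    for d in decisions
                ]
            except ValueError as exc:
                errors.append({"animal": "-", "stage": "wt_filter", "error": str(exc)})

    statistics = pd.DataFrame(stat_rows)
    if len(statistics):
        statistics["p_fdr"] = fdr_adjust(statistics["omnibus_p"].to_numpy())
        statistics["significant_fdr"] = statistics["p_fdr"] < config.stats.alpha
    filter_decisions = pd.DataFrame(
        filter_rows,
        columns=["parameter", "wt_subgroups_differ", "pooled_significant",
                 "own_wt_significant", "decision"],
    )

    curve_rows = []
    if config.entry_logs and config.schedule is not None:
        for e in config.entry_logs:
            try:
                elog = read_entry_log(e["path"], config.schedule)
                lc = learning_curves(elog)
                df = lc.bins.copy()
                df.insert(0, "animal", e["id"])
                df.insert(1, "group", e.get("group", ""))
                curve_rows.append(df)
            except Exception as exc:  # noqa: BLE001
                errors.append({"animal": e.get("id", "?"), "stage": "learning_curves",
                               "error": str(exc)})
    curves = (
        pd.concat(curve_rows, ignore_index=True) if curve_rows else pd.DataFrame()
    )

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "runtime_s": round(time.time() - t0, 3),
        "n_animals": len(config.animals),
        "n_errors": len(errors),
    }
    report = RunReport(phenotypes, statistics, filter_decisions, curves, errors, provenance)

    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        phenotypes.to_csv(out / "phenotypes.csv", index=False)
        stats_out = statistics.copy()
        if "pairwise" in stats_out.columns:
            stats_out["pairwise"] = stats_out["pairwise"].apply(json.dumps)
        stats_out.to_csv(out / "statistics.csv", index=False)
        filter_decisions.to_csv(out / "filter_decisions.csv", index=False)
        if len(curves):
            curves.to_csv(out / "learning_curves.csv", index=False)
        index = dict(provenance)
        index["errors"] = errors
        index["tables"] = ["phenotypes.csv", "statistics.csv", "filter_decisions.csv"]
        with open(out / "report.json", "w") as fh:
            json.dump(index, fh, indent=2)
    return report


FIXTURE_GROUPS = ("WT", "mdx5cv", "mdx52", "DMD-null")


def generate_fixtures(seed: int, out_dir: str | Path, n_per_group: int = 4,
                      duration_days: int = 1, sample_rate: float = 2.0) -> Path:
    """Write a miniature synthetic cohort exercising every reader.

    Four groups of ``n_per_group`` animals, one simulated day at a
    reduced sample rate: trace CSVs, ground-truth event CSV + JSON
    sidecars, and a ready-to-run TOML config.  Returns the config path.
    """
    out = Path(out_dir)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    base = HomecageSimSpec(seed=seed, duration_days=duration_days,
                           sample_rate=sample_rate)
    cohort = CohortSpec(
        seed=seed,
        base_spec=base,
        groups=tuple((g, n_per_group, {}) for g in FIXTURE_GROUPS),
    )
    animals = simulate_cohort(cohort, render_traces=True)
    lines = [
        f"seed = {seed}",
        'out_dir = "out"',
        "",
        "[arena]",
        'kind = "phenotyper"',
        "",
        "[lightcycle]",
        f"lights_on = {base.lightcycle.lights_on}",
        f"lights_off = {base.lightcycle.lights_off}",
        f"start_clock = {base.lightcycle.start_clock}",
        "",
        "[phenotype]",
        "day = 1" if duration_days < 3 else "day = 3",
        "",
    ]
    rng = np.random.default_rng(seed)
    for idx, a in enumerate(animals):
        trace_rel = f"traces/{a.animal_id}.csv"
        write_trace(a.trace, out / trace_rel)
        write_events(a.events, out / f"traces/{a.animal_id}_truth.csv")
        with open(out / f"traces/{a.animal_id}_truth.json", "w") as fh:
            json.dump(
                {
                    "animal": a.animal_id,
                    "group": a.group,
                    "seed": a.spec.seed,
                    "offsets": a.offsets,
                    "n_events": len(a.events),
                },
                fh,
            )
        # WT littermate structure: control animals alternate subgroups
        if a.group == "WT":
            sub = FIXTURE_GROUPS[1:][idx % 3]
        else:
            sub = a.group
        lines += [
            "[[animals]]",
            f'id = "{a.animal_id}"',
            f'group = "{a.group}"',
            f'wt_subgroup = "{sub}"',
            f'trace = "{trace_rel}"',
            "",
        ]
    cfg_path = out / "run.toml"
    cfg_path.write_text("\n".join(lines))
    return cfg_path
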