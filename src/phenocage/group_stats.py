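"""The group-statistics ladder used for multi-model phenotyping cohorts.

Group comparisons are gated on per-group normality (Shapiro-Wilk at
alpha 0.05).  If every group is normal - if necessary after a single
log10 transform - a one-way ANOVA with Tukey post-hoc is used; otherwise
a Kruskal-Wallis omnibus followed, only when the omnibus is significant,
by pairwise Mann-Whitney tests.  Pairwise comparisons follow the pooled-
control convention: every model group is compared with the pooled
control, and model-versus-model comparisons are made only when at least
one model differs significantly from the control.  Comparisons to a
chance constant use a one-sample t-test (normal data) or Wilcoxon signed
rank.  Multiplicity over the spontaneous-behavior registry is handled
with Benjamini-Hochberg false-discovery-rate adjustment.

The pooled-control consistency filter re-examines parameters that are
significant only against the pooled control: a parameter is excluded
when the control subgroups differ among themselves, the pooled
comparison is significant, and no model differs from its own matched
control subgroup - the pattern of a pooling artifact.

Time-course analyses (linear mixed models) are not implemented here;
the tidy per-bin tables this package exports are the intended input for
a dedicated mixed-model backend.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatsConfig",
    "GroupComparisonResult",
    "ChanceTestResult",
    "FilterDecision",
    "compare_groups",
    "chance_test",
    "alternation_chisq",
    "fdr_adjust",
    "wt_consistency_filter",
]


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    normality_alpha: float = 0.05
    control: str = "WT"
    adjust_pairwise: bool = False  # optional BH over the pairwise set
    min_n: int = 3


@dataclass
class GroupComparisonResult:
    path: str  # anova_tukey | kruskal_mannwhitney
    transform: str  # none | log10
    omnibus_stat: float
    omnibus_p: float
    pairwise: pd.DataFrame  # group1, group2, p, p_adjusted
    normality: dict[str, float]
    degenerate: bool = False


@dataclass
class ChanceTestResult:
    test: str  # one_sample_t | wilcoxon_signed_rank
    chance: float
    p: float
    estimate: float
    degenerate: bool = False


def _shapiro_p(x: np.ndarray) -> float:
    """Shapiro-Wilk p; constant or tiny samples count as non-normal (p = 0)."""
    if len(x) < 3 or np.ptp(x) < 1e-12:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(x).pvalue)


def _pair_order(groups: list[str], control: str) -> tuple[list, list]:
    models = [g for g in groups if g != control]
    vs_control = [(g, control) for g in models] if control in groups else []
    model_pairs = list(itertools.combinations(models, 2))
    if control not in groups:
        # no designated control: compare everything pairwise
        return list(itertools.combinations(groups, 2)), []
    return vs_control, model_pairs


def compare_groups(values_by_group: dict[str, np.ndarray],
                   cfg: StatsConfig | None = None,
                   compute_pairwise: bool = True) -> GroupComparisonResult:
    """Normality-gated omnibus and pairwise comparison of 2+ groups.

    The gate never changes the data used for the nonparametric path; the
    log10 transform is attempted once, only when some group fails
    normality and all values are positive.  ``compute_pairwise=False``
    skips the post-hoc stage (useful in large simulation studies of the
    omnibus).
    """
    cfg = cfg or StatsConfig()
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, v in groups.items():
        if len(v) < cfg.min_n:
            raise ValueError(f"group {name!r} has n={len(v)} < {cfg.min_n}")

    arrays = list(groups.values())
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) < 1e-12:
        return GroupComparisonResult(
            path="degenerate", transform="none", omnibus_stat=0.0, omnibus_p=1.0,
            pairwise=pd.DataFrame(columns=["group1", "group2", "p", "p_adjusted"]),
            normality={k: 0.0 for k in groups}, degenerate=True,
        )

    norm_p = {k: _shapiro_p(v) for k, v in groups.items()}
    transform = "none"
    use = groups
    if any(p < cfg.normality_alpha for p in norm_p.values()) and pooled.min() > 0:
        logged = {k: np.log10(v) for k, v in groups.items()}
        log_p = {k: _shapiro_p(v) for k, v in logged.items()}
        if all(p >= cfg.normality_alpha for p in log_p.values()):
            transform = "log10"
            use = logged
            norm_p = log_p

    all_normal = all(p >= cfg.normality_alpha for p in norm_p.values())
    names = list(use)
    arrays = [use[k] for k in names]
    rows = []
    if all_normal:
        path = "anova_tukey"
        stat, p = stats.f_oneway(*arrays)
        if compute_pairwise:
            res = stats.tukey_hsd(*arrays)
            vs_control, model_pairs = _pair_order(names, cfg.control)

            def tukey_p(a: str, b: str) -> float:
                return float(res.pvalue[names.index(a), names.index(b)])

            sig_vs_control = False
            for a, b in vs_control:
                pv = tukey_p(a, b)
                sig_vs_control |= pv < cfg.alpha
                rows.append((a, b, pv))
            if sig_vs_control or not vs_control:
                for a, b in model_pairs:
                    rows.append((a, b, tukey_p(a, b)))
    else:
        path = "kruskal_mannwhitney"
        stat, p = stats.kruskal(*arrays)
        if p < cfg.alpha and compute_pairwise:
            vs_control, model_pairs = _pair_order(names, cfg.control)

            def mw_p(a: str, b: str) -> float:
                return float(stats.mannwhitneyu(use[a], use[b],
                                                alternative="two-sided").pvalue)

            sig_vs_control = False
            for a, b in vs_control:
                pv = mw_p(a, b)
                sig_vs_control |= pv < cfg.alpha
                rows.append((a, b, pv))
            if sig_vs_control or not vs_control:
                for a, b in model_pairs:
                    rows.append((a, b, mw_p(a, b)))

    pw = pd.DataFrame(rows, columns=["group1", "group2", "p"])
    if len(pw) and cfg.adjust_pairwise:
        pw["p_adjusted"] = fdr_adjust(pw["p"].to_numpy())
    else:
        pw["p_adjusted"] = pw["p"] if len(pw) else pd.Series(dtype=float)
    return GroupComparisonResult(
        path=path, transform=transform, omnibus_stat=float(stat),
        omnibus_p=float(p), pairwise=pw, normality=norm_p,
    )


def chance_test(values, chance: float, normal: bool | None = None,
                cfg: StatsConfig | None = None) -> ChanceTestResult:
    """One-sample comparison against a chance constant.

    Uses a one-sample t-test when the data are normal (Shapiro-Wilk gate
    unless ``normal`` is given) and the Wilcoxon signed-rank test
    otherwise.  All values equal to chance is reported as degenerate
    with p = 1.
    """
    cfg = cfg or StatsConfig()
    x = np.asarray(values, dtype=float)
    if len(x) < cfg.min_n:
        raise ValueError(f"need n >= {cfg.min_n}")
    est = float(x.mean())
    if np.all(np.abs(x - chance) < 1e-12):
        return ChanceTestResult("one_sample_t", chance, 1.0, est, degenerate=True)
    if normal is None:
        normal = _shapiro_p(x) >= cfg.normality_alpha
    if normal:
        p = float(stats.ttest_1samp(x, popmean=chance).pvalue)
        return ChanceTestResult("one_sample_t", chance, p, est)
    diffs = x - chance
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        return ChanceTestResult("wilcoxon_signed_rank", chance, 1.0, est, degenerate=True)
    p = float(stats.wilcoxon(diffs).pvalue)
    return ChanceTestResult("wilcoxon_signed_rank", chance, p, est)


def alternation_chisq(counts) -> tuple[float, float, bool]:
    """Chi-square test on a 2x2 target/non-target count table.

    ``counts`` is [[target_a, nontarget_a], [target_b, nontarget_b]].
    Returns (statistic, p, degenerate); a zero margin is degenerate with
    statistic 0 and p 1.  No continuity correction, matching the plain
    sum((O-E)^2/E) formula.
    """
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("counts must be a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 0.0, 1.0, True
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p), False


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # step-up: running minimum from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class FilterDecision:
    parameter: str
    wt_subgroups_differ: bool
    pooled_significant: bool
    own_wt_significant: bool
    decision: str  # retain | exclude
    record: dict = field(default_factory=dict)


def _two_group_p(a: np.ndarray, b: np.ndarray, cfg: StatsConfig) -> float:
    """Normality-gated two-group test (Welch t or Mann-Whitney)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.ptp(np.concatenate([a, b])) < 1e-12:
        return 1.0
    normal = (_shapiro_p(a) >= cfg.normality_alpha
              and _shapiro_p(b) >= cfg.normality_alpha)
    if normal:
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def wt_consistency_filter(table: pd.DataFrame,
                          cfg: StatsConfig | None = None) -> list[FilterDecision]:
    """Exclusion decisions for pooled-control artifacts, per parameter.

    ``table`` is tidy with columns parameter, group, wt_subgroup, value:
    control animals carry ``group == cfg.control`` and the label of the
    model line they are littermates of in ``wt_subgroup``; model animals
    carry their own group label in both.  A parameter is excluded iff
    the control subgroups differ, some model is significant against the
    pooled control, and no such model is significant against its own
    control subgroup.
    """
    cfg = cfg or StatsConfig()
    need = {"parameter", "group", "wt_subgroup", "value"}
    if not need <= set(table.columns):
        raise ValueError(f"table needs columns {sorted(need)}")
    decisions = []
    for param, sub in table.groupby("parameter"):
        wt = sub[sub["group"] == cfg.control]
        models = [g for g in sub["group"].unique() if g != cfg.control]
        if not len(wt):
            raise ValueError(f"parameter {param!r} has no control group")
        wt_by_sub = {
            k: g["value"].to_numpy() for k, g in wt.groupby("wt_subgroup")
        }
        for m in models:
            if m not in wt_by_sub:
                raise ValueError(f"model {m!r} lacks a matched control subgroup")
        # do control subgroups differ among themselves?
        if len(wt_by_sub) >= 2:
            if len(wt_by_sub) == 2:
                a, b = wt_by_sub.values()
                p_wt = _two_group_p(a, b, cfg)
            else:
                arrays = list(wt_by_sub.values())
                if np.ptp(np.concatenate(arrays)) < 1e-12:
                    p_wt = 1.0
                else:
                    p_wt = float(stats.kruskal(*arrays).pvalue)
        else:
            p_wt = 1.0
        differ = p_wt < cfg.alpha

        pooled_wt = wt["value"].to_numpy()
        p_pooled = {}
        p_own = {}
        for m in models:
            mv = sub.loc[sub["group"] == m, "value"].to_numpy()
            p_pooled[m] = _two_group_p(mv, pooled_wt, cfg)
            p_own[m] = _two_group_p(mv, wt_by_sub[m], cfg)
        sig_models = [m for m in models if p_pooled[m] < cfg.alpha]
        pooled_sig = bool(sig_models)
        own_sig = any(p_own[m] < cfg.alpha for m in sig_models)
        exclude = differ and pooled_sig and not own_sig
        decisions.append(
            FilterDecision(
                parameter=str(param),
                wt_subgroups_differ=differ,
                pooled_significant=pooled_sig,
                own_wt_significant=own_sig,
                decision="exclude" if exclude else "retain",
                record={"p_wt_subgroups": p_wt, "p_pooled": p_pooled, "p_own": p_own},
            )
        )
    return decisions
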