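"""Orchestration of the sensitivity analyses.

Runs the two comparison designs across time points and missing-data modes,
turns per-comparison Mann-Whitney estimates into instrument-level
sensitivity summaries (percent of feasible comparisons with at least a
medium effect), ranks instruments, derives recommendation labels from the
predominant effect class, and computes impairment prevalences and
between-instrument Spearman correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import groups as _groups
from . import instruments as _instr
from . import mwstats as _mw
from .groups import ALL_SCORES, PROM_SCORES, ComparisonSpec, enumerate_comparisons

__all__ = [
    "AnalysisConfig",
    "ResultsBundle",
    "prepare_cohort",
    "completer_subjects",
    "run_design",
    "run_analysis",
    "summarize_sensitivity",
    "rank_instruments",
    "assign_recommendations",
    "prevalence_impaired",
    "correlate_outcomes",
    "spearman_label",
]

EFFECT_COLUMNS = [
    "design", "timepoint", "context", "factor", "arm1", "arm2", "instrument",
    "n1", "n2", "theta", "se", "ci_low", "ci_high", "effect_class",
    "z", "p", "alpha_family", "alpha", "significant", "feasible", "reason",
]

#: weakest-first ordering used for recommendation tie-breaks.
_CLASS_ORDER = ("small", "medium", "large")
_CLASS_TO_LABEL = {
    "large": "strongly_recommended",
    "medium": "recommended",
    "small": "little_information_gain",
}


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings of one analysis run.

    ``mode`` is either ``as_available`` (every record with the outcome
    present contributes) or ``completers`` (restricted to subjects with at
    least one outcome at every configured time point). ``count_rule``
    decides whether the sensitivity summaries count comparisons by effect
    size alone (default) or additionally require significance at the
    family's adjusted alpha.
    """

    designs: tuple[str, ...] = ("A", "B")
    timepoints: tuple[int, ...] = (3, 6, 12)
    mode: str = "as_available"
    min_arm_n: int = 10
    ci_level: float = 0.95
    ci_scale: str = "identity"
    count_rule: str = "effect_only"
    pooling: str = "equal"  # or "inverse_variance"
    instruments_a: tuple[str, ...] = ALL_SCORES
    instruments_b: tuple[str, ...] = PROM_SCORES
    sf_cutoff: float = 40.0

    def __post_init__(self) -> None:
        if self.mode not in ("as_available", "completers"):
            raise ValueError(f"unknown missing-data mode {self.mode!r}")
        if self.count_rule not in ("effect_only", "effect_and_significance"):
            raise ValueError(f"unknown count rule {self.count_rule!r}")
        if self.pooling not in ("equal", "inverse_variance"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if not set(self.timepoints) <= {3, 6, 12}:
            raise ValueError("time points must be a subset of {3, 6, 12}")
        for d in self.designs:
            if d not in ("A", "B"):
                raise ValueError(f"unknown design {d!r}")


@dataclass
class ResultsBundle:
    """Tidy result tables of one run."""

    effects: pd.DataFrame           # one row per comparison x instrument
    pooled: pd.DataFrame            # design-B Wei-Lachin pooled rows
    config: AnalysisConfig

    @property
    def infeasible(self) -> pd.DataFrame:
        return self.effects[~self.effects["feasible"]]


def prepare_cohort(frame: pd.DataFrame,
                   registry: Optional[dict] = None) -> pd.DataFrame:
    """Score instruments, merge GOSE sources, attach grouping columns."""
    scored = _instr.score_cohort(frame, registry)
    return _groups.derive_binary_groups(scored)


def _oriented_column(instrument: str) -> str:
    return f"{instrument}_oriented"


def completer_subjects(frame: pd.DataFrame, instruments: Sequence[str],
                       timepoints: Sequence[int]) -> set:
    """Subjects with at least one non-missing outcome at every time point."""
    cols = [_oriented_column(i) for i in instruments
            if _oriented_column(i) in frame.columns]
    ok_rows = frame[cols].notna().any(axis=1)
    per_tp = (frame.assign(_ok=ok_rows)
              .groupby(["subject_id", "timepoint_months"])["_ok"].any()
              .unstack("timepoint_months"))
    missing_tp = [tp for tp in timepoints if tp not in per_tp.columns]
    if missing_tp:
        return set()
    complete = per_tp[list(timepoints)].all(axis=1)
    return set(per_tp.index[complete])


def _instrument_rows(comp: ComparisonSpec, frame: pd.DataFrame,
                     cfg: AnalysisConfig, alpha_family: str) -> list[dict]:
    alpha = _mw.adjust_alpha(alpha_family)
    rows = []
    base = dict(design=comp.design, timepoint=comp.timepoint,
                context=comp.context, factor=comp.factor,
                arm1=comp.arm1, arm2=comp.arm2,
                alpha_family=alpha_family, alpha=alpha)
    for instrument in comp.instruments:
        col = _oriented_column(instrument)
        x = frame.loc[comp.idx1, col].to_numpy(dtype=float)
        y = frame.loc[comp.idx2, col].to_numpy(dtype=float)
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        row = dict(base, instrument=instrument, n1=len(x), n2=len(y))
        if not comp.feasible:
            row.update(theta=np.nan, se=np.nan, ci_low=np.nan, ci_high=np.nan,
                       effect_class=None, z=np.nan, p=np.nan, significant=None,
                       feasible=False, reason=comp.reason)
        elif len(x) < 2 or len(y) < 2:
            row.update(theta=np.nan, se=np.nan, ci_low=np.nan, ci_high=np.nan,
                       effect_class=None, z=np.nan, p=np.nan, significant=None,
                       feasible=False,
                       reason="fewer than 2 non-missing observations in an arm")
        else:
            est = _mw.mw_effect(x, y, ci_level=cfg.ci_level, ci_scale=cfg.ci_scale)
            p = est.p
            row.update(theta=est.theta, se=est.se,
                       ci_low=est.ci[0], ci_high=est.ci[1],
                       effect_class=_mw.classify_effect(est.theta),
                       z=est.z, p=p,
                       significant=None if math.isnan(p) else bool(p < alpha),
                       feasible=True, reason="")
        rows.append(row)
    return rows


def _pooled_row(comp: ComparisonSpec, frame: pd.DataFrame,
                cfg: AnalysisConfig) -> Optional[dict]:
    """Wei-Lachin pooled PROM effect for one design-B comparison
    (complete-case subjects across the pooled instruments)."""
    cols = [_oriented_column(i) for i in comp.instruments]
    arm1 = frame.loc[comp.idx1, cols].to_numpy(dtype=float)
    arm2 = frame.loc[comp.idx2, cols].to_numpy(dtype=float)
    alpha = _mw.adjust_alpha("design_B_groups")
    base = dict(design=comp.design, timepoint=comp.timepoint,
                context=comp.context, factor=comp.factor,
                arm1=comp.arm1, arm2=comp.arm2, instrument="pooled",
                alpha_family="design_B_groups", alpha=alpha)
    try:
        thetas, sigma = _mw.mw_cov(arm1, arm2)
    except _mw.InfeasibleComparison as exc:
        return dict(base, n1=0, n2=0, theta=np.nan, se=np.nan,
                    ci_low=np.nan, ci_high=np.nan, effect_class=None,
                    z=np.nan, p=np.nan, significant=None,
                    feasible=False, reason=str(exc))
    weights = (_mw.inverse_variance_weights(sigma)
               if cfg.pooling == "inverse_variance" else None)
    pooled = _mw.pool_mmw(thetas, sigma, weights, ci_level=cfg.ci_level)
    n1 = int((~np.isnan(arm1).any(axis=1)).sum())
    n2 = int((~np.isnan(arm2).any(axis=1)).sum())
    return dict(base, n1=n1, n2=n2, theta=pooled.pooled_theta,
                se=pooled.pooled_se, ci_low=pooled.pooled_ci[0],
                ci_high=pooled.pooled_ci[1],
                effect_class=_mw.classify_effect(pooled.pooled_theta),
                z=pooled.z, p=pooled.p,
                significant=None if math.isnan(pooled.p) else bool(pooled.p < alpha),
                feasible=not pooled.degenerate,
                reason="degenerate pooled variance" if pooled.degenerate else "")


def run_design(frame: pd.DataFrame, design: str,
               cfg: AnalysisConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run one design over all configured time points on a prepared cohort.

    Returns ``(effects, pooled)`` tidy frames; ``pooled`` is empty for
    design A.
    """
    if frame.empty:
        raise ValueError("empty cohort")
    instruments = cfg.instruments_a if design == "A" else cfg.instruments_b
    for instrument in instruments:
        if _oriented_column(instrument) not in frame.columns:
            raise ValueError(f"unknown or unscored instrument {instrument!r}")
    alpha_family = "design_A_instruments" if design == "A" else "design_B_proms"
    effect_rows: list[dict] = []
    pooled_rows: list[dict] = []
    for tp in cfg.timepoints:
        tp_frame = frame[frame["timepoint_months"] == tp]
        comps = enumerate_comparisons(tp_frame, design, tp,
                                      min_arm_n=cfg.min_arm_n,
                                      instruments=instruments)
        for comp in comps:
            effect_rows.extend(_instrument_rows(comp, tp_frame, cfg, alpha_family))
            if design == "B" and comp.feasible:
                row = _pooled_row(comp, tp_frame, cfg)
                if row is not None:
                    pooled_rows.append(row)
    effects = pd.DataFrame(effect_rows, columns=EFFECT_COLUMNS)
    pooled = pd.DataFrame(pooled_rows, columns=EFFECT_COLUMNS)
    return effects, pooled


def run_analysis(cohort: pd.DataFrame,
                 cfg: Optional[AnalysisConfig] = None,
                 registry: Optional[dict] = None,
                 prepared: bool = False) -> ResultsBundle:
    """Score, group and analyze a cohort under both designs.

    In ``completers`` mode the cohort is first restricted to subjects with
    at least one non-missing outcome at every configured time point; the
    results then equal an as-available run on that restricted cohort.
    """
    cfg = cfg if cfg is not None else AnalysisConfig()
    registry = registry if registry is not None else _instr.default_registry(cfg.sf_cutoff)
    frame = cohort if prepared else prepare_cohort(cohort, registry)
    if cfg.mode == "completers":
        keep = completer_subjects(frame, ("gose",) + tuple(PROM_SCORES),
                                  cfg.timepoints)
        frame = frame[frame["subject_id"].isin(keep)]
    all_effects, all_pooled = [], []
    for design in cfg.designs:
        effects, pooled = run_design(frame, design, cfg)
        all_effects.append(effects)
        all_pooled.append(pooled)
    non_empty_pooled = [p for p in all_pooled if not p.empty]
    return ResultsBundle(
        effects=pd.concat(all_effects, ignore_index=True),
        pooled=(pd.concat(non_empty_pooled, ignore_index=True)
                if non_empty_pooled else pd.DataFrame(columns=EFFECT_COLUMNS)),
        config=cfg,
    )


def _counts_sensitive(sub: pd.DataFrame, count_rule: str) -> tuple[int, int]:
    feas = sub[sub["feasible"] == True]  # noqa: E712 (object dtype with None)
    hit = feas["effect_class"].isin(["medium", "large"])
    if count_rule == "effect_and_significance":
        hit &= feas["significant"] == True  # noqa: E712
    return int(len(feas)), int(hit.sum())


def summarize_sensitivity(effects: pd.DataFrame,
                          count_rule: str = "effect_only") -> pd.DataFrame:
    """Per instrument x time point: percent of feasible comparisons with at
    least a medium effect, plus an unweighted across-time average row
    (``timepoint="average"``). Cells with no feasible comparison carry a
    NaN percent."""
    rows = []
    for (instrument, tp), sub in effects.groupby(["instrument", "timepoint"],
                                                 sort=True):
        n_feas, n_hit = _counts_sensitive(sub, count_rule)
        pct = 100.0 * n_hit / n_feas if n_feas else np.nan
        rows.append(dict(instrument=instrument, timepoint=tp,
                         n_feasible=n_feas, n_at_least_medium=n_hit,
                         percent=pct))
    summary = pd.DataFrame(rows)
    if summary.empty:
        return summary
    for instrument, sub in summary.groupby("instrument", sort=True):
        rows.append(dict(instrument=instrument, timepoint="average",
                         n_feasible=int(sub["n_feasible"].sum()),
                         n_at_least_medium=int(sub["n_at_least_medium"].sum()),
                         percent=float(sub["percent"].mean())))
    return pd.DataFrame(rows)


def rank_instruments(summary: pd.DataFrame) -> pd.DataFrame:
    """Rank instruments per time point by descending sensitivity percent.

    Ties share a rank (competition ranking); the top three ranks are
    flagged ``top3``.
    """
    if summary.empty:
        raise ValueError("empty sensitivity summary")
    out = summary.copy()
    out["rank"] = (out.groupby("timepoint")["percent"]
                   .rank(ascending=False, method="min", na_option="bottom")
                   .astype(int))
    out["top3"] = out["rank"] <= 3
    out.loc[out["percent"].isna(), "top3"] = False
    return out


def assign_recommendations(effects: pd.DataFrame) -> pd.DataFrame:
    """Recommendation label per (time point, group context, instrument).

    The label follows the predominant (modal) effect class over the
    context's feasible comparisons: large -> strongly recommended, medium ->
    recommended, small -> little information gain. Modal ties resolve toward
    the weaker label. Contexts without a classified comparison get no label.
    """
    feas = effects[(effects["feasible"] == True) & effects["effect_class"].notna()]  # noqa: E712
    rows = []
    for (tp, context, instrument), sub in feas.groupby(
            ["timepoint", "context", "instrument"], sort=True):
        counts = sub["effect_class"].value_counts()
        top = counts.max()
        modal = [c for c in _CLASS_ORDER if counts.get(c, 0) == top]
        cls = modal[0]  # weakest among the tied modal classes
        rows.append(dict(timepoint=tp, context=context, instrument=instrument,
                         n_comparisons=int(len(sub)), modal_class=cls,
                         label=_CLASS_TO_LABEL[cls]))
    return pd.DataFrame(rows, columns=["timepoint", "context", "instrument",
                                       "n_comparisons", "modal_class", "label"])


_PREV_INSTRUMENTS = ("gose",) + PROM_SCORES


def prevalence_impaired(frame: pd.DataFrame,
                        factors: Optional[Sequence[str]] = None,
                        timepoints: Optional[Sequence[int]] = None,
                        instruments: Sequence[str] = _PREV_INSTRUMENTS,
                        ) -> pd.DataFrame:
    """Impairment prevalence per instrument x group x time point.

    ``proportion = n_impaired / n`` where the denominator counts non-missing
    totals only; cells with an empty denominator are flagged by a NaN
    proportion. ``factors`` defaults to the six a-priori factors plus TBI
    severity; an ``all`` pseudo-factor gives the marginal row.
    """
    if factors is None:
        factors = ("all", "sex", "age", "education", "premorbid_psych",
                   "pathway", "iss", "tbi_severity")
    if timepoints is None:
        timepoints = sorted(frame["timepoint_months"].dropna().unique())
    rows = []
    for instrument in instruments:
        col = f"{instrument}_impaired"
        if col not in frame.columns:
            raise ValueError(f"unknown instrument {instrument!r} (no {col} column)")
        flags = frame[col]
        for tp in timepoints:
            at_tp = frame["timepoint_months"] == tp
            for factor in factors:
                if factor == "all":
                    levels = {"all": at_tp}
                else:
                    fcol = ("tbi_severity" if factor == "tbi_severity"
                            else f"grp_{factor}")
                    if fcol not in frame.columns:
                        raise ValueError(f"unknown group factor {factor!r}")
                    levels = {lv: at_tp & (frame[fcol] == lv)
                              for lv in frame.loc[at_tp, fcol].dropna().unique()}
                for level, sel in levels.items():
                    cell = flags[sel]
                    n = int(cell.notna().sum())
                    k = int((cell == True).sum())  # noqa: E712
                    rows.append(dict(instrument=instrument, factor=factor,
                                     level=level, timepoint=tp,
                                     n_impaired=k, n=n,
                                     proportion=k / n if n else np.nan))
    return pd.DataFrame(rows)


def spearman_label(rho: float) -> Optional[str]:
    """Conventional effect label for a Spearman coefficient: |rho| >= 0.50
    large, >= 0.30 medium, >= 0.10 small, below that negligible."""
    if rho is None or (isinstance(rho, float) and math.isnan(rho)):
        return None
    a = abs(rho)
    if a >= 0.50:
        return "large"
    if a >= 0.30:
        return "medium"
    if a >= 0.10:
        return "small"
    return "negligible"


def correlate_outcomes(frame: pd.DataFrame, timepoint: int,
                       instruments: Sequence[str] = _PREV_INSTRUMENTS,
                       min_pairs: int = 3,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Spearman correlations between instruments at one
    time point, with conventional effect labels.

    Returns ``(matrix, labels)``: the coefficient matrix and a long frame
    with one row per instrument pair. Constant columns (or pairs with fewer
    than ``min_pairs`` joint observations) yield NaN coefficients, labelled
    None.
    """
    cols = {}
    for instrument in instruments:
        col = _oriented_column(instrument)
        if col not in frame.columns:
            raise ValueError(f"unknown instrument {instrument!r}")
        cols[instrument] = col
    at_tp = frame[frame["timepoint_months"] == timepoint]
    data = at_tp[list(cols.values())].astype(float)
    data.columns = list(cols)
    if len(data.columns) < 2:
        raise ValueError("need at least two instruments")
    matrix = data.corr(method="spearman", min_periods=min_pairs)
    rows = []
    names = list(matrix.columns)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            rho = float(matrix.loc[a, b])
            rows.append(dict(instrument_a=a, instrument_b=b, rho=rho,
                             label=spearman_label(rho)))
    return matrix, pd.DataFrame(rows)
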