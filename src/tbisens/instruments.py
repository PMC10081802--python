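"""Scoring of TBI outcome instruments.

Nine instruments are registered: the GOSE (with its questionnaire version
merged in), two generic HRQOL component scores per SF form (PCS/MCS of the
SF-36v2 and SF-12v2, consumed as T-scores), TBI-specific HRQOL (QOLIBRI and
QOLIBRI-OS), anxiety (GAD-7), depression (PHQ-9), post-traumatic stress
(PCL-5) and post-concussion symptoms (RPQ).

Every instrument carries a clinical impairment cut-off and a direction.
Symptom scales (higher = worse) are re-oriented onto a common
"higher = better" axis before any effect-size computation, so that a
Mann-Whitney statistic above 0.5 uniformly means the first group fared
better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InstrumentSpec",
    "ScoredOutcome",
    "GoseRating",
    "default_registry",
    "score_total",
    "flag_impaired",
    "orient_score",
    "collapse_gose",
    "merge_gose_sources",
    "fill_sf12_from_sf36",
    "score_cohort",
    "GOSE_LEVEL_LABELS",
    "GOSE_IMPAIRED_BELOW",
]

HIGHER_BETTER = "higher_better"
HIGHER_WORSE = "higher_worse"

#: merged GOSE/-Q scale: ordinal code (1-based index) -> printed label.
#: Vegetative state and lower severe disability are combined ("2/3") because
#: the questionnaire version cannot distinguish them.
GOSE_LEVEL_LABELS: tuple[str, ...] = ("1", "2/3", "4", "5", "6", "7", "8")

#: recovery counts as impaired when below level 7 on the merged scale,
#: i.e. merged ordinal code < 6.
GOSE_IMPAIRED_BELOW = 6


@dataclass(frozen=True)
class InstrumentSpec:
    """Scoring rules for one instrument.

    ``transform``:
      - ``sum``: total is the (prorated) sum of item ratings;
      - ``percent_0_100``: item mean rescaled linearly onto 0-100
        (QOLIBRI convention);
      - ``component_T``: no item scoring; the total (a norm-based T-score)
        is consumed as provided.
    """

    name: str
    direction: str
    total_range: tuple[float, float]
    transform: str
    impairment_threshold: float
    impairment_comparator: str  # "ge" -> impaired when total >= c; "lt" -> total < c
    n_items: Optional[int] = None
    item_range: Optional[tuple[int, int]] = None
    max_missing_items: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.direction not in (HIGHER_BETTER, HIGHER_WORSE):
            raise ValueError(f"{self.name}: unknown direction {self.direction!r}")
        if self.transform not in ("sum", "percent_0_100", "component_T"):
            raise ValueError(f"{self.name}: unknown transform {self.transform!r}")
        if self.impairment_comparator not in ("ge", "lt"):
            raise ValueError(f"{self.name}: unknown comparator")
        lo, hi = self.total_range
        if not lo < hi:
            raise ValueError(f"{self.name}: empty total range")
        if not (lo <= self.impairment_threshold <= hi):
            raise ValueError(f"{self.name}: impairment cut-off outside total range")
        if self.transform == "sum":
            if self.n_items is None or self.item_range is None:
                raise ValueError(f"{self.name}: sum transform requires items")
            ilo, ihi = self.item_range
            if (lo, hi) != (self.n_items * ilo, self.n_items * ihi):
                raise ValueError(f"{self.name}: total range inconsistent with items")
        if self.transform == "percent_0_100":
            if self.n_items is None or self.item_range is None:
                raise ValueError(f"{self.name}: percent transform requires items")
            if (lo, hi) != (0.0, 100.0):
                raise ValueError(f"{self.name}: percent transform implies range 0-100")
        if not 0.0 <= self.max_missing_items < 1.0:
            raise ValueError(f"{self.name}: max_missing_items must be in [0, 1)")


@dataclass(frozen=True)
class ScoredOutcome:
    """Total score of one instrument for one participant.

    ``impaired`` is tri-state: True / False / None (missing total).
    ``oriented`` is the total mapped onto the higher-is-better axis.
    """

    instrument: str
    total: float  # NaN when missing
    oriented: float
    impaired: Optional[bool]


@dataclass(frozen=True)
class GoseRating:
    """Merged GOSE/-Q functional-recovery rating.

    ``level`` is the ordinal code 1..7 on the merged 7-level scale
    (labels ``1, 2/3, 4, 5, 6, 7, 8``); None when no source is available.
    """

    level: Optional[int]
    source: str  # interview | questionnaire | interviewer_rating | missing

    @property
    def label(self) -> Optional[str]:
        return None if self.level is None else GOSE_LEVEL_LABELS[self.level - 1]


def default_registry(sf_cutoff: float = 40.0) -> dict[str, InstrumentSpec]:
    """The nine study instruments with their printed ranges and cut-offs.

    ``sf_cutoff`` is the impairment threshold for the SF component T-scores:
    40 (the study rule, 50 minus one SD) by default; 47 reproduces the US
    general-population norm.
    """
    sf = dict(
        direction=HIGHER_BETTER,
        total_range=(0.0, 100.0),
        transform="component_T",
        impairment_threshold=float(sf_cutoff),
        impairment_comparator="lt",
    )
    specs = [
        InstrumentSpec("gad7", HIGHER_WORSE, (0, 21), "sum", 10, "ge",
                       n_items=7, item_range=(0, 3)),
        InstrumentSpec("phq9", HIGHER_WORSE, (0, 27), "sum", 10, "ge",
                       n_items=9, item_range=(0, 3)),
        InstrumentSpec("pcl5", HIGHER_WORSE, (0, 80), "sum", 33, "ge",
                       n_items=20, item_range=(0, 4)),
        InstrumentSpec("rpq", HIGHER_WORSE, (0, 64), "sum", 12, "ge",
                       n_items=16, item_range=(0, 4)),
        InstrumentSpec("qolibri", HIGHER_BETTER, (0, 100), "percent_0_100", 60, "lt",
                       n_items=37, item_range=(1, 5)),
        InstrumentSpec("qolibri_os", HIGHER_BETTER, (0, 100), "percent_0_100", 52, "lt",
                       n_items=6, item_range=(1, 5)),
        InstrumentSpec(name="sf36_pcs", **sf),
        InstrumentSpec(name="sf36_mcs", **sf),
        InstrumentSpec(name="sf12_pcs", **sf),
        InstrumentSpec(name="sf12_mcs", **sf),
    ]
    return {s.name: s for s in specs}


def _is_missing(v) -> bool:
    if v is None:
        return True
    try:
        return math.isnan(float(v))
    except (TypeError, ValueError):
        return False


def score_total(values: Sequence, spec: InstrumentSpec) -> float:
    """Total score from item responses; NaN when too many items are missing.

    Sum scales prorate (observed mean times item count) as long as the
    missing fraction does not exceed ``spec.max_missing_items``; the percent
    transform rescales the observed item mean onto 0-100.
    """
    if spec.transform == "component_T":
        raise ValueError(f"{spec.name}: component T-scores are consumed as "
                         "provided, not scored from items")
    if len(values) != spec.n_items:
        raise ValueError(
            f"{spec.name}: expected {spec.n_items} items, got {len(values)}")
    ilo, ihi = spec.item_range
    observed = []
    for idx, v in enumerate(values):
        if _is_missing(v):
            continue
        v = float(v)
        if not (ilo <= v <= ihi) or v != int(v):
            raise ValueError(
                f"{spec.name}: item {idx + 1} value {v!r} outside {ilo}-{ihi}")
        observed.append(v)
    n_miss = spec.n_items - len(observed)
    if n_miss > spec.max_missing_items * spec.n_items:
        return float("nan")
    mean = float(np.mean(observed))
    if spec.transform == "sum":
        return mean * spec.n_items
    return 100.0 * (mean - ilo) / (ihi - ilo)


def flag_impaired(total: float, spec: InstrumentSpec) -> Optional[bool]:
    """Clinical impairment flag from a total score; None when missing."""
    if _is_missing(total):
        return None
    if spec.impairment_comparator == "ge":
        return total >= spec.impairment_threshold
    return total < spec.impairment_threshold


def orient_score(total: float, spec: InstrumentSpec) -> float:
    """Map a total onto the common higher-is-better axis.

    Symptom scales are reflected by ``x -> max + min - x``, a strictly
    decreasing involution, so effect sizes read uniformly.
    """
    if _is_missing(total):
        return float("nan")
    if spec.direction == HIGHER_BETTER:
        return float(total)
    lo, hi = spec.total_range
    return hi + lo - float(total)


def scored_outcome(total: float, spec: InstrumentSpec) -> ScoredOutcome:
    """Bundle total, oriented value and impairment flag."""
    return ScoredOutcome(spec.name, float("nan") if _is_missing(total) else float(total),
                         orient_score(total, spec), flag_impaired(total, spec))


# --- GOSE / GOSE-Q -----------------------------------------------------------

def collapse_gose(raw_level) -> Optional[int]:
    """Raw 8-level GOSE rating -> merged 7-level ordinal code.

    Raw levels 2 (vegetative state) and 3 (lower severe disability) collapse
    into one category; GOSE-Q sources never emit raw level 2.
    """
    if _is_missing(raw_level):
        return None
    lv = float(raw_level)
    if lv != int(lv) or not 1 <= lv <= 8:
        raise ValueError(f"GOSE level {raw_level!r} outside 1-8")
    lv = int(lv)
    return 1 if lv == 1 else (2 if lv in (2, 3) else lv - 1)


def merge_gose_sources(interview=None, questionnaire=None, rater=None) -> GoseRating:
    """Merge GOSE sources, taking the first available in priority order
    interview -> questionnaire -> interviewer rating."""
    for value, source in ((interview, "interview"),
                          (questionnaire, "questionnaire"),
                          (rater, "interviewer_rating")):
        level = collapse_gose(value)
        if level is not None:
            return GoseRating(level, source)
    return GoseRating(None, "missing")


def gose_impaired(level: Optional[int]) -> Optional[bool]:
    """Recovery not complete: merged level below 7 (ordinal code < 6)."""
    if level is None or _is_missing(level):
        return None
    return int(level) < GOSE_IMPAIRED_BELOW


def gose_oriented(level) -> float:
    """Merged ordinal code used directly as the higher-is-better score."""
    return float("nan") if _is_missing(level) else float(level)


# --- SF-12 backfill ----------------------------------------------------------

def fill_sf12_from_sf36(sf12_items: Sequence, sf36_items: Sequence,
                        mapping: Mapping[int, int]) -> list:
    """Replace missing SF-12v2 items by their SF-36v2 counterparts.

    ``mapping`` pairs each 0-based SF-12 item index with its 0-based SF-36
    index and must cover every SF-12 item. Reported SF-12 values are never
    overwritten.
    """
    if set(mapping) != set(range(len(sf12_items))):
        raise ValueError("mapping must pair every SF-12 item with an SF-36 item")
    out = list(sf12_items)
    for i12, i36 in mapping.items():
        if _is_missing(out[i12]) and not _is_missing(sf36_items[i36]):
            out[i12] = sf36_items[i36]
    return out


# --- cohort-level scoring ----------------------------------------------------

def score_cohort(frame: pd.DataFrame,
                 registry: Optional[dict[str, InstrumentSpec]] = None) -> pd.DataFrame:
    """Score a long-format cohort frame in place of item columns.

    For each registered instrument: compute ``<name>_total`` from
    ``<name>_i<k>`` item columns where no total is provided, then derive
    ``<name>_oriented`` and ``<name>_impaired``. GOSE sources
    (``gose_interview``/``gose_q``/``gose_rater``, raw 1-8) are merged into
    ``gose_level`` (ordinal 1-7 code), ``gose_source``, ``gose_oriented``
    and ``gose_impaired``.
    """
    registry = registry if registry is not None else default_registry()
    out = frame.copy()
    for name, spec in registry.items():
        total_col = f"{name}_total"
        item_cols = [f"{name}_i{k}" for k in range(1, (spec.n_items or 0) + 1)]
        have_items = spec.n_items is not None and all(c in out.columns for c in item_cols)
        if total_col not in out.columns:
            if not have_items:
                continue
            out[total_col] = np.nan
        if have_items:
            need = out[total_col].isna()
            if need.any():
                items = out.loc[need, item_cols]
                out.loc[need, total_col] = [
                    score_total(row, spec) for row in items.to_numpy()
                ]
        totals = out[total_col].astype(float)
        out[f"{name}_oriented"] = [orient_score(t, spec) for t in totals]
        out[f"{name}_impaired"] = [flag_impaired(t, spec) for t in totals]

    if any(c in out.columns for c in ("gose_interview", "gose_q", "gose_rater")):
        def _merge(row):
            return merge_gose_sources(row.get("gose_interview"),
                                      row.get("gose_q"),
                                      row.get("gose_rater"))
        ratings = [_merge(row) for _, row in out.iterrows()]
        out["gose_level"] = [r.level if r.level is not None else np.nan for r in ratings]
        out["gose_source"] = [r.source for r in ratings]
    if "gose_level" in out.columns:
        out["gose_oriented"] = [gose_oriented(v) for v in out["gose_level"]]
        out["gose_impaired"] = [gose_impaired(v) if not _is_missing(v) else None
                                for v in out["gose_level"]]
    return out
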