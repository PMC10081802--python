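"""Patient groups, severity and recovery strata, comparison enumeration.

Two analysis designs are supported:

* design A — the six a-priori grouping factors (sex, age, education,
  premorbid psychological status, clinical care pathway, extracranial
  injury severity) contrasted within each of the four TBI-severity strata,
  on all instruments including the merged GOSE/-Q;
* design B — functional-recovery levels (good recovery 7-8, moderate
  disability 5-6, severe disability 2/3-4) contrasted within each patient
  group, on the patient-reported outcome scores only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ComparisonSpec",
    "classify_tbi_severity",
    "derive_binary_groups",
    "recovery_stratum",
    "enumerate_comparisons",
    "TBI_SEVERITY_LEVELS",
    "RECOVERY_LEVELS",
    "DESIGN_A_FACTORS",
    "PROM_SCORES",
    "ALL_SCORES",
]

TBI_SEVERITY_LEVELS = ("uncomplicated_mild", "complicated_mild", "moderate", "severe")
RECOVERY_LEVELS = ("good_recovery", "moderate_disability", "severe_disability")

#: design-A factor contrasts, arm 1 first (reference level). The clinical
#: pathway enters as three pairwise contrasts.
DESIGN_A_FACTORS: tuple[tuple[str, tuple[str, str]], ...] = (
    ("sex", ("male", "female")),
    ("age", ("<65", ">=65")),
    ("education", ("at_least_secondary", "primary_or_less")),
    ("premorbid_psych", ("absent", "present")),
    ("pathway", ("ER", "ADM")),
    ("pathway", ("ER", "ICU")),
    ("pathway", ("ADM", "ICU")),
    ("iss", ("<10", ">=10")),
)

#: recovery contrasts for design B, better recovery first.
RECOVERY_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("good_recovery", "moderate_disability"),
    ("good_recovery", "severe_disability"),
    ("moderate_disability", "severe_disability"),
)

PROM_SCORES = ("sf36_pcs", "sf36_mcs", "sf12_pcs", "sf12_mcs",
               "qolibri", "qolibri_os", "gad7", "phq9", "pcl5", "rpq")
ALL_SCORES = ("gose",) + PROM_SCORES


@dataclass(frozen=True)
class ComparisonSpec:
    """One pairwise group comparison with resolved arm memberships."""

    design: str                     # "A" | "B"
    timepoint: int
    context: str                    # severity stratum (A) or patient group (B)
    factor: str                     # grouping factor (A) or "recovery" (B)
    arm1: str
    arm2: str
    instruments: tuple[str, ...]
    idx1: np.ndarray = field(repr=False)  # row indices into the time-point frame
    idx2: np.ndarray = field(repr=False)
    feasible: bool = True
    reason: str = ""

    @property
    def n1(self) -> int:
        return int(len(self.idx1))

    @property
    def n2(self) -> int:
        return int(len(self.idx2))


def classify_tbi_severity(gcs: int, ct_abnormal: bool) -> str:
    """GCS + CT-finding based TBI severity.

    GCS >= 13 without CT abnormality -> uncomplicated mild; with abnormality
    -> complicated mild; 9 <= GCS <= 12 -> moderate; GCS <= 8 -> severe.
    """
    if not (3 <= gcs <= 15):
        raise ValueError(f"GCS {gcs} outside 3-15")
    if gcs >= 13:
        return "complicated_mild" if ct_abnormal else "uncomplicated_mild"
    if gcs >= 9:
        return "moderate"
    return "severe"


def recovery_stratum(gose_level) -> Optional[str]:
    """Merged GOSE/-Q ordinal code -> recovery stratum.

    Codes 2-3 (labels 2/3 and 4) -> severe disability; 4-5 (labels 5, 6) ->
    moderate disability; 6-7 (labels 7, 8) -> good recovery. Level 1 (dead)
    is excluded from the strata (no self-report is possible) and a missing
    level maps to no stratum.
    """
    if gose_level is None or (isinstance(gose_level, float) and math.isnan(gose_level)):
        return None
    lv = int(gose_level)
    if not 1 <= lv <= 7:
        raise ValueError(f"merged GOSE code {gose_level!r} outside 1-7")
    if lv == 1:
        return None
    if lv <= 3:
        return "severe_disability"
    if lv <= 5:
        return "moderate_disability"
    return "good_recovery"


def derive_binary_groups(frame: pd.DataFrame) -> pd.DataFrame:
    """Attach derived grouping columns to a scored cohort frame.

    Adds ``grp_sex``, ``grp_age`` (<65 / >=65, the boundary in the older
    group), ``grp_education``, ``grp_premorbid_psych``, ``grp_pathway``,
    ``grp_iss`` (<10 / >=10), ``tbi_severity`` and ``recovery``.
    Missing covariates leave the factor unavailable (NaN) for that record.
    """
    out = frame.copy()
    out["grp_sex"] = out["sex"].where(out["sex"].isin(["male", "female"]))
    age = pd.to_numeric(out["age_years"], errors="coerce")
    out["grp_age"] = np.where(age.isna(), None,
                              np.where(age >= 65, ">=65", "<65"))
    out["grp_education"] = out["education"].where(
        out["education"].isin(["primary_or_less", "at_least_secondary"]))
    out["grp_premorbid_psych"] = out["premorbid_psych"].where(
        out["premorbid_psych"].isin(["absent", "present"]))
    out["grp_pathway"] = out["pathway"].where(out["pathway"].isin(["ER", "ADM", "ICU"]))
    iss = pd.to_numeric(out["iss"], errors="coerce")
    out["grp_iss"] = np.where(iss.isna(), None, np.where(iss >= 10, ">=10", "<10"))

    gcs = pd.to_numeric(out["gcs"], errors="coerce")
    ct = out["ct_abnormal"]
    sev = []
    for g, c in zip(gcs, ct):
        if np.isnan(g) or pd.isna(c):
            sev.append(None)
        else:
            sev.append(classify_tbi_severity(int(g), bool(c)))
    out["tbi_severity"] = sev
    if "gose_level" in out.columns:
        out["recovery"] = [recovery_stratum(v) for v in out["gose_level"]]
    else:
        out["recovery"] = None
    return out


def _factor_column(factor: str) -> str:
    return "tbi_severity" if factor == "tbi_severity" else f"grp_{factor}"


def _design_b_groups(frame: pd.DataFrame) -> list[tuple[str, str]]:
    """(factor, level) patient-group contexts for design B: the six a-priori
    factors plus the four TBI-severity strata."""
    groups: list[tuple[str, str]] = []
    for factor, levels in (("sex", ("male", "female")),
                           ("age", ("<65", ">=65")),
                           ("education", ("at_least_secondary", "primary_or_less")),
                           ("premorbid_psych", ("absent", "present")),
                           ("pathway", ("ER", "ADM", "ICU")),
                           ("iss", ("<10", ">=10")),
                           ("tbi_severity", TBI_SEVERITY_LEVELS)):
        groups.extend((factor, lv) for lv in levels)
    return groups


def enumerate_comparisons(frame: pd.DataFrame, design: str, timepoint: int,
                          min_arm_n: int = 10,
                          instruments: Optional[Sequence[str]] = None,
                          ) -> list[ComparisonSpec]:
    """Enumerate the pairwise comparisons of one design at one time point.

    ``frame`` must be a scored, grouped cohort frame already restricted to
    ``timepoint``. Comparisons whose either arm has fewer than ``min_arm_n``
    members are emitted flagged infeasible (and excluded from summaries
    downstream).
    """
    if design not in ("A", "B"):
        raise ValueError(f"unknown design {design!r}")
    if min_arm_n < 1:
        raise ValueError("min_arm_n must be >= 1")
    specs: list[ComparisonSpec] = []
    if design == "A":
        instruments = tuple(instruments) if instruments is not None else ALL_SCORES
        for stratum in TBI_SEVERITY_LEVELS:
            in_stratum = frame["tbi_severity"] == stratum
            for factor, (a1, a2) in DESIGN_A_FACTORS:
                col = _factor_column(factor)
                idx1 = frame.index[in_stratum & (frame[col] == a1)].to_numpy()
                idx2 = frame.index[in_stratum & (frame[col] == a2)].to_numpy()
                feasible = len(idx1) >= min_arm_n and len(idx2) >= min_arm_n
                specs.append(ComparisonSpec(
                    "A", timepoint, stratum, factor, a1, a2, instruments,
                    idx1, idx2, feasible,
                    "" if feasible else f"arm below min_arm_n={min_arm_n}"))
    else:
        instruments = tuple(instruments) if instruments is not None else PROM_SCORES
        for factor, level in _design_b_groups(frame):
            col = _factor_column(factor)
            in_group = frame[col] == level
            context = f"{factor}:{level}"
            for a1, a2 in RECOVERY_CONTRASTS:
                idx1 = frame.index[in_group & (frame["recovery"] == a1)].to_numpy()
                idx2 = frame.index[in_group & (frame["recovery"] == a2)].to_numpy()
                feasible = len(idx1) >= min_arm_n and len(idx2) >= min_arm_n
                specs.append(ComparisonSpec(
                    "B", timepoint, context, "recovery", a1, a2, instruments,
                    idx1, idx2, feasible,
                    "" if feasible else f"arm below min_arm_n={min_arm_n}"))
    return specs
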