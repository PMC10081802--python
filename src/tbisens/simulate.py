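"""Synthetic TBI cohort generator.

Emulates the statistical structure the sensitivity analysis assumes, so the
whole pipeline is testable without access-controlled registry data:

* a Gaussian copula over K = 11 latent outcome domains (merged GOSE plus
  ten PROM scores) with moderate-to-high correlations except a low PCS-MCS
  block;
* monotone quantile maps from each latent onto the instrument's discrete
  native scale (beta-binomial shapes skewed toward health, calibrated so
  impairment prevalences fall in clinically reported bands);
* an ordinal cut of the GOSE latent (7 merged levels incl. death);
* group effects as latent location shifts calibrated to target MW effect
  sizes via ``delta = sqrt(2) * Phi^-1(theta)``, mean-centered within each
  factor so marginal distributions stay put;
* a subject-level random effect linking the three assessment months, and a
  small improvement trend over time;
* MCAR missingness per instrument and time point, with GOSE interview
  missingness inside the reported 14-21% band and a GOSE-Q shadow rating
  that substitutes most missing interviews.

Because the MW statistic is rank-invariant, a latent-scale theta target
transfers to the discrete score scale exactly up to ties introduced by
discretization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimulationConfig",
    "shift_for_target_mw",
    "effects_from_targets",
    "default_sigma",
    "default_effects",
    "generate_cohort",
    "apply_missingness",
    "attach_goseq_shadow",
    "SCORE_DOMAINS",
]

#: latent domain order; index 0 is the GOSE functional-recovery latent.
SCORE_DOMAINS: tuple[str, ...] = (
    "gose", "sf36_pcs", "sf36_mcs", "sf12_pcs", "sf12_mcs",
    "qolibri", "qolibri_os", "gad7", "phq9", "pcl5", "rpq",
)

#: beta-binomial quantile-map shapes (N, a, b) per discrete instrument,
#: on the *symptom* scale for higher-worse instruments (mapped from 1-u) and
#: on the score scale for QOLIBRI/-OS. Calibrated so marginal impairment
#: prevalences land in clinically reported bands.
MARGINAL_SHAPES: dict[str, tuple[int, float, float]] = {
    "gad7": (21, 1.0, 4.5),
    "phq9": (27, 1.0, 5.0),
    "pcl5": (80, 0.8, 4.0),
    "rpq": (64, 0.7, 2.8),
    "qolibri": (100, 3.2, 1.3),
    "qolibri_os": (100, 2.4, 1.1),
}

#: merged-scale GOSE category probabilities (1, 2/3, 4, 5, 6, 7, 8);
#: P(level < 7) = 0.43. The interview splits the 2/3 mass 0.02 / 0.06.
GOSE_PROBS: tuple[float, ...] = (0.02, 0.08, 0.08, 0.12, 0.13, 0.27, 0.30)
GOSE_INTERVIEW_PROBS: tuple[float, ...] = (0.02, 0.02, 0.06, 0.08, 0.12, 0.13, 0.27, 0.30)


def default_sigma() -> np.ndarray:
    """Default latent correlation matrix.

    Moderate baseline (0.45) everywhere; same-construct long/short forms at
    0.85; the mental-health cluster (MCS forms, GAD-7, PHQ-9, PCL-5) at 0.6;
    GOSE tied more closely to physical HRQOL; and a deliberately low 0.15
    between every PCS and MCS pair, so that after group shifts (which add a
    little common variance across domains) the observed Spearman stays below
    0.30, mirroring the reported low physical-mental correlation.
    """
    idx = {d: i for i, d in enumerate(SCORE_DOMAINS)}
    K = len(SCORE_DOMAINS)
    sig = np.full((K, K), 0.45)
    np.fill_diagonal(sig, 1.0)

    def put(a: str, b: str, r: float) -> None:
        sig[idx[a], idx[b]] = sig[idx[b], idx[a]] = r

    put("sf36_pcs", "sf12_pcs", 0.85)
    put("sf36_mcs", "sf12_mcs", 0.85)
    put("qolibri", "qolibri_os", 0.85)
    mental = ("sf36_mcs", "sf12_mcs", "gad7", "phq9", "pcl5")
    for i, a in enumerate(mental):
        for b in mental[i + 1:]:
            if sig[idx[a], idx[b]] < 0.6:
                put(a, b, 0.6)
    for pcs in ("sf36_pcs", "sf12_pcs"):
        for mcs in ("sf36_mcs", "sf12_mcs"):
            put(pcs, mcs, 0.15)
        put("gose", pcs, 0.6)
    for q in ("qolibri", "qolibri_os"):
        put("gose", q, 0.55)
    return sig


def default_effects() -> dict[tuple[str, str], dict[str, float]]:
    """Default group latent shifts (negative = worse outcomes).

    Per (factor, level); the special key ``"all"`` applies to every domain
    unless an instrument-specific entry overrides it. Reference levels
    (male, <65, at_least_secondary, absent, ER, <10, uncomplicated_mild)
    carry no entry. Magnitudes are plausibility choices: e.g. -0.25 on the
    latent corresponds to a pairwise MW effect of about 0.57.

    The functional-recovery latent separates groups most strongly — the
    GOSE is the clinically most group-sensitive instrument — followed by
    physical HRQOL for injury-related factors and the mental-health cluster
    for premorbid psychological problems.
    """
    mental_extra = {dom: -0.50 for dom in ("sf36_mcs", "sf12_mcs", "gad7", "phq9", "pcl5")}
    physical_extra = {"sf36_pcs": -0.50, "sf12_pcs": -0.50, "rpq": -0.45,
                      "qolibri": -0.40, "qolibri_os": -0.40}
    return {
        ("sex", "female"): {"all": -0.25, "gose": -0.40},
        ("age", ">=65"): {"all": -0.35, "gose": -0.70,
                          "sf36_pcs": -0.55, "sf12_pcs": -0.55},
        ("education", "primary_or_less"): {"all": -0.20, "gose": -0.35},
        ("premorbid_psych", "present"): {"all": -0.15, "gose": -0.30, **mental_extra},
        ("pathway", "ADM"): {"all": -0.25, "gose": -0.45},
        ("pathway", "ICU"): {"all": -0.50, "gose": -0.90,
                             "sf36_pcs": -0.65, "sf12_pcs": -0.65},
        ("iss", ">=10"): {"all": -0.20, "gose": -0.60, **physical_extra},
        ("tbi_severity", "complicated_mild"): {"all": -0.20, "gose": -0.30},
        ("tbi_severity", "moderate"): {"all": -0.45, "gose": -0.65},
        ("tbi_severity", "severe"): {"all": -0.80, "gose": -1.20},
    }


def _default_missingness() -> dict[str, dict[int, float]]:
    prom = {3: 0.20, 6: 0.22, 12: 0.30}
    rates: dict[str, dict[int, float]] = {d: dict(prom) for d in SCORE_DOMAINS[1:]}
    rates["gose_interview"] = {3: 0.18, 6: 0.16, 12: 0.20}
    rates["gose_q"] = {3: 0.15, 6: 0.15, 12: 0.15}
    rates["gose_rater"] = {3: 0.70, 6: 0.70, 12: 0.70}
    return rates


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults emulate the observed cohort composition: ~65% male, ~25% aged
    65+, ~70% with at least secondary education, ~35% premorbid psychological
    problems, pathway mix 25/30/45 (ER/ADM/ICU), TBI severity mix
    36/36/8/20 (uncomplicated mild/complicated mild/moderate/severe) and
    ~60% with ISS >= 10.
    """

    n_subjects: int = 3000
    timepoints: tuple[int, ...] = (3, 6, 12)
    seed: Optional[int] = None

    p_male: float = 0.65
    age_mean: float = 52.0
    age_sd: float = 19.0
    p_secondary: float = 0.70
    p_premorbid: float = 0.35
    p_pathway: tuple[float, float, float] = (0.25, 0.30, 0.45)  # ER, ADM, ICU
    p_severity: tuple[float, float, float, float] = (0.36, 0.36, 0.08, 0.20)
    iss_shape: float = 2.0
    iss_scale: float = 7.0

    sigma: np.ndarray = field(default_factory=default_sigma)
    effects: dict = field(default_factory=default_effects)
    gose_interview_probs: tuple[float, ...] = GOSE_INTERVIEW_PROBS
    subject_corr: float = 0.7
    time_trend: dict = field(default_factory=lambda: {3: 0.0, 6: 0.15, 12: 0.25})

    missingness: dict = field(default_factory=_default_missingness)
    goseq_agreement: float = 0.8
    rater_agreement: float = 0.9
    with_missingness: bool = True

    def validate(self) -> None:
        sig = np.asarray(self.sigma, dtype=float)
        K = len(SCORE_DOMAINS)
        if sig.shape != (K, K):
            raise ValueError(f"sigma must be {K}x{K} over {SCORE_DOMAINS}")
        if not np.allclose(sig, sig.T):
            raise ValueError("sigma must be symmetric")
        if not np.allclose(np.diag(sig), 1.0):
            raise ValueError("sigma must have unit diagonal")
        eigmin = float(np.linalg.eigvalsh(sig).min())
        if eigmin <= 1e-10:
            raise ValueError(f"sigma not positive definite (min eigenvalue {eigmin:.3g})")
        for p in (self.p_male, self.p_secondary, self.p_premorbid,
                  *self.p_pathway, *self.p_severity):
            if not 0.0 < p < 1.0:
                raise ValueError("prevalences must lie in (0, 1)")
        if not math.isclose(sum(self.p_pathway), 1.0, abs_tol=1e-9):
            raise ValueError("pathway probabilities must sum to 1")
        if not math.isclose(sum(self.p_severity), 1.0, abs_tol=1e-9):
            raise ValueError("severity probabilities must sum to 1")
        if not math.isclose(sum(self.gose_interview_probs), 1.0, abs_tol=1e-9):
            raise ValueError("GOSE probabilities must sum to 1")
        if not 0.0 <= self.subject_corr < 1.0:
            raise ValueError("subject_corr must be in [0, 1)")
        if not 0.0 < self.goseq_agreement <= 1.0:
            raise ValueError("goseq_agreement must be in (0, 1]")
        for instr, rate in self.missingness.items():
            vals = rate.values() if isinstance(rate, Mapping) else [rate]
            for r in vals:
                if not 0.0 <= r <= 1.0:
                    raise ValueError(f"missingness rate for {instr} outside [0, 1]")

    def null(self) -> "SimulationConfig":
        """Copy with all group effects removed (global stochastic equality)."""
        return replace(self, effects={})


def shift_for_target_mw(theta_target: float) -> float:
    """Latent shift achieving a target MW effect for normal latents.

    Two unit-variance normal latents whose means differ by
    ``delta = sqrt(2) * Phi^-1(theta)`` satisfy P(X > Y) = theta.
    Boundary targets 0 and 1 are rejected (no finite shift exists).
    """
    if not 0.0 < theta_target < 1.0:
        raise ValueError("theta target must lie strictly inside (0, 1)")
    return math.sqrt(2.0) * float(stats.norm.ppf(theta_target))


def effects_from_targets(targets: Mapping[tuple[str, str], Mapping[str, float]],
                         ) -> dict[tuple[str, str], dict[str, float]]:
    """Convert (factor, level) -> {instrument: theta target} into latent
    shifts, where theta is the target MW effect of the *reference* level
    over the given level (theta > 0.5 means the given level fares worse)."""
    return {key: {instr: -shift_for_target_mw(t) for instr, t in spec.items()}
            for key, spec in targets.items()}


def _level_prevalences(cfg: SimulationConfig) -> dict[tuple[str, str], float]:
    """Analytic level prevalences used for mean-centering the shifts."""
    p_old = float(stats.norm.sf(65.0, loc=cfg.age_mean, scale=cfg.age_sd))
    p_iss_hi = float(stats.gamma.sf(9.5, cfg.iss_shape, scale=cfg.iss_scale))
    prev = {
        ("sex", "male"): cfg.p_male, ("sex", "female"): 1 - cfg.p_male,
        ("age", "<65"): 1 - p_old, ("age", ">=65"): p_old,
        ("education", "at_least_secondary"): cfg.p_secondary,
        ("education", "primary_or_less"): 1 - cfg.p_secondary,
        ("premorbid_psych", "absent"): 1 - cfg.p_premorbid,
        ("premorbid_psych", "present"): cfg.p_premorbid,
        ("pathway", "ER"): cfg.p_pathway[0],
        ("pathway", "ADM"): cfg.p_pathway[1],
        ("pathway", "ICU"): cfg.p_pathway[2],
        ("iss", "<10"): 1 - p_iss_hi, ("iss", ">=10"): p_iss_hi,
    }
    for lvl, p in zip(("uncomplicated_mild", "complicated_mild", "moderate", "severe"),
                      cfg.p_severity):
        prev[("tbi_severity", lvl)] = p
    return prev


def _shift_matrix(cfg: SimulationConfig, factors: pd.DataFrame) -> np.ndarray:
    """Per-subject latent shift for each domain, mean-centered per factor."""
    n = len(factors)
    K = len(SCORE_DOMAINS)
    shifts = np.zeros((n, K))
    prev = _level_prevalences(cfg)
    by_factor: dict[str, list[tuple[str, dict]]] = {}
    for (factor, level), spec in cfg.effects.items():
        by_factor.setdefault(factor, []).append((level, dict(spec)))
    for factor, levels in by_factor.items():
        col = factors[factor].to_numpy()
        for k, dom in enumerate(SCORE_DOMAINS):
            # weighted mean shift over all levels (absent levels shift 0)
            mean_shift = sum(prev[(factor, lvl)] * spec.get(dom, spec.get("all", 0.0))
                             for lvl, spec in levels)
            for lvl, spec in levels:
                delta = spec.get(dom, spec.get("all", 0.0))
                shifts[col == lvl, k] += delta - mean_shift
            matched = np.isin(col, [lvl for lvl, _ in levels])
            shifts[~matched, k] += -mean_shift
    return shifts


def _quantile_map(u: np.ndarray, domain: str, latent: np.ndarray) -> np.ndarray:
    """Monotone map from the health latent onto the instrument scale."""
    if domain in ("sf36_pcs", "sf36_mcs", "sf12_pcs", "sf12_mcs"):
        return np.clip(np.round(45.0 + 10.0 * latent, 1), 0.0, 100.0)
    N, a, b = MARGINAL_SHAPES[domain]
    table = stats.betabinom.cdf(np.arange(N + 1), N, a, b)
    if domain in ("qolibri", "qolibri_os"):
        q = u                       # higher latent -> higher (better) score
    else:
        q = 1.0 - u                 # higher latent -> fewer symptoms
    return np.searchsorted(table, q, side="left").clip(0, N).astype(float)


def _gose_raw(latent: np.ndarray, probs: Sequence[float]) -> np.ndarray:
    """Ordinal cut of the GOSE latent into raw interview levels 1..8."""
    cuts = stats.norm.ppf(np.cumsum(probs)[:-1])
    return (np.searchsorted(cuts, latent, side="right") + 1).astype(float)


def generate_cohort(config: Optional[SimulationConfig] = None,
                    seed: Optional[int] = None) -> pd.DataFrame:
    """Generate a long-format cohort (one row per subject x time point).

    Columns: subject_id, timepoint_months, the covariates, raw GOSE sources
    (``gose_interview`` 1-8, ``gose_q``/``gose_rater`` with 3 standing for
    the combined 2/3 category) and one ``<instrument>_total`` column per
    PROM score. Deterministic for a fixed config and seed.
    """
    cfg = config if config is not None else SimulationConfig()
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    n = cfg.n_subjects
    K = len(SCORE_DOMAINS)

    sex = rng.choice(["male", "female"], n, p=[cfg.p_male, 1 - cfg.p_male])
    age = np.clip(np.round(rng.normal(cfg.age_mean, cfg.age_sd, n)), 16, 95)
    education = rng.choice(["at_least_secondary", "primary_or_less"], n,
                           p=[cfg.p_secondary, 1 - cfg.p_secondary])
    premorbid = rng.choice(["absent", "present"], n,
                           p=[1 - cfg.p_premorbid, cfg.p_premorbid])
    pathway = rng.choice(["ER", "ADM", "ICU"], n, p=list(cfg.p_pathway))
    severity = rng.choice(["uncomplicated_mild", "complicated_mild",
                           "moderate", "severe"], n, p=list(cfg.p_severity))
    gcs = np.empty(n, dtype=int)
    ct = np.empty(n, dtype=bool)
    for i, sev in enumerate(severity):
        if sev in ("uncomplicated_mild", "complicated_mild"):
            gcs[i] = rng.choice([13, 14, 15], p=[0.15, 0.25, 0.60])
            ct[i] = sev == "complicated_mild"
        elif sev == "moderate":
            gcs[i] = rng.integers(9, 13)
            ct[i] = rng.random() < 0.9
        else:
            gcs[i] = rng.integers(3, 9)
            ct[i] = rng.random() < 0.95
    iss = np.rint(rng.gamma(cfg.iss_shape, cfg.iss_scale, n)).astype(int)

    factors = pd.DataFrame({
        "sex": sex,
        "age": np.where(age >= 65, ">=65", "<65"),
        "education": education,
        "premorbid_psych": premorbid,
        "pathway": pathway,
        "iss": np.where(iss >= 10, ">=10", "<10"),
        "tbi_severity": severity,
    })
    shifts = _shift_matrix(cfg, factors)

    chol = np.linalg.cholesky(np.asarray(cfg.sigma, dtype=float))
    subject_lat = rng.standard_normal((n, K)) @ chol.T
    r = cfg.subject_corr

    rows = []
    dead = np.zeros(n, dtype=bool)
    for tp in cfg.timepoints:
        eps = rng.standard_normal((n, K)) @ chol.T
        lat = (math.sqrt(r) * subject_lat + math.sqrt(1 - r) * eps
               + shifts + cfg.time_trend.get(tp, 0.0))
        u = stats.norm.cdf(lat)
        gose_raw = _gose_raw(lat[:, 0], cfg.gose_interview_probs)
        dead |= gose_raw == 1          # death is absorbing across time
        gose_raw[dead] = 1.0
        frame = pd.DataFrame({
            "subject_id": [f"S{i:05d}" for i in range(n)],
            "timepoint_months": tp,
            "sex": sex,
            "age_years": age,
            "education": education,
            "premorbid_psych": premorbid,
            "pathway": pathway,
            "gcs": gcs,
            "ct_abnormal": ct,
            "iss": iss,
            "gose_interview": gose_raw,
        })
        for k, dom in enumerate(SCORE_DOMAINS[1:], start=1):
            scores = _quantile_map(u[:, k], dom, lat[:, k])
            scores[dead] = np.nan      # no self-report after death
            frame[f"{dom}_total"] = scores
        rows.append(frame)
    cohort = pd.concat(rows, ignore_index=True)

    cohort = attach_goseq_shadow(cohort, cfg.goseq_agreement, rng=rng)
    cohort = _attach_rater(cohort, cfg.rater_agreement, rng=rng)
    if cfg.with_missingness:
        cohort = apply_missingness(cohort, cfg.missingness, rng=rng)
    return cohort


def _merged_to_raw(merged: np.ndarray) -> np.ndarray:
    """Merged 7-level codes back to raw coding (3 stands for the 2/3 mass)."""
    raw = merged + 1.0
    raw[merged == 1] = 1.0
    return raw


def attach_goseq_shadow(cohort: pd.DataFrame, agreement: float,
                        rng: Optional[np.random.Generator] = None,
                        seed: Optional[int] = None) -> pd.DataFrame:
    """Attach a GOSE-Q rating that shadows the interview rating.

    With probability ``agreement`` the GOSE-Q equals the collapsed interview
    level; otherwise it moves one level up or down on the merged scale,
    clipped to the self-reportable range (2/3 .. 8). Death has no
    questionnaire rating.
    """
    if not 0.0 < agreement <= 1.0:
        raise ValueError("agreement must be in (0, 1]")
    rng = rng if rng is not None else np.random.default_rng(seed)
    out = cohort.copy()
    raw = out["gose_interview"].to_numpy(dtype=float)
    merged = np.where(np.isnan(raw), np.nan,
                      np.where(raw <= 1, 1, np.where(raw <= 3, 2, raw - 1)))
    agree = rng.random(len(out)) < agreement
    step = rng.choice([-1.0, 1.0], len(out))
    shadow = np.where(agree, merged, np.clip(merged + step, 2, 7))
    shadow[np.isnan(merged) | (merged == 1)] = np.nan
    out["gose_q"] = _merged_to_raw(shadow)
    return out


def _attach_rater(cohort: pd.DataFrame, agreement: float,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Central interviewer rating: shadows the interview like the GOSE-Q but
    is rated on the full raw scale and can rate death."""
    out = cohort.copy()
    raw = out["gose_interview"].to_numpy(dtype=float)
    agree = rng.random(len(out)) < agreement
    step = rng.choice([-1.0, 1.0], len(out))
    rater = np.where(agree, raw, np.clip(raw + step, 1, 8))
    out["gose_rater"] = rater
    return out


def apply_missingness(cohort: pd.DataFrame, rates: Mapping,
                      rng: Optional[np.random.Generator] = None,
                      seed: Optional[int] = None) -> pd.DataFrame:
    """Mask outcomes missing-completely-at-random.

    ``rates`` maps an instrument (``<name>`` for ``<name>_total`` columns,
    or ``gose_interview``/``gose_q``/``gose_rater``) to a rate or to a
    per-time-point mapping ``{months: rate}``.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    out = cohort.copy()
    tps = out["timepoint_months"].to_numpy()
    for instr, rate in rates.items():
        col = instr if instr.startswith("gose_") else f"{instr}_total"
        if col not in out.columns:
            continue
        per_tp = rate if isinstance(rate, Mapping) else {tp: rate for tp in set(tps)}
        for tp, r in per_tp.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missingness rate {r} outside [0, 1]")
            sel = tps == tp
            mask = rng.random(int(sel.sum())) < r
            vals = out.loc[sel, col].to_numpy(dtype=float)
            vals[mask] = np.nan
            out.loc[sel, col] = vals
    return out
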