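"""Synthetic cohort generator: calibration, structure, missingness."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tbisens as tb
from tbisens.simulate import MARGINAL_SHAPES, SCORE_DOMAINS, _default_missingness


@pytest.mark.parametrize("target,expected", [
    (0.5, 0.0),
    (0.71, math.sqrt(2) * stats.norm.ppf(0.71)),   # ~ +0.7827
    (0.29, -math.sqrt(2) * stats.norm.ppf(0.71)),  # symmetric
])
def test_shift_for_target_mw(target, expected):
    assert tb.shift_for_target_mw(target) == pytest.approx(expected, abs=1e-12)
    assert tb.shift_for_target_mw(0.71) == pytest.approx(0.7827, abs=5e-4)


@pytest.mark.parametrize("bad", [0.0, 1.0, -0.1])
def test_shift_rejects_boundary_targets(bad):
    with pytest.raises(ValueError):
        tb.shift_for_target_mw(bad)


def test_shift_calibration_by_pair_simulation(rng):
    delta = tb.shift_for_target_mw(0.71)
    x = rng.normal(delta, 1, 200_000)
    y = rng.normal(0, 1, 200_000)
    assert np.mean(x > y) == pytest.approx(0.71, abs=0.005)


def test_effects_from_targets_inverts_to_shifts():
    eff = tb.effects_from_targets({("sex", "female"): {"rpq": 0.71}})
    assert eff[("sex", "female")]["rpq"] == pytest.approx(-tb.shift_for_target_mw(0.71))


def test_fixed_seed_reproducibility():
    cfg = tb.SimulationConfig(n_subjects=150)
    a = tb.generate_cohort(cfg, seed=5).to_csv(index=False)
    b = tb.generate_cohort(cfg, seed=5).to_csv(index=False)
    c = tb.generate_cohort(cfg, seed=6).to_csv(index=False)
    assert a == b
    assert a != c


def test_non_positive_definite_sigma_rejected():
    sigma = np.ones((len(SCORE_DOMAINS),) * 2)
    with pytest.raises(ValueError, match="positive definite"):
        tb.SimulationConfig(sigma=sigma).validate()


@pytest.fixture(scope="module")
def default_cohort():
    cfg = tb.SimulationConfig(n_subjects=2000)
    return tb.prepare_cohort(tb.generate_cohort(cfg, seed=42))


def test_null_config_gives_theta_near_half():
    # ~2000 per arm so the +-0.03 band sits at more than 3 sampling SDs
    cfg = tb.SimulationConfig(n_subjects=4000, with_missingness=False).null()
    frame = tb.prepare_cohort(tb.generate_cohort(cfg, seed=77))
    tp = frame[frame["timepoint_months"] == 3]
    for factor, (a1, a2) in (("sex", ("male", "female")),
                             ("iss", ("<10", ">=10"))):
        for instrument in ("rpq", "sf36_pcs", "gose"):
            x = tp.loc[tp[f"grp_{factor}"] == a1, f"{instrument}_oriented"]
            y = tp.loc[tp[f"grp_{factor}"] == a2, f"{instrument}_oriented"]
            assert tb.mw_effect(x, y).theta == pytest.approx(0.5, abs=0.03)


def test_configured_theta_target_is_recovered_on_near_continuous_scale():
    # the T-score scale has ~1000 attainable levels, so discretization ties
    # barely shrink the latent-scale target
    cfg = tb.SimulationConfig(
        n_subjects=4000, timepoints=(3,), with_missingness=False,
        effects=tb.effects_from_targets({("sex", "female"): {"sf36_pcs": 0.71}}))
    frame = tb.prepare_cohort(tb.generate_cohort(cfg, seed=9))
    x = frame.loc[frame["grp_sex"] == "male", "sf36_pcs_oriented"]
    y = frame.loc[frame["grp_sex"] == "female", "sf36_pcs_oriented"]
    assert tb.mw_effect(x, y).theta == pytest.approx(0.71, abs=0.025)


def test_discretization_gap_shrinks_with_scale_resolution():
    # same latent shift; coarser scales lose more of it to ties
    cfg = tb.SimulationConfig(
        n_subjects=4000, timepoints=(3,), with_missingness=False,
        effects={("sex", "female"): {"all": -tb.shift_for_target_mw(0.71)}})
    frame = tb.prepare_cohort(tb.generate_cohort(cfg, seed=10))
    male = frame["grp_sex"] == "male"
    gaps = {}
    for instrument in ("sf36_pcs", "pcl5", "gad7", "gose"):
        theta = tb.mw_effect(frame.loc[male, f"{instrument}_oriented"],
                             frame.loc[~male, f"{instrument}_oriented"]).theta
        gaps[instrument] = 0.71 - theta
    assert all(g >= -0.02 for g in gaps.values())     # ties only ever shrink
    assert gaps["sf36_pcs"] < gaps["gad7"] + 0.02      # finer scale, smaller gap
    assert gaps["sf36_pcs"] < gaps["gose"]             # 7-level ordinal loses most


def test_missingness_rates_and_validation(rng):
    cfg = tb.SimulationConfig(n_subjects=2000, with_missingness=False)
    cohort = tb.generate_cohort(cfg, seed=3)
    unchanged = tb.apply_missingness(cohort, {"gad7": 0.0}, seed=1)
    pd.testing.assert_frame_equal(unchanged, cohort)
    all_gone = tb.apply_missingness(cohort, {"gad7": {12: 1.0}}, seed=1)
    assert all_gone.query("timepoint_months == 12")["gad7_total"].isna().all()
    masked = tb.apply_missingness(cohort, {"gose_interview": 0.18}, seed=1)
    alive = cohort["gose_interview"].notna()
    rate = masked.loc[alive, "gose_interview"].isna().mean()
    assert rate == pytest.approx(0.18, abs=0.02)
    with pytest.raises(ValueError, match="outside"):
        tb.apply_missingness(cohort, {"gad7": 1.5}, seed=1)


def test_goseq_shadow_agreement_and_neighbour_rule():
    cfg = tb.SimulationConfig(n_subjects=1500, timepoints=(3,),
                              with_missingness=False)
    cohort = tb.generate_cohort(cfg, seed=12)
    exact = tb.attach_goseq_shadow(cohort.drop(columns="gose_q"), 1.0, seed=1)
    alive = cohort["gose_interview"] > 1
    merged = cohort.loc[alive, "gose_interview"].map(tb.collapse_gose)
    assert (exact.loc[alive, "gose_q"].map(tb.collapse_gose) == merged).all()
    noisy = tb.attach_goseq_shadow(cohort.drop(columns="gose_q"), 0.5, seed=2)
    diff = noisy.loc[alive, "gose_q"].map(tb.collapse_gose) - merged
    assert diff.abs().max() <= 1                        # neighbour moves only
    assert noisy.loc[alive, "gose_q"].map(tb.collapse_gose).between(2, 7).all()


def test_goseq_substitution_reduces_gose_missingness():
    cfg = tb.SimulationConfig(n_subjects=2000)
    frame = tb.prepare_cohort(tb.generate_cohort(cfg, seed=13))
    pre = frame["gose_interview"].isna().mean()
    post = frame["gose_level"].isna().mean()
    assert 0.14 <= pre <= 0.21          # interview masked inside reported band
    assert post < pre                    # questionnaire/rater fill most gaps
    assert post < 0.06


def test_correlation_pattern_low_pcs_mcs_block(default_cohort):
    matrix, labels = tb.correlate_outcomes(default_cohort, 3)
    for pcs in ("sf36_pcs", "sf12_pcs"):
        for mcs in ("sf36_mcs", "sf12_mcs"):
            assert abs(matrix.loc[pcs, mcs]) < 0.30
    others = labels[~(labels.instrument_a.str.contains("pcs")
                      & labels.instrument_b.str.contains("mcs"))]
    assert (others["rho"].abs() >= 0.30).mean() > 0.9   # moderate-to-high elsewhere


def test_gose_impairment_prevalence_in_reported_band(default_cohort):
    tp3 = default_cohort[default_cohort["timepoint_months"] == 3]
    flags = tp3["gose_impaired"].dropna()
    prevalence = flags.astype(bool).mean()
    assert 0.41 <= prevalence <= 0.46


def test_impairment_prevalence_monotone_in_health_shift():
    prevalences = []
    for trend in (0.0, 0.4, 0.8):
        cfg = tb.SimulationConfig(n_subjects=1500, timepoints=(3,),
                                  with_missingness=False,
                                  time_trend={3: trend})
        frame = tb.prepare_cohort(tb.generate_cohort(cfg, seed=21))
        prevalences.append(frame["rpq_impaired"].dropna().astype(bool).mean())
    assert prevalences[0] > prevalences[1] > prevalences[2]


def test_default_missingness_covers_every_instrument():
    rates = _default_missingness()
    for dom in SCORE_DOMAINS[1:]:
        assert dom in rates
    assert all(0.14 <= r <= 0.21 for r in rates["gose_interview"].values())
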