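"""Synthetic-cohort generator: covariates, latent trajectories, events."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy.stats import kendalltau

from immunejm.simulate import (
    CohortSimulator,
    TrueParams,
    default_true_params,
    latent_slope,
    latent_value,
    sample_event_time,
    sample_event_times,
    simulate_measurements,
    two_cause_recovery_params,
    two_cause_recovery_simulator,
)
from immunejm.splines import SplineBasisDef

REF_ROW = {"disease_risk": "non_high", "donor_type": "RD", "cmv_pair": "neg_neg"}


def _flat_params(intercept=0.0, alpha=(0.0,), log_h0=(-1.0,), sigma=0.5,
                 cuts=()):
    """Covariate-free truth with a constant latent value."""
    basis = SplineBasisDef((), (0.0, 6.0))
    return TrueParams(
        basis=basis, beta=(intercept, 0.0), re_covariance=((1e-12,),),
        sigma_eps=sigma, baseline_cuts=cuts,
        baseline_log_hazard=tuple((v,) * (len(cuts) + 1) for v in log_h0),
        gamma=tuple({} for _ in alpha), alpha=tuple(alpha),
        interaction="none", cmv_main_effect=False)


# -- baseline covariates ----------------------------------------------------

def test_baseline_proportions_match_study_composition():
    sim = CohortSimulator(n_subjects=100_000, random_state=0)
    cov = sim.sample_baseline(np.random.default_rng(0))
    assert abs((cov["disease_risk"] == "high").mean() - 62 / 166) < 0.005
    assert abs((cov["cmv_pair"] == "neg_neg").mean() - 51 / 166) < 0.005
    assert abs((cov["donor_type"] == "UD_ATG").mean() - 109 / 166) < 0.005


def test_degenerate_proportions():
    sim = CohortSimulator(n_subjects=200, p_high_risk=0.0, random_state=0)
    cov = sim.sample_baseline(np.random.default_rng(1))
    assert (cov["disease_risk"] == "non_high").all()


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        CohortSimulator(p_high_risk=1.5).sample()
    with pytest.raises(ValueError):
        CohortSimulator(horizon=-1.0).sample()
    with pytest.raises(ValueError):
        CohortSimulator(visit_times=(2.0, 1.0)).sample()


# -- latent trajectories ----------------------------------------------------

def test_latent_value_reduces_to_intercept_terms(default_truth):
    tp = default_truth
    nb = tp.basis.n_basis
    beta = np.array(tp.beta)
    flat = beta.copy()
    flat[1:] = 0.0
    flat[1 + nb] = beta[1 + nb]  # keep the CMV main effect
    tp0 = replace(tp, beta=tuple(flat))
    t = np.array([0.0, 2.0, 5.0])
    b = np.zeros(2)
    v_ref = latent_value(tp0, REF_ROW, b, t)
    v_cmv = latent_value(tp0, dict(REF_ROW, cmv_pair="other"), b, t)
    np.testing.assert_allclose(v_ref, flat[0])
    np.testing.assert_allclose(v_cmv - v_ref, beta[1 + nb])
    np.testing.assert_allclose(latent_slope(tp0, REF_ROW, b, t), 0.0,
                               atol=1e-12)


def test_cmv_effect_is_constant_shift(default_truth):
    t = np.linspace(0, 6, 25)
    b = np.array([0.3, -0.1])
    v1 = latent_value(default_truth, REF_ROW, b, t)
    v2 = latent_value(default_truth, dict(REF_ROW, cmv_pair="other"), b, t)
    diff = v2 - v1
    np.testing.assert_allclose(diff, diff[0], atol=1e-12)
    assert diff[0] == pytest.approx(0.11)


def test_latent_slope_matches_finite_differences(default_truth):
    rng = np.random.default_rng(3)
    t = rng.uniform(0.1, 5.9, 30)
    b = rng.normal(size=2) * 0.5
    row = {"disease_risk": "high", "donor_type": "UD_ATG", "cmv_pair": "other"}
    h = 1e-5
    fd = (latent_value(default_truth, row, b, t + h)
          - latent_value(default_truth, row, b, t - h)) / (2 * h)
    np.testing.assert_allclose(latent_slope(default_truth, row, b, t), fd,
                               atol=1e-4)


# -- measurements -----------------------------------------------------------

def test_measurements_noise_free_limit(default_truth):
    tp = replace(default_truth, sigma_eps=1e-12)
    rng = np.random.default_rng(0)
    t = np.array([0.5, 2.0, 5.0])
    b = np.array([0.2, 0.05])
    got = simulate_measurements(tp, REF_ROW, b, t, rng)
    want = np.maximum(np.exp(latent_value(tp, REF_ROW, b, t)), 0.5)
    np.testing.assert_allclose(got, want, rtol=1e-9)


def test_measurements_floored_at_detection_limit():
    tp = _flat_params(intercept=np.log(0.01))
    rng = np.random.default_rng(5)
    got = simulate_measurements(tp, REF_ROW, np.zeros(1),
                                np.linspace(0.1, 5, 20), rng)
    assert (got == 0.5).all()


def test_measurement_mean_is_latent_value():
    tp = _flat_params(intercept=3.0, sigma=0.4)
    rng = np.random.default_rng(7)
    n = 100_000
    got = simulate_measurements(tp, REF_ROW, np.zeros(1), np.full(n, 2.0), rng)
    assert abs(np.log(got).mean() - 3.0) < 3 * 0.4 / np.sqrt(n)


# -- events -----------------------------------------------------------------

def test_constant_hazard_gives_exponential_times():
    lam = 0.8
    tp = _flat_params(log_h0=(np.log(lam),))
    rng = np.random.default_rng(11)
    u = rng.random(100_000)
    t = sample_event_times(tp, REF_ROW, np.zeros(1), u, horizon=60.0)
    observed = t[t < 60.0 - 1e-9]
    # P(T > 60) = e^-48 ~ 0, so the mean over events is the full mean
    assert abs(observed.mean() - 1 / lam) < 0.01 / lam


def test_competing_constant_hazards_cause_proportions():
    lam1, lam2 = 0.5, 0.25
    tp = _flat_params(alpha=(0.0, 0.0), log_h0=(np.log(lam1), np.log(lam2)))
    sim = CohortSimulator(n_subjects=20_000, true_params=tp, horizon=6.0,
                          visit_times=(1.0,), random_state=2)
    tab = sim.sample()
    ev = tab.events[tab.events["cause"] > 0]
    p1 = (ev["cause"] == 1).mean()
    assert abs(p1 - lam1 / (lam1 + lam2)) < 0.01


def test_scalar_brent_and_vectorized_sampler_agree(recovery_truth):
    rng = np.random.default_rng(13)
    b = np.array([0.4])
    u = rng.random(50)
    t_vec = sample_event_times(recovery_truth, REF_ROW, b, u, horizon=6.0)
    for ui, tv in zip(u, t_vec):
        ts, _ = sample_event_time(recovery_truth, REF_ROW, b, float(ui), 6.0)
        assert abs(ts - tv) < 1e-6


def test_independence_of_events_and_trajectory_when_alpha_zero(recovery_truth):
    tp = replace(recovery_truth, alpha=(0.0, 0.0))
    sim = two_cause_recovery_simulator(n_subjects=4000, random_state=29,
                                      true_params=tp)
    _, truth = sim.sample(return_truth=True)
    r = np.corrcoef(truth["b0"], truth["event_time"])[0, 1]
    assert abs(r) < 0.05


def test_positive_alpha_orders_event_times_by_intercept(recovery_truth):
    # cause-1 hazard increases with the latent value: higher random
    # intercepts -> stochastically earlier events
    sim = two_cause_recovery_simulator(n_subjects=3000, random_state=31)
    _, truth = sim.sample(return_truth=True)
    tau, p = kendalltau(truth["b0"], truth["event_time"])
    assert tau < 0 and p < 1e-6


# -- cohort-level checks ----------------------------------------------------

def test_default_cohort_measurement_counts():
    tab = CohortSimulator(n_subjects=166, random_state=37).sample()
    counts = (tab.longitudinal.groupby("subject_id").size()
              .reindex(tab.events["subject_id"], fill_value=0))
    assert 5 <= counts.median() <= 8


def test_measurements_never_after_event():
    tab = CohortSimulator(n_subjects=120, random_state=41).sample()
    etime = tab.events.set_index("subject_id")["time_months"]
    assert (tab.longitudinal["time_months"]
            <= tab.longitudinal["subject_id"].map(etime) + 1e-9).all()
    assert (tab.longitudinal["count_e6_per_L"] >= 0.5).all()


def test_bitwise_reproducibility():
    a = CohortSimulator(n_subjects=50, random_state=43).sample()
    b = CohortSimulator(n_subjects=50, random_state=43).sample()
    c = CohortSimulator(n_subjects=50, random_state=44).sample()
    pd.testing.assert_frame_equal(a.longitudinal, b.longitudinal)
    pd.testing.assert_frame_equal(a.events, b.events)
    pd.testing.assert_frame_equal(a.covariates, b.covariates)
    assert not a.events.equals(c.events)
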