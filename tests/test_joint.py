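"""Shared-parameter joint model: likelihood, fitting, reporting."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from immunejm import (
    CohortSimulator,
    JointModel,
    LinearMixedModel,
    two_cause_recovery_simulator,
    wald_hr,
)
from immunejm.cohort import CohortTables
from immunejm.joint import CauseSpec, JointSpec
from immunejm.joint import test_slope_association as slope_association_test
from immunejm.lmm import LongitudinalSpec
from immunejm.splines import ncs_basis


def _pack_truth(jm, tp, alpha=None):
    gam = [np.array([g.get("donor_UD_ATG", 0.0), g.get("risk_high", 0.0)]
                    [:len(cs.covariates)])
           for g, cs in zip(tp.gamma, jm.spec_.causes)]
    return jm.layout_.pack(
        np.array(tp.beta), tp.sigma_eps, np.array(tp.re_covariance),
        [np.array(r) for r in tp.baseline_log_hazard], gam,
        list(tp.alpha) if alpha is None else list(alpha))


class TestLikelihood:
    def test_quadrature_order_insensitive_on_default_cohort(
            self, default_cohort, default_truth, recovery_spec):
        spec = replace(recovery_spec,
                       longitudinal=default_truth.longitudinal_spec(),
                       causes=(CauseSpec("GvHD", 1, ("donor_UD_ATG", "risk_high")),
                               CauseSpec("relapse", 2, ("donor_UD_ATG", "risk_high")),
                               CauseSpec("other_failure", 3, ("donor_UD_ATG",))),
                       baseline_cuts=(1.5, 3.0))
        jm = JointModel(spec=spec, compute_se=False).prepare(default_cohort)
        theta = _pack_truth(jm, default_truth)
        ll9 = jm.loglik(theta, gh_order=9)
        ll15 = jm.loglik(theta, gh_order=15)
        assert abs(ll9 - ll15) < 1e-4

    def test_invalid_quadrature_order(self, recovery_fit):
        with pytest.raises(ValueError):
            recovery_fit.subject_logliks(gh_order=0)

    def test_censored_subject_without_measurements_is_marginal_survival(
            self, recovery_truth):
        # a subject contributing no measurements enters only through the
        # marginal survival probability; cross-check by Monte Carlo
        tp = recovery_truth
        long = pd.DataFrame({"subject_id": [1, 1], "time_months": [0.5, 2.0],
                             "marker": ["CD4"] * 2,
                             "count_e6_per_L": [1.0, 30.0]})
        events = pd.DataFrame({"subject_id": [1, 2],
                               "time_months": [6.0, 4.0], "cause": [0, 0]})
        cov = pd.DataFrame({"subject_id": [1, 2],
                            "disease_risk": ["non_high"] * 2,
                            "donor_type": ["RD"] * 2,
                            "cmv_pair": ["neg_neg"] * 2})
        tables = CohortTables(long, events, cov)
        spec = JointSpec(tp.longitudinal_spec(),
                         (CauseSpec("c1", 1, ()), CauseSpec("c2", 2, ())),
                         baseline_cuts=tp.baseline_cuts, horizon=6.0)
        jm = JointModel(spec=spec).prepare(tables)
        theta = _pack_truth(jm, tp)
        ll = jm.subject_logliks(theta)[1]

        # Monte-Carlo oracle: S = E_b exp(-sum_k Lambda_k(4; b)); with a
        # random intercept, Lambda_k(t; b) = exp(alpha_k b) Lambda_k(t; 0)
        rng = np.random.default_rng(99)
        tgrid = np.linspace(0, 4.0, 4001)
        a_t = tp.beta[0] + ncs_basis(tgrid, tp.basis) @ np.array(tp.beta[1:])
        cuts = np.array(tp.baseline_cuts)
        lev = np.searchsorted(cuts, tgrid)
        lam0 = [np.trapezoid(np.exp(np.array(tp.baseline_log_hazard[k])[lev]
                                    + tp.alpha[k] * a_t), tgrid)
                for k in range(2)]
        b = rng.normal(0, np.sqrt(tp.re_covariance[0][0]), 200_000)
        S = np.exp(-(np.exp(tp.alpha[0] * b) * lam0[0]
                     + np.exp(tp.alpha[1] * b) * lam0[1]))
        mc, mc_se = S.mean(), S.std() / np.sqrt(S.size)
        assert abs(np.exp(ll) - mc) < 3 * mc_se + 1e-5


class TestFit:
    def test_association_recovered_within_3_se(self, recovery_fit,
                                               recovery_truth):
        se = np.sqrt(np.diag(recovery_fit.vcov_))
        names = recovery_fit.param_names_
        for k, truth in enumerate(recovery_truth.alpha):
            j = names.index(f"c{k + 1}:current_value")
            assert abs(recovery_fit.theta_[j] - truth) < 3 * se[j]

    def test_loglik_at_fit_dominates_truth(self, recovery_fit,
                                           recovery_truth):
        theta_t = _pack_truth(recovery_fit, recovery_truth)
        assert recovery_fit.loglik_ >= recovery_fit.loglik(theta_t) - 1e-6

    def test_sigma_and_re_variance_recovered(self, recovery_fit,
                                             recovery_truth):
        assert recovery_fit.params_["sigma"] == pytest.approx(
            recovery_truth.sigma_eps, rel=0.15)
        assert recovery_fit.params_["D"][0, 0] == pytest.approx(
            recovery_truth.re_covariance[0][0], rel=0.4)

    def test_null_association_recovery(self, recovery_truth):
        # with the association switched off the baselines must carry the
        # event rates themselves
        tp = replace(recovery_truth, alpha=(0.0, 0.0),
                     baseline_log_hazard=((-3.0, -2.4, -2.0),
                                          (-2.5, -1.9, -1.5)))
        tab = two_cause_recovery_simulator(
            n_subjects=200, random_state=51, true_params=tp).sample()
        spec = JointSpec(tp.longitudinal_spec(),
                         (CauseSpec("c1", 1, ()), CauseSpec("c2", 2, ())),
                         baseline_cuts=tp.baseline_cuts, horizon=6.0)
        jm = JointModel(spec=spec, gh_order=7, gl_order=9).fit(tab)
        se = np.sqrt(np.diag(jm.vcov_))
        for k in range(2):
            j = jm.param_names_.index(f"c{k + 1}:current_value")
            assert abs(jm.theta_[j]) < 3 * se[j]

    def test_dropout_correction_direction(self, recovery_fit,
                                          recovery_cohort, recovery_truth):
        # informative dropout removes high-trajectory subjects (cause 1
        # dominates, alpha > 0), biasing the naive mixed-model mean downward
        # at late times; the joint fit corrects upward
        tables, _ = recovery_cohort
        lmm = LinearMixedModel(
            spec=recovery_truth.longitudinal_spec()).fit(tables)
        t6 = [6.0]
        naive = lmm.predict_mean_trajectory({}, t6)["log_estimate"].iloc[0]
        joint = recovery_fit.predict_mean_trajectory(
            {}, t6)["log_estimate"].iloc[0]
        assert joint > naive

    def test_reference_level_swap_flips_sign_not_magnitude(self,
                                                           recovery_truth):
        tp = replace(recovery_truth, gamma=({"donor_UD_ATG": 0.8}, {}))
        tab = two_cause_recovery_simulator(
            n_subjects=200, random_state=53, true_params=tp).sample()
        spec = JointSpec(tp.longitudinal_spec(),
                         (CauseSpec("c1", 1, ("donor_UD_ATG",)),
                          CauseSpec("c2", 2, ())),
                         baseline_cuts=tp.baseline_cuts, horizon=6.0)
        jm1 = JointModel(spec=spec, gh_order=7, gl_order=9,
                         compute_se=False).fit(tab)
        swapped = tab.copy()
        swapped.covariates["donor_type"] = np.where(
            swapped.covariates["donor_type"] == "RD", "UD_ATG", "RD")
        jm2 = JointModel(spec=spec, gh_order=7, gl_order=9,
                         compute_se=False).fit(swapped)
        j = jm1.param_names_.index("c1:donor_UD_ATG")
        g1, g2 = jm1.theta_[j], jm2.theta_[j]
        assert np.sign(g1) == -np.sign(g2)
        assert abs(abs(g1) - abs(g2)) < 0.02
        # association coefficient unaffected by the recoding
        ja = jm1.param_names_.index("c1:current_value")
        assert abs(jm1.theta_[ja] - jm2.theta_[ja]) < 0.02


class TestReporting:
    @pytest.mark.parametrize("est, se, expected", [
        (0.0, 0.1, (1.00, 0.82, 1.22)),
        (0.892, 0.267, (2.44, 1.45, 4.12)),
        (-0.431, 0.180, (0.65, 0.46, 0.92)),
    ])
    def test_wald_hazard_ratio_presentation(self, est, se, expected):
        hr, lo, hi = wald_hr(est, se)
        assert round(hr, 2) == expected[0]
        assert round(lo, 2) == expected[1]
        assert round(hi, 2) == expected[2]

    def test_hazard_ratio_table_layout(self, recovery_fit):
        tab = recovery_fit.hazard_ratios()
        assert set(tab["cause"]) == {"c1", "c2"}
        assert (tab["term"] == "current_value").all()
        row = tab.set_index("cause").loc["c1"]
        np.testing.assert_allclose(row["HR"], np.exp(row["estimate"]))
        assert row["lo95"] < row["HR"] < row["hi95"]

    def test_trajectory_consistency_count_scale(self, recovery_fit):
        c = recovery_fit.predict_mean_trajectory({}, np.linspace(0, 6, 7))
        np.testing.assert_allclose(c["count"], np.exp(c["log_estimate"]))

    def test_subject_trajectory_tracks_measurements(self, recovery_fit,
                                                    recovery_cohort):
        tables, _ = recovery_cohort
        counts = tables.longitudinal.groupby("subject_id").size()
        sid = counts.idxmax()
        obs = tables.longitudinal[tables.longitudinal["subject_id"] == sid]
        curve = recovery_fit.subject_trajectory(
            sid, obs["time_months"].to_numpy())
        resid = np.log(np.maximum(obs["count_e6_per_L"], 0.5)) \
            - curve["log_estimate"].to_numpy()
        # subject curve should sit within a few residual SDs of the data
        assert np.abs(resid).mean() < 3 * recovery_fit.params_["sigma"]

    def test_slope_test_requires_nested_fits(self, recovery_fit):
        with pytest.raises(ValueError):
            slope_association_test(recovery_fit, recovery_fit)
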