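"""Linear mixed-effects submodel for log cell counts.

The mean structure is a natural cubic spline of time since the origin with
baseline covariates: the patient/donor CMV pair enters as a simple level
shift, while the intention-to-treat disease-risk group and the donor type
enter through a full three-way factorial interaction with the spline of time
(model I), so that each risk-by-donor cell has its own recovery shape.  The
post-infusion variant (model II) drops disease risk — every subject there is
high risk — and keeps a donor-by-time interaction.

Fitting is delegated to :class:`statsmodels` ``MixedLM`` (ML or REML) behind
the :class:`LinearMixedModel` estimator; the closed-form marginal likelihood
and empirical-Bayes posteriors needed elsewhere (joint-model initialization
and oracle checks) are implemented here directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import CohortTables, prepare_log_response, DETECTION_LIMIT
from .splines import SplineBasisDef, ncs_basis, ncs_deriv, default_knots

__all__ = [
    "LongitudinalSpec",
    "build_design",
    "design_column_names",
    "LinearMixedModel",
    "lmm_marginal_loglik",
    "eb_posterior",
]

#: factor -> (covariate column, indicator level, design name)
_RISK = ("disease_risk", "high", "risk_high")
_DONOR = ("donor_type", "UD_ATG", "donor_UD_ATG")
_CMV = ("cmv_pair", "other", "cmv_other")


@dataclass(frozen=True)
class LongitudinalSpec:
    """Mean and random-effects structure of the longitudinal submodel.

    ``interaction``: ``"risk_by_donor"`` is the transplant-origin model
    (three-way risk x donor x spline-of-time expansion), ``"donor_only"``
    the infusion-origin model (donor x spline of time, no disease risk),
    ``"none"`` a covariate-free trajectory.

    ``random_effects``: ``"intercept"``, ``"intercept_linear"`` (intercept
    plus the linear-time column), ``"intercept_spline"`` (intercept plus all
    spline columns), or ``"none"``.
    """

    basis: SplineBasisDef | None = None
    interaction: str = "risk_by_donor"
    cmv_main_effect: bool = True
    random_effects: str = "intercept_spline"
    marker: str = "CD4"

    def __post_init__(self):
        if self.interaction not in ("risk_by_donor", "donor_only", "none"):
            raise ValueError(f"unknown interaction {self.interaction!r}")
        if self.random_effects not in (
            "none", "intercept", "intercept_linear", "intercept_spline"
        ):
            raise ValueError(f"unknown random_effects {self.random_effects!r}")

    def resolve_basis(self, times) -> "LongitudinalSpec":
        """Fill in data-driven quantile knots when no basis was given."""
        if self.basis is not None:
            return self
        return replace(self, basis=default_knots(times))

    @property
    def n_random_effects(self) -> int:
        if self.basis is None:
            raise ValueError("basis not resolved")
        return {"none": 0, "intercept": 1, "intercept_linear": 2,
                "intercept_spline": 1 + self.basis.n_basis}[self.random_effects]


def _indicator(covariates: pd.DataFrame, factor) -> np.ndarray:
    col, level, _ = factor
    vals = covariates[col].to_numpy()
    return (vals == level).astype(float)


def design_column_names(spec: LongitudinalSpec) -> list[str]:
    nb = spec.basis.n_basis
    spline = ["time"] + [f"ncs{j}" for j in range(1, nb)]
    names = ["intercept", *spline]
    if spec.cmv_main_effect:
        names.append(_CMV[2])
    if spec.interaction == "risk_by_donor":
        r, d = _RISK[2], _DONOR[2]
        names += [r, d, f"{r}:{d}"]
        names += [f"{r}:{s}" for s in spline]
        names += [f"{d}:{s}" for s in spline]
        names += [f"{r}:{d}:{s}" for s in spline]
    elif spec.interaction == "donor_only":
        d = _DONOR[2]
        names += [d] + [f"{d}:{s}" for s in spline]
    return names


def build_design(
    covariates: pd.DataFrame,
    times,
    spec: LongitudinalSpec,
    deriv: bool = False,
):
    """Fixed- and random-effects design matrices at given times.

    ``covariates`` must have one row per element of ``times`` (repeat the
    subject row for repeated measures) with reference levels
    non_high / RD / neg_neg.  With ``deriv=True`` both matrices are the exact
    time-derivatives of the ``deriv=False`` ones (time-constant columns
    become zero), which is what the current-slope association needs.

    Returns ``(X, Z)``; column order follows :func:`design_column_names` and
    is stable.
    """
    if spec.basis is None:
        raise ValueError("spec.basis must be resolved before building designs")
    t = np.asarray(times, dtype=float)
    if len(covariates) != t.size:
        raise ValueError("covariates rows must align with times")
    for col, levels in (("disease_risk", ("non_high", "high")),
                        ("donor_type", ("RD", "UD_ATG")),
                        ("cmv_pair", ("neg_neg", "other"))):
        if col in covariates.columns:
            bad = set(covariates[col].unique()) - set(levels)
            if bad:
                raise ValueError(f"unknown {col} levels {sorted(bad)}")

    S = ncs_deriv(t, spec.basis) if deriv else ncs_basis(t, spec.basis)
    one = np.zeros(t.size) if deriv else np.ones(t.size)
    cols = [one[:, None], S]
    zero = np.zeros(t.size)

    def main(ind):
        return (zero if deriv else ind)[:, None]

    if spec.cmv_main_effect:
        cols.append(main(_indicator(covariates, _CMV)))
    if spec.interaction == "risk_by_donor":
        r = _indicator(covariates, _RISK)
        d = _indicator(covariates, _DONOR)
        cols += [main(r), main(d), main(r * d)]
        cols += [S * r[:, None], S * d[:, None], S * (r * d)[:, None]]
    elif spec.interaction == "donor_only":
        d = _indicator(covariates, _DONOR)
        cols += [main(d), S * d[:, None]]
    X = np.hstack(cols)

    if spec.random_effects == "none":
        Z = np.empty((t.size, 0))
    elif spec.random_effects == "intercept":
        Z = one[:, None].copy()
    elif spec.random_effects == "intercept_linear":
        Z = np.hstack([one[:, None], S[:, :1]])
    else:
        Z = np.hstack([one[:, None], S])
    return X, Z


# ---------------------------------------------------------------------------
# closed-form marginal likelihood and empirical Bayes


def _subject_slices(subj: np.ndarray):
    """Start/stop index pairs of each subject's contiguous block."""
    change = np.flatnonzero(np.diff(subj)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [subj.size]])
    return starts, stops


def lmm_marginal_loglik(y, X, Z, subj, beta, D, sigma) -> float:
    """Exact marginal Gaussian log-likelihood of an LMM.

    ``subj`` must be sorted; ``D`` may be singular (including the zero
    matrix, which reduces to independent-Normal errors).
    """
    y = np.asarray(y, float)
    r = y - X @ beta
    subj = np.asarray(subj)
    starts, stops = _subject_slices(subj)
    d = Z.shape[1]
    total = 0.0
    for a, b in zip(starts, stops):
        ri = r[a:b]
        Zi = Z[a:b]
        Vi = sigma ** 2 * np.eye(b - a)
        if d:
            Vi = Vi + Zi @ D @ Zi.T
        sign, logdet = np.linalg.slogdet(Vi)
        total += -0.5 * ((b - a) * np.log(2 * np.pi) + logdet
                         + ri @ np.linalg.solve(Vi, ri))
    return float(total)


def eb_posterior(y, X, Z, subj, beta, D, sigma):
    """Per-subject Gaussian posterior of the random effects.

    Returns ``(means, covs)`` with shapes ``(n, d)`` and ``(n, d, d)``:
    ``cov = (Z'Z / sigma^2 + D^-1)^-1`` and ``mean = cov Z'(y - X beta) /
    sigma^2`` (posterior mode = posterior mean for the Gaussian model).
    """
    r = np.asarray(y, float) - X @ beta
    subj = np.asarray(subj)
    starts, stops = _subject_slices(subj)
    d = Z.shape[1]
    Dinv = np.linalg.inv(D)
    means = np.zeros((starts.size, d))
    covs = np.zeros((starts.size, d, d))
    for i, (a, b) in enumerate(zip(starts, stops)):
        Zi = Z[a:b]
        P = Zi.T @ Zi / sigma ** 2 + Dinv
        covs[i] = np.linalg.inv(P)
        means[i] = covs[i] @ (Zi.T @ r[a:b]) / sigma ** 2
    return means, covs


class LinearMixedModel(BaseEstimator):
    """Spline mixed-effects model of log cell counts over time.

    Parameters
    ----------
    spec : LongitudinalSpec
        Mean/random-effects structure; a basis of None is resolved to
        quantile knots of the observed measurement times at fit time.
    method : {"ML", "REML"}
        Estimation criterion.  ML is required when the fit seeds the joint
        model; REML is available for standalone use.

    Fitted attributes: ``beta_``, ``D_``, ``sigma_``, ``loglik_``,
    ``vcov_beta_``, ``converged_``, ``design_names_``, ``spec_``.
    """

    def __init__(self, spec: LongitudinalSpec | None = None, method: str = "ML"):
        self.spec = spec
        self.method = method

    # -- data preparation ---------------------------------------------------

    def _prepare(self, tables: CohortTables):
        spec = self.spec if self.spec is not None else LongitudinalSpec()
        long = tables.longitudinal
        if "marker" in long.columns and long["marker"].nunique() > 1:
            long = long[long["marker"] == spec.marker]
        if long.empty:
            raise ValueError(f"no measurements for marker {spec.marker!r}")
        long = long.sort_values(["subject_id", "time_months"], kind="stable")
        merged = long.merge(tables.covariates, on="subject_id", how="left",
                            validate="many_to_one")
        if merged[["disease_risk", "donor_type", "cmv_pair"]].isna().any().any():
            raise ValueError("measurements for subjects without covariate rows")
        t = merged["time_months"].to_numpy(float)
        spec = spec.resolve_basis(t)
        X, Z = build_design(merged, t, spec)
        y = prepare_log_response(merged["count_e6_per_L"].to_numpy(float))
        subj = merged["subject_id"].to_numpy()
        return spec, merged, y, X, Z, subj, t

    def fit(self, tables: CohortTables, y=None):
        if self.method not in ("ML", "REML"):
            raise ValueError("method must be 'ML' or 'REML'")
        spec, merged, yv, X, Z, subj, t = self._prepare(tables)
        self.spec_ = spec
        self.design_names_ = design_column_names(spec)
        self.y_, self.X_, self.Z_, self.subj_, self.t_ = yv, X, Z, subj, t

        import statsmodels.api as sm

        if spec.random_effects == "none":
            ols = sm.OLS(yv, X).fit()
            self.beta_ = ols.params
            self.D_ = np.empty((0, 0))
            sigma2 = float(ols.ssr / len(yv))  # ML variance estimate
            self.sigma_ = float(np.sqrt(sigma2))
            self.loglik_ = float(
                -0.5 * len(yv) * (np.log(2 * np.pi * sigma2) + 1.0)
            )
            self.vcov_beta_ = np.asarray(ols.cov_params()) * sigma2 / ols.scale
            self.converged_ = True
            return self

        model = sm.MixedLM(yv, X, groups=subj, exog_re=Z)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=(self.method == "REML"), method=["lbfgs"],
                            maxiter=500)
        self.beta_ = np.asarray(res.fe_params)
        self.D_ = np.asarray(res.cov_re)
        self.sigma_ = float(np.sqrt(res.scale))
        self.loglik_ = float(res.llf)
        p = X.shape[1]
        self.vcov_beta_ = np.asarray(res.cov_params())[:p, :p]
        self.converged_ = bool(res.converged)
        if not self.converged_:
            warnings.warn("MixedLM did not converge", RuntimeWarning)
        return self

    # -- predictions --------------------------------------------------------

    def _profile_frame(self, profile: dict, n: int) -> pd.DataFrame:
        base = {"disease_risk": "non_high", "donor_type": "RD",
                "cmv_pair": "neg_neg"}
        base.update(profile)
        return pd.DataFrame([base] * n)

    def predict_mean_trajectory(self, profile: dict, time_grid) -> pd.DataFrame:
        """Population-average trajectory for a covariate profile.

        Returns a frame with the log-scale estimate and delta-method 95%
        pointwise CI, and the same exponentiated to the count scale (1e6
        cells/L).  Times beyond the boundary knots are allowed (the basis is
        linear there) but flagged in the ``extrapolated`` column.
        """
        t = np.asarray(time_grid, float)
        cov = self._profile_frame(profile, t.size)
        X, _ = build_design(cov, t, self.spec_)
        est = X @ self.beta_
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.vcov_beta_, X), 0))
        lo, hi = est - 1.96 * se, est + 1.96 * se
        lo_b, hi_b = self.spec_.basis.boundary_knots
        return pd.DataFrame({
            "time_months": t, "log_estimate": est, "log_se": se,
            "log_lo95": lo, "log_hi95": hi,
            "count": np.exp(est), "count_lo95": np.exp(lo),
            "count_hi95": np.exp(hi),
            "extrapolated": (t < lo_b) | (t > hi_b),
        })

    def empirical_bayes(self) -> pd.DataFrame:
        """Posterior modes of the random effects for every fitted subject."""
        means, _ = eb_posterior(self.y_, self.X_, self.Z_, self.subj_,
                                self.beta_, self.D_, self.sigma_)
        starts, _ = _subject_slices(self.subj_)
        ids = self.subj_[starts]
        cols = [f"b{j}" for j in range(means.shape[1])]
        return pd.DataFrame(means, columns=cols).assign(subject_id=ids)

    def subject_trajectory(self, subject_id, time_grid,
                           covariates: pd.DataFrame | None = None) -> pd.DataFrame:
        """Subject-specific curve: fixed part plus empirical-Bayes random part.

        A subject absent from the fitted data (no measurements) gets random
        effects at the prior mode, i.e. the population-average curve for its
        profile.
        """
        t = np.asarray(time_grid, float)
        eb = self.empirical_bayes().set_index("subject_id")
        d = self.Z_.shape[1]
        b = (eb.loc[subject_id].to_numpy(float)
             if subject_id in eb.index else np.zeros(d))
        if covariates is None:
            mask = self.subj_ == subject_id
            if not mask.any():
                raise ValueError(
                    f"no covariates available for subject {subject_id!r}")
            idx = int(np.flatnonzero(mask)[0])
            # rebuild the subject's covariate row from the stored design
            prof = self._covariate_row_from_design(idx)
        else:
            prof = covariates.iloc[0].to_dict()
        cov = self._profile_frame(prof, t.size)
        X, Z = build_design(cov, t, self.spec_)
        est = X @ self.beta_ + (Z @ b if d else 0.0)
        return pd.DataFrame({"time_months": t, "log_estimate": est,
                             "count": np.exp(est)})

    def _covariate_row_from_design(self, idx: int) -> dict:
        names = self.design_names_
        row = self.X_[idx]
        prof = {}
        if "cmv_other" in names:
            prof["cmv_pair"] = "other" if row[names.index("cmv_other")] else "neg_neg"
        if "risk_high" in names:
            prof["disease_risk"] = "high" if row[names.index("risk_high")] else "non_high"
        if "donor_UD_ATG" in names:
            prof["donor_type"] = "UD_ATG" if row[names.index("donor_UD_ATG")] else "RD"
        return prof

    def to_dict(self) -> dict:
        return {
            "design_names": list(self.design_names_),
            "beta": [float(v) for v in self.beta_],
            "se_beta": [float(v) for v in np.sqrt(np.diag(self.vcov_beta_))],
            "D": [[float(v) for v in row] for row in np.atleast_2d(self.D_)],
            "sigma": float(self.sigma_),
            "loglik": float(self.loglik_),
            "converged": bool(self.converged_),
            "method": self.method,
            "basis": {
                "interior_knots": list(self.spec_.basis.interior_knots),
                "boundary_knots": list(self.spec_.basis.boundary_knots),
            },
        }
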