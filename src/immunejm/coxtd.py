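"""Cause-specific Cox models with time-dependent marker covariates.

The exploratory analysis carries last-observation-carried-forward (LOCF) log
cell counts — possibly several markers at once, e.g. CD4 and NK — into
cause-specific proportional-hazards models on a start–stop counting-process
representation.  Competing causes are treated as censoring.  Estimation is
delegated to :mod:`lifelines`' ``CoxTimeVaryingFitter`` (Breslow-equivalent
on tie-free data) behind the :class:`CauseSpecificCox` surface.

Subjects enter the risk set at their first marker measurement (delayed
entry) when no measurement precedes time zero, which also accommodates the
infusion-origin timescale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import CohortTables, prepare_log_response

__all__ = ["lvcf_expand", "CauseSpecificCox", "fit_cause_specific_cox"]


def lvcf_expand(
    longitudinal: pd.DataFrame,
    events: pd.DataFrame,
    markers: list[str],
    detection_limit: float = 0.5,
) -> pd.DataFrame:
    """Expand to a start-stop counting process with LOCF log-count covariates.

    Intervals are split at each subject's measurement times; the covariate
    ``log_<marker>`` on an interval is the log count of the last measurement
    at or before the interval start.  A subject enters the risk set at the
    first time all requested markers have been measured (delayed entry);
    measurements after the event time are ignored.  ``status`` carries the
    cause code on the subject's last interval and 0 elsewhere.
    """
    rows = []
    ev = events.set_index("subject_id")
    for sid, g in longitudinal[longitudinal["marker"].isin(markers)].groupby(
            "subject_id"):
        if sid not in ev.index:
            continue
        t_event = float(ev.loc[sid, "time_months"])
        cause = int(ev.loc[sid, "cause"])
        g = g[g["time_months"] <= t_event + 1e-9]
        if g.empty:
            continue
        per_marker = {}
        for mk in markers:
            gm = g[g["marker"] == mk].sort_values("time_months")
            if gm.empty:
                per_marker = None
                break
            per_marker[mk] = (
                gm["time_months"].to_numpy(float),
                prepare_log_response(gm["count_e6_per_L"].to_numpy(float),
                                     detection_limit),
            )
        if per_marker is None:
            continue
        entry = max(tm[0] for tm, _ in per_marker.values())
        breaks = np.unique(np.concatenate(
            [tm for tm, _ in per_marker.values()]))
        breaks = breaks[(breaks >= entry) & (breaks < t_event - 1e-9)]
        bounds = np.concatenate([breaks, [t_event]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b <= a + 1e-12:
                continue
            row = {"subject_id": sid, "start": float(a), "stop": float(b),
                   "status": 0}
            for mk, (tm, lv) in per_marker.items():
                row[f"log_{mk}"] = float(lv[np.searchsorted(tm, a + 1e-9) - 1])
            rows.append(row)
        if rows and rows[-1]["subject_id"] == sid:
            rows[-1]["status"] = cause
    return pd.DataFrame(rows)


def collapse_counting_process(cp: pd.DataFrame) -> pd.DataFrame:
    """Recover the per-subject event table from a counting process."""
    last = cp.sort_values(["subject_id", "stop"]).groupby("subject_id").tail(1)
    return last[["subject_id", "stop", "status"]].rename(
        columns={"stop": "time_months", "status": "cause"}
    ).reset_index(drop=True)


class CauseSpecificCox(BaseEstimator):
    """Cause-specific Cox model on a start-stop counting process.

    Competing causes are censored; ties are handled Breslow-style (event
    times from the simulator are almost surely distinct).  Fitted
    attributes: ``coef_`` (Series of log hazard ratios), ``se_``, ``vcov_``,
    ``loglik_``, ``converged_``.
    """

    def __init__(self, cause: int = 1, covariates: list[str] | None = None,
                 penalizer: float = 0.0):
        self.cause = cause
        self.covariates = covariates
        self.penalizer = penalizer

    def fit(self, counting_process: pd.DataFrame, y=None):
        cp = counting_process.copy()
        cols = self.covariates
        if cols is None:
            cols = [c for c in cp.columns
                    if c not in ("subject_id", "start", "stop", "status")]
        if not cols:
            raise ValueError("no covariate columns")
        if (cp["status"] == self.cause).sum() == 0:
            raise ValueError(f"no events of cause {self.cause}")
        for c in cols:
            if np.ptp(cp[c].to_numpy(float)) == 0.0:
                raise ValueError(
                    f"covariate {c!r} is constant; coefficient unidentifiable")
        cp["event"] = (cp["status"] == self.cause).astype(int)

        from lifelines import CoxTimeVaryingFitter
        from lifelines.exceptions import ConvergenceError

        ctv = CoxTimeVaryingFitter(penalizer=self.penalizer)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                ctv.fit(cp[["subject_id", "start", "stop", "event"] + cols],
                        id_col="subject_id", start_col="start",
                        stop_col="stop", event_col="event")
            except ConvergenceError as err:
                raise RuntimeError(
                    "Cox partial likelihood did not converge (possible "
                    "monotone likelihood / separation)") from err
        self.covariates_ = cols
        self.coef_ = ctv.params_.copy()
        self.se_ = ctv.standard_errors_.copy()
        self.vcov_ = ctv.variance_matrix_.to_numpy()
        self.loglik_ = float(ctv.log_likelihood_)
        self.converged_ = True
        self.model_ = ctv
        return self

    def summary(self) -> pd.DataFrame:
        hr = np.exp(self.coef_)
        lo = np.exp(self.coef_ - 1.96 * self.se_)
        hi = np.exp(self.coef_ + 1.96 * self.se_)
        return pd.DataFrame({"coef": self.coef_, "se": self.se_, "HR": hr,
                             "lo95": lo, "hi95": hi})


def fit_cause_specific_cox(counting_process, cause, covariates=None,
                           **kw) -> CauseSpecificCox:
    return CauseSpecificCox(cause=cause, covariates=covariates, **kw).fit(
        counting_process)
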