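"""Nonparametric survival and cumulative-incidence estimators.

Kaplan–Meier for single-endpoint survival (overall and relapse-free survival
style analyses) and the Aalen–Johansen estimator of cause-specific cumulative
incidence under competing risks (GvHD, relapse, other failure).  Both are
implemented as exact step functions so that the algebraic identities hold at
machine precision: with a single cause the Aalen–Johansen incidence equals
one minus Kaplan–Meier, and at every time the cause-specific incidences plus
the all-cause survival sum to one.

Tie convention: events precede censorings at the same time — subjects
censored at t are still in the risk set for events at t.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "KaplanMeierEstimator",
    "AalenJohansenEstimator",
    "kaplan_meier",
    "aalen_johansen",
]


def _check_surv(durations, flags) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(durations, float)
    e = np.asarray(flags)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.ndim != 1 or e.shape != t.shape:
        raise ValueError("durations and event flags must be 1-D and aligned")
    if np.any(t < 0) or np.any(~np.isfinite(t)):
        raise ValueError("durations must be finite and nonnegative")
    return t, e


class KaplanMeierEstimator(BaseEstimator):
    """Product-limit estimator with Greenwood variance.

    ``ci_method`` is ``"log-log"`` (default; bounds stay inside (0,1)) or
    ``"log"``.  Fitted attributes: ``event_times_`` (distinct event times),
    ``survival_`` (value just after each event time), ``ci_lower_`` /
    ``ci_upper_`` (pointwise 95%), ``n_at_risk_``, ``n_events_``.
    """

    def __init__(self, ci_method: str = "log-log", alpha: float = 0.05):
        self.ci_method = ci_method
        self.alpha = alpha

    def fit(self, durations, event_observed):
        t, e = _check_surv(durations, event_observed)
        if not np.isin(e, (0, 1)).all():
            raise ValueError("event_observed must be 0/1")
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order].astype(int)
        times = np.unique(t[e == 1])
        n = t.size
        surv, var_sum = 1.0, 0.0
        S, lo, hi, atrisk, nev = [], [], [], [], []
        from scipy.stats import norm
        z = norm.ppf(1 - self.alpha / 2)
        for tj in times:
            nj = int(np.sum(t >= tj))
            dj = int(np.sum((t == tj) & (e == 1)))
            surv *= 1.0 - dj / nj
            if nj > dj:
                var_sum += dj / (nj * (nj - dj))
            se_f = surv * np.sqrt(var_sum)  # Greenwood SE of S
            if surv in (0.0, 1.0):
                l = h = surv
            elif self.ci_method == "log":
                l = surv * np.exp(-z * np.sqrt(var_sum))
                h = min(1.0, surv * np.exp(z * np.sqrt(var_sum)))
            else:  # log-log
                se_ll = np.sqrt(var_sum) / abs(np.log(surv))
                l = surv ** np.exp(z * se_ll)
                h = surv ** np.exp(-z * se_ll)
            S.append(surv); lo.append(l); hi.append(h)
            atrisk.append(nj); nev.append(dj)
        self.event_times_ = times
        self.survival_ = np.asarray(S)
        self.ci_lower_ = np.asarray(lo)
        self.ci_upper_ = np.asarray(hi)
        self.n_at_risk_ = np.asarray(atrisk)
        self.n_events_ = np.asarray(nev)
        return self

    def survival_at(self, times) -> np.ndarray:
        """Right-continuous step evaluation of S(t)."""
        idx = np.searchsorted(self.event_times_, np.asarray(times, float),
                              side="right")
        padded = np.concatenate([[1.0], self.survival_])
        return padded[idx]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_months": self.event_times_,
            "survival": self.survival_,
            "lo95": self.ci_lower_,
            "hi95": self.ci_upper_,
            "n_at_risk": self.n_at_risk_,
            "n_events": self.n_events_,
        })


class AalenJohansenEstimator(BaseEstimator):
    """Cause-specific cumulative incidence under competing risks.

    ``CIF_k(t) = sum_{t_j <= t} S(t_j-) d_kj / n_j`` with ``S`` the all-cause
    Kaplan–Meier.  By construction ``sum_k CIF_k(t) + S(t) = 1`` exactly at
    every time.  Fitted attributes: ``event_times_``, ``cif_`` of shape
    ``(n_times, n_causes)``, ``overall_survival_``.
    """

    def __init__(self, n_causes: int = 3):
        self.n_causes = n_causes

    def fit(self, durations, causes):
        t, c = _check_surv(durations, causes)
        c = c.astype(int)
        if np.any(c < 0) or np.any(c > self.n_causes):
            raise ValueError(f"cause codes must be in 0..{self.n_causes}")
        times = np.unique(t[c > 0])
        cif = np.zeros((times.size, self.n_causes))
        S_minus, surv = 1.0, 1.0
        Ss = np.empty(times.size)
        acc = np.zeros(self.n_causes)
        for j, tj in enumerate(times):
            nj = int(np.sum(t >= tj))
            dkj = np.array([np.sum((t == tj) & (c == k + 1))
                            for k in range(self.n_causes)], float)
            dj = dkj.sum()
            acc = acc + S_minus * dkj / nj
            surv = S_minus * (1.0 - dj / nj)
            cif[j] = acc
            Ss[j] = surv
            S_minus = surv
        self.event_times_ = times
        self.cif_ = cif
        self.overall_survival_ = Ss
        return self

    def cif_at(self, times, cause: int) -> np.ndarray:
        """Right-continuous step evaluation of CIF for one cause (1-based)."""
        idx = np.searchsorted(self.event_times_, np.asarray(times, float),
                              side="right")
        padded = np.concatenate([[0.0], self.cif_[:, cause - 1]])
        return padded[idx]

    def survival_at(self, times) -> np.ndarray:
        idx = np.searchsorted(self.event_times_, np.asarray(times, float),
                              side="right")
        padded = np.concatenate([[1.0], self.overall_survival_])
        return padded[idx]

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_months": self.event_times_,
                           "overall_survival": self.overall_survival_})
        for k in range(self.n_causes):
            df[f"cif_cause{k + 1}"] = self.cif_[:, k]
        return df


def kaplan_meier(durations, event_observed, **kw) -> KaplanMeierEstimator:
    return KaplanMeierEstimator(**kw).fit(durations, event_observed)


def aalen_johansen(durations, causes, n_causes: int = 3) -> AalenJohansenEstimator:
    return AalenJohansenEstimator(n_causes=n_causes).fit(durations, causes)
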