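"""Cohort data containers, unit conventions and validation.

A cohort is the triple of tidy tables the whole analysis runs on:

* ``longitudinal`` — one row per measurement: ``subject_id``, ``time_months``,
  ``marker`` (CD3 / CD4 / CD8 / NK), ``count_e6_per_L`` (absolute circulating
  count in 1e6 cells/L);
* ``events`` — one row per subject: ``subject_id``, ``time_months`` (event or
  censoring time), ``cause`` (0 censored, 1 GvHD, 2 relapse, 3 other failure;
  in the post-infusion composite coding, 2 is relapse-or-other-failure);
* ``covariates`` — one row per subject: ``disease_risk`` (non_high / high,
  intention-to-treat relapse-risk group), ``donor_type`` (RD related donor /
  UD_ATG unrelated donor with ATG conditioning), ``cmv_pair`` (neg_neg when
  both patient and donor are CMV seronegative, else other).

Times are months since the model origin (transplant for model I, the early
low-dose infusion for model II).  Counts below the assay detection limit of
0.5e6 cells/L are floored to the limit before the log transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortTables",
    "CAUSE_CENSORED",
    "CAUSE_GVHD",
    "CAUSE_RELAPSE",
    "CAUSE_OTHER",
    "DETECTION_LIMIT",
    "DAYS_PER_MONTH",
    "RISK_LEVELS",
    "DONOR_LEVELS",
    "CMV_LEVELS",
    "prepare_log_response",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "apply_censoring_rules",
]

CAUSE_CENSORED = 0
CAUSE_GVHD = 1
CAUSE_RELAPSE = 2
CAUSE_OTHER = 3

#: assay lower detection limit, 1e6 cells/L
DETECTION_LIMIT = 0.5
#: canonical calendar conversion for day-based rules
DAYS_PER_MONTH = 30.44

# reference level first
RISK_LEVELS = ("non_high", "high")
DONOR_LEVELS = ("RD", "UD_ATG")
CMV_LEVELS = ("neg_neg", "other")

_LONG_COLS = ["subject_id", "time_months", "marker", "count_e6_per_L"]
_EVENT_COLS = ["subject_id", "time_months", "cause"]
_COV_COLS = ["subject_id", "disease_risk", "donor_type", "cmv_pair"]


@dataclass
class CohortTables:
    """The longitudinal / events / covariates table triple."""

    longitudinal: pd.DataFrame
    events: pd.DataFrame
    covariates: pd.DataFrame

    def subset_marker(self, marker: str) -> "CohortTables":
        keep = self.longitudinal[self.longitudinal["marker"] == marker]
        return CohortTables(keep.reset_index(drop=True), self.events, self.covariates)

    def copy(self) -> "CohortTables":
        return CohortTables(
            self.longitudinal.copy(), self.events.copy(), self.covariates.copy()
        )

    @property
    def n_subjects(self) -> int:
        return len(self.events)

    def markers(self) -> list[str]:
        return sorted(self.longitudinal["marker"].unique())


def prepare_log_response(counts, detection_limit: float = DETECTION_LIMIT) -> np.ndarray:
    """Natural log of counts after flooring at the detection limit.

    Sub-limit measurements carry no quantitative information beyond "below
    0.5e6/L" and are set to the limit before the log transform; negative
    counts are a data error, not a detection issue.
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0) or np.any(~np.isfinite(c)):
        raise ValueError("counts must be finite and nonnegative")
    return np.log(np.maximum(c, detection_limit))


def write_cohort(tables: CohortTables, directory) -> dict[str, Path]:
    """Write the three CSV tables into ``directory``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "longitudinal": directory / "longitudinal.csv",
        "events": directory / "events.csv",
        "covariates": directory / "covariates.csv",
    }
    tables.longitudinal.to_csv(paths["longitudinal"], index=False)
    tables.events.to_csv(paths["events"], index=False)
    tables.covariates.to_csv(paths["covariates"], index=False)
    return paths


def read_cohort(directory) -> CohortTables:
    directory = Path(directory)
    longitudinal = pd.read_csv(directory / "longitudinal.csv")
    events = pd.read_csv(directory / "events.csv")
    covariates = pd.read_csv(directory / "covariates.csv")
    for df, cols in (
        (longitudinal, _LONG_COLS),
        (events, _EVENT_COLS),
        (covariates, _COV_COLS),
    ):
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValueError(f"cohort table missing columns {sorted(missing)}")
    if len(longitudinal) == 0:
        longitudinal = longitudinal.astype(
            {"subject_id": "int64", "time_months": "float64", "count_e6_per_L": "float64"}
        )
    return CohortTables(longitudinal, events, covariates)


def validate_cohort(tables: CohortTables, n_causes: int = 3) -> dict:
    """Structural and semantic checks on a cohort.

    Returns a machine-readable report ``{"valid": bool, "errors": [...],
    "violations": [...]}``.  ``errors`` are structural problems (bad types,
    negative counts, unknown factor levels) on which downstream analysis must
    not run; ``violations`` are per-subject consistency breaches such as
    measurements recorded after the subject's terminating event.
    """
    errors: list[str] = []
    violations: list[dict] = []

    for df, cols, name in (
        (tables.longitudinal, _LONG_COLS, "longitudinal"),
        (tables.events, _EVENT_COLS, "events"),
        (tables.covariates, _COV_COLS, "covariates"),
    ):
        missing = set(cols) - set(df.columns)
        if missing:
            errors.append(f"{name}: missing columns {sorted(missing)}")
    if errors:
        return {"valid": False, "errors": errors, "violations": violations}

    long, ev, cov = tables.longitudinal, tables.events, tables.covariates

    if ev["subject_id"].duplicated().any():
        errors.append("events: duplicated subject_id")
    if cov["subject_id"].duplicated().any():
        errors.append("covariates: duplicated subject_id")
    if (np.asarray(long["count_e6_per_L"], dtype=float) < 0).any():
        bad = long.loc[long["count_e6_per_L"] < 0, "subject_id"].tolist()
        errors.append(f"longitudinal: negative counts for subjects {bad}")
    if (np.asarray(long["time_months"], dtype=float) < 0).any():
        errors.append("longitudinal: negative measurement times")
    if (np.asarray(ev["time_months"], dtype=float) <= 0).any():
        errors.append("events: nonpositive event/censoring times")
    if not ev["cause"].isin(range(n_causes + 1)).all():
        errors.append(f"events: cause codes outside 0..{n_causes}")
    for col, levels in (
        ("disease_risk", RISK_LEVELS),
        ("donor_type", DONOR_LEVELS),
        ("cmv_pair", CMV_LEVELS),
    ):
        bad = set(cov[col].unique()) - set(levels)
        if bad:
            errors.append(f"covariates: unknown {col} levels {sorted(bad)}")

    ev_ids = set(ev["subject_id"])
    orphan = sorted(set(long["subject_id"]) - ev_ids)
    if orphan:
        errors.append(f"longitudinal: subjects without event record {orphan}")
    if set(cov["subject_id"]) != ev_ids:
        errors.append("covariates and events subject sets differ")

    if not errors:
        etime = ev.set_index("subject_id")["time_months"]
        merged = long.merge(ev[["subject_id", "time_months"]], on="subject_id",
                            suffixes=("", "_event"))
        after = merged["time_months"] > merged["time_months_event"] + 1e-9
        for sid in sorted(merged.loc[after, "subject_id"].unique()):
            violations.append(
                {"subject_id": int(sid), "problem": "measurement after event time"}
            )

    return {"valid": not errors and not violations, "errors": errors,
            "violations": violations}


def apply_censoring_rules(
    tables: CohortTables,
    horizon: float,
    infusion_times: pd.Series | dict | None = None,
    censor_after_infusion_days: float = 7.0,
) -> CohortTables:
    """Apply the administrative censoring rules of the analysis window.

    Every subject is censored at ``horizon`` months; subjects with a
    protocol infusion (standard-dose or modified T-cell product) are
    additionally censored ``censor_after_infusion_days`` days after that
    infusion, this being prophylactic and hence non-informative.  Event
    records are truncated to the earliest applicable censoring time and
    measurements after it are dropped.  Deterministic; the input is not
    modified.
    """
    out = tables.copy()
    ev = out.events
    cut = np.full(len(ev), float(horizon))
    if infusion_times is not None:
        inf = pd.Series(infusion_times, dtype=float)
        mapped = ev["subject_id"].map(inf)
        extra = mapped.to_numpy(dtype=float) + censor_after_infusion_days / DAYS_PER_MONTH
        cut = np.fmin(cut, np.where(np.isnan(extra), np.inf, extra))
    truncate = ev["time_months"].to_numpy(dtype=float) > cut
    ev.loc[truncate, "time_months"] = cut[truncate]
    ev.loc[truncate, "cause"] = CAUSE_CENSORED
    etime = ev.set_index("subject_id")["time_months"]
    keep = out.longitudinal["time_months"] <= out.longitudinal["subject_id"].map(etime) + 1e-9
    out.longitudinal = out.longitudinal[keep].reset_index(drop=True)
    return out
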