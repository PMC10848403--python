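"""Derivation of recurrent liver-function upgrade events.

A graded longitudinal series is compared visit-by-visit: the first
post-treatment visit is compared against a pre-treatment reference grade
(the latest test within one week before completion of radiotherapy, with a
configurable one-month fallback), each later visit against the previous
one.  Any grade increase is an event; its delta classifies it as a 1-grade
or >1-grade event.  Events of different chemistries on the same calendar
day are *synchronous*; a combined (composite) event is recorded on every
patient-day with at least one member event.  Follow-up is counted in
person-months per scope, censored at the last visit carrying that scope's
test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .grading import DAYS_PER_MONTH, CompositeDefinition

__all__ = [
    "LFEvent",
    "reference_grade",
    "derive_individual_events",
    "classify_synchrony",
    "derive_combined_events",
    "derive_all_events",
    "person_months",
    "incidence_rates",
    "summarize_events",
]

ONE_GRADE = "one_grade"
GT_ONE_GRADE = "gt_one_grade"

EVENT_COLUMNS = [
    "patient_id",
    "time_months",
    "day",
    "scope",
    "prev_grade",
    "new_grade",
    "delta",
    "synchronous",
    "magnitude",
]


@dataclass(frozen=True)
class LFEvent:
    """One liver-function upgrade event."""

    patient_id: object
    time_months: float
    day: int
    scope: str
    prev_grade: int
    new_grade: int

    @property
    def delta(self) -> int:
        return self.new_grade - self.prev_grade

    @property
    def magnitude(self) -> str:
        return GT_ONE_GRADE if self.delta > 1 else ONE_GRADE


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(columns=EVENT_COLUMNS)


def reference_grade(
    pre_rt: pd.DataFrame,
    analyte: str,
    primary_window_days: float = 7.0,
    fallback_window_days: Optional[float] = DAYS_PER_MONTH,
):
    """Pre-treatment reference grade for one patient and analyte.

    The reference is the grade of the latest test with time in the open-low
    window ``(-primary_window_days, 0]`` (days before radiotherapy
    completion); a test exactly at the window edge is excluded.  If none
    exists the fallback window (default one month) is searched; if still
    none, ``None`` is returned and the first post-treatment visit will
    initialize the comparator without being event-eligible.
    """
    g = pre_rt[(pre_rt["analyte"] == analyte) & (pre_rt["time_months"] <= 0)]
    if g.empty:
        return None
    windows = [primary_window_days]
    if fallback_window_days is not None:
        windows.append(fallback_window_days)
    for w in windows:
        lo = -w / DAYS_PER_MONTH
        hit = g[g["time_months"] > lo]
        if not hit.empty:
            return int(hit.loc[hit["time_months"].idxmax(), "grade"])
    return None


def derive_individual_events(series: pd.DataFrame, reference) -> pd.DataFrame:
    """Upgrade events for one patient x analyte graded series.

    ``series`` holds post-treatment grade records (columns ``patient_id,
    time_months, day, analyte, grade``), sorted by time with one record per
    day.  An event fires at visit j when its grade exceeds the comparator
    (the reference for the first visit, the previous visit's grade after
    that); the comparator then always resets to the visit's grade.
    """
    if series.empty:
        return _empty_events()
    t = series["time_months"].to_numpy()
    if np.any(np.diff(t) < 0):
        raise ValueError("series must be sorted by time")
    if np.any(t <= 0):
        raise ValueError("post-treatment series must have strictly positive times")
    analyte = series["analyte"].iloc[0]
    patient = series["patient_id"].iloc[0]
    grades = series["grade"].to_numpy()
    days = series["day"].to_numpy()

    rows = []
    comparator = reference
    for j in range(len(series)):
        g = int(grades[j])
        if comparator is not None and g > comparator:
            rows.append(
                {
                    "patient_id": patient,
                    "time_months": float(t[j]),
                    "day": int(days[j]),
                    "scope": analyte,
                    "prev_grade": int(comparator),
                    "new_grade": g,
                    "delta": g - int(comparator),
                }
            )
        comparator = g
    if not rows:
        return _empty_events()
    out = pd.DataFrame(rows)
    out["synchronous"] = False
    out["magnitude"] = np.where(out["delta"] > 1, GT_ONE_GRADE, ONE_GRADE)
    return out[EVENT_COLUMNS]


def classify_synchrony(individual_events: pd.DataFrame) -> pd.DataFrame:
    """Flag events sharing a patient-day with another chemistry's event."""
    if individual_events.empty:
        return individual_events.copy()
    ev = individual_events.copy()
    n_per_day = ev.groupby(["patient_id", "day"])["scope"].transform("nunique")
    ev["synchronous"] = n_per_day > 1
    return ev


def derive_combined_events(
    individual_events: pd.DataFrame,
    definition: CompositeDefinition,
    magnitude_rule: str = "sum",
) -> pd.DataFrame:
    """One composite event per patient-day with >= 1 member event.

    The composite delta aggregates the same-day member deltas (default
    ``"sum"``; ``"max"`` is the alternative rule), so two synchronous
    1-grade member upgrades yield a >1-grade composite event under the sum
    rule.  ``synchronous`` marks days with >= 2 member events.
    """
    if magnitude_rule not in ("sum", "max"):
        raise ValueError(f"magnitude_rule must be 'sum' or 'max', got {magnitude_rule!r}")
    ev = individual_events[individual_events["scope"].isin(definition.members)]
    if ev.empty:
        return _empty_events()
    agg = ev.groupby(["patient_id", "day"], as_index=False).agg(
        time_months=("time_months", "max"),
        delta=("delta", magnitude_rule),
        n_members=("scope", "nunique"),
        prev_grade=("prev_grade", "sum"),
        new_grade=("new_grade", "sum"),
    )
    out = pd.DataFrame(
        {
            "patient_id": agg["patient_id"],
            "time_months": agg["time_months"],
            "day": agg["day"],
            "scope": definition.name,
            "prev_grade": agg["prev_grade"],
            "new_grade": agg["new_grade"],
            "delta": agg["delta"],
            "synchronous": agg["n_members"] > 1,
            "magnitude": np.where(agg["delta"] > 1, GT_ONE_GRADE, ONE_GRADE),
        }
    )
    return out.sort_values(["patient_id", "time_months"]).reset_index(drop=True)[EVENT_COLUMNS]


def derive_all_events(
    grades: pd.DataFrame,
    definition: CompositeDefinition,
    magnitude_rule: str = "sum",
    primary_window_days: float = 7.0,
    fallback_window_days: Optional[float] = DAYS_PER_MONTH,
) -> pd.DataFrame:
    """Full event derivation over a graded cohort table.

    Splits each patient's records into pre-treatment (time <= 0, used only
    for the reference grade) and follow-up, derives individual events per
    member analyte, flags synchrony, and appends the composite events.
    """
    pre = grades[grades["time_months"] <= 0]
    post = grades[grades["time_months"] > 0]
    pieces = []
    for (pid, analyte), series in post.groupby(["patient_id", "analyte"], sort=True):
        if analyte not in definition.members:
            continue
        ref = reference_grade(
            pre[pre["patient_id"] == pid],
            analyte,
            primary_window_days,
            fallback_window_days,
        )
        pieces.append(derive_individual_events(series.sort_values("time_months"), ref))
    indiv = (
        pd.concat([p for p in pieces if not p.empty], ignore_index=True)
        if any(not p.empty for p in pieces)
        else _empty_events()
    )
    indiv = classify_synchrony(indiv)
    combined = derive_combined_events(indiv, definition, magnitude_rule)
    out = pd.concat([indiv, combined], ignore_index=True)
    return out.sort_values(["patient_id", "scope", "time_months"]).reset_index(drop=True)


def person_months(grades: pd.DataFrame, scope) -> pd.DataFrame:
    """Follow-up per patient for one scope (analyte name or composite).

    Person-months run from radiotherapy completion (time 0) to the last
    visit carrying a test for the scope; a patient with no post-treatment
    test of the scope gets 0 person-months and is flagged unobserved.
    """
    if isinstance(scope, CompositeDefinition):
        members, label = set(scope.members), scope.name
    else:
        members, label = {scope}, scope
    post = grades[(grades["time_months"] > 0) & (grades["analyte"].isin(members))]
    last = post.groupby("patient_id")["time_months"].max()
    patients = pd.Index(grades["patient_id"].unique(), name="patient_id")
    pm = last.reindex(patients).fillna(0.0)
    return pd.DataFrame(
        {
            "patient_id": patients,
            "scope": label,
            "person_months": pm.to_numpy(),
            "observed": (pm > 0).to_numpy(),
        }
    ).reset_index(drop=True)


def incidence_rates(
    events: pd.DataFrame,
    follow_up: pd.DataFrame,
    strata: Mapping,
    scope: Optional[str] = None,
) -> pd.DataFrame:
    """Events per person-month by stratum.

    ``strata`` maps patient_id to a stratum label (baseline score value,
    gender, ...).  A stratum with zero person-months reports a NaN rate,
    not zero.
    """
    fu = follow_up.copy()
    fu["stratum"] = fu["patient_id"].map(strata)
    ev = events if scope is None else events[events["scope"] == scope]
    ev = ev[ev["patient_id"].isin(fu["patient_id"])]
    counts = ev.assign(stratum=ev["patient_id"].map(strata)).groupby("stratum").size()
    pm = fu.groupby("stratum")["person_months"].sum()
    table = pd.DataFrame({"events": counts, "person_months": pm}).fillna({"events": 0})
    table["events"] = table["events"].astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        table["rate"] = np.where(
            table["person_months"] > 0, table["events"] / table["person_months"], np.nan
        )
    return table.reset_index().sort_values("stratum").reset_index(drop=True)


def summarize_events(events: pd.DataFrame, scopes: Sequence[str]) -> pd.DataFrame:
    """Per-scope counts and row percentages of single/synchronous and
    1-grade/>1-grade events (the cohort event-summary layout)."""
    rows = []
    for scope in scopes:
        ev = events[events["scope"] == scope]
        total = len(ev)
        sync = int(ev["synchronous"].sum())
        gt1 = int((ev["magnitude"] == GT_ONE_GRADE).sum())
        single, one = total - sync, total - gt1
        pct = lambda k: round(100.0 * k / total, 1) if total else 0.0
        rows.append(
            {
                "scope": scope,
                "single": single,
                "single_pct": pct(single),
                "synchronous": sync,
                "synchronous_pct": pct(sync),
                "one_grade": one,
                "one_grade_pct": pct(one),
                "gt_one_grade": gt1,
                "gt_one_grade_pct": pct(gt1),
                "total": total,
            }
        )
    return pd.DataFrame(rows)
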