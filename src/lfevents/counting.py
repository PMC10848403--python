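"""Andersen–Gill counting-process representation of recurrent events.

Each patient's follow-up for one event scope becomes disjoint, contiguous
``(start, stop]`` intervals on the calendar (total-time) scale, split at the
patient's own event times: ``(0, t1], (t1, t2], ..., (tk, C]`` with the
event indicator 1 on intervals ending at event times.  Baseline covariates
are time-fixed; covariate-by-time products are *not* expanded into the
table but evaluated exactly at event times inside the estimation engine.
"""

from __future__ import annotations

import logging
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["build_intervals", "time_dependent_value", "prepare_covariates", "INTERVAL_COLUMNS"]

INTERVAL_COLUMNS = ["cluster_id", "start", "stop", "status"]


def identity(t):
    return t


def time_dependent_value(covariate_value: float, t: float, transform: Callable = identity) -> float:
    """Value of a constructed covariate-by-time product at time ``t``."""
    return covariate_value * transform(t)


def prepare_covariates(raw: pd.DataFrame) -> pd.DataFrame:
    """Model-scale covariate table.

    Renames/derives the model columns: CTV and NLV enter per 100 mL,
    normal-liver mean dose per Gy; binary indicators pass through.  Columns
    already on model scale are left untouched.
    """
    cov = raw.copy()
    if "ctv_ml" in cov.columns and "ctv_per_100ml" not in cov.columns:
        cov["ctv_per_100ml"] = cov["ctv_ml"] / 100.0
    if "nlv_ml" in cov.columns and "nlv_per_100ml" not in cov.columns:
        cov["nlv_per_100ml"] = cov["nlv_ml"] / 100.0
    return cov


def build_intervals(
    events: pd.DataFrame,
    follow_up: pd.DataFrame,
    covariates: pd.DataFrame,
    scope: str,
    covariate_cols: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Build (start, stop] risk intervals for one event scope.

    Parameters
    ----------
    events : DataFrame
        Event table with ``patient_id, time_months, scope`` (other columns
        ignored); only rows matching ``scope`` are used.
    follow_up : DataFrame
        ``patient_id, person_months`` for the same scope (censor times).
    covariates : DataFrame
        One row per patient (``patient_id`` + covariate columns); patients
        with any missing covariate among ``covariate_cols`` are excluded
        complete-case, with the count logged.
    scope : str
        Event-type label (analyte or composite name).

    Returns
    -------
    DataFrame with ``cluster_id, start, stop, status`` plus covariate
    columns, one block of contiguous intervals per retained patient.
    """
    ev = events[events["scope"] == scope] if "scope" in events.columns else events
    cov = covariates.set_index("patient_id")
    if covariate_cols is None:
        covariate_cols = [c for c in cov.columns]
    cov = cov[list(covariate_cols)]

    complete = cov.dropna()
    n_excluded = len(cov) - len(complete)
    if n_excluded:
        logger.info("scope %s: excluded %d patients with missing covariates", scope, n_excluded)

    censor = follow_up.set_index("patient_id")["person_months"]
    rows = []
    for pid, c_time in censor.items():
        if pid not in complete.index or c_time <= 0:
            continue
        times = np.sort(ev.loc[ev["patient_id"] == pid, "time_months"].to_numpy(dtype=float))
        if len(times) and times[-1] > c_time + 1e-12:
            raise ValueError(f"patient {pid}: event at {times[-1]} after censor time {c_time}")
        if len(np.unique(times)) != len(times):
            raise ValueError(f"patient {pid}: duplicate event times within scope {scope}")
        edges = [0.0] + list(times)
        for j, t in enumerate(times):
            rows.append((pid, edges[j], t, 1))
        if not len(times) or times[-1] < c_time - 1e-12:
            rows.append((pid, edges[-1], float(c_time), 0))
    out = pd.DataFrame(rows, columns=INTERVAL_COLUMNS)
    out = out.join(complete, on="cluster_id")
    out.attrs["scope"] = scope
    out.attrs["n_excluded_missing"] = n_excluded
    return out
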