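"""CTCAE-style grading of liver chemistries.

Six serum liver chemistries (BIL, AST, ALT, ALKP, INR, ALB) are mapped to
ordinal grades by fixed cutoff ladders anchored at multiples of the upper
(or, for albumin, lower) limit of normal.  Grades sum into composite
liver-function scores (ALL6 over all six chemistries, ALL4 and ALL3 over
subsets).  A uniform multiplicative cutoff scaling supports sensitivity
analyses of the grading scale itself.

Boundary semantics follow the clinical scale exactly: for chemistries where
high values are worse, grade 0 is ``value <= c1`` and grade k is
``c_k < value <= c_{k+1}``; for albumin (low is worse), grade 0 is
``value >= c1`` and grade k is ``c_{k+1} <= value < c_k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ANALYTES",
    "AnalyteScale",
    "CompositeDefinition",
    "DEFAULT_SCALES",
    "ALL6",
    "ALL4",
    "ALL3",
    "COMPOSITES",
    "DAYS_PER_MONTH",
    "grade_value",
    "scale_cutoffs",
    "composite_score",
    "grade_series",
    "value_band",
]

#: Average calendar month length used for all day <-> month conversions.
DAYS_PER_MONTH = 30.4375

ANALYTES = ("BIL", "AST", "ALT", "ALKP", "INR", "ALB")

HIGH_IS_WORSE = "high_is_worse"
LOW_IS_WORSE = "low_is_worse"


@dataclass(frozen=True)
class AnalyteScale:
    """Graded cutoff ladder for one liver chemistry.

    Parameters
    ----------
    analyte : str
        One of ``BIL, AST, ALT, ALKP, INR, ALB``.
    direction : str
        ``"high_is_worse"`` or ``"low_is_worse"`` (albumin).
    cutoffs : tuple of float
        Grade boundaries in analyte units, strictly increasing for
        high-is-worse scales and strictly decreasing for low-is-worse.
        ``len(cutoffs) == max_grade``.
    units : str
        Unit label the input values must carry (validated, not converted).
    scale_factor : float
        Multiplier already applied to the printed cutoffs (sensitivity
        analyses use 0.7–1.3); 1.0 for the default scale.
    """

    analyte: str
    direction: str
    cutoffs: tuple
    units: str
    scale_factor: float = 1.0

    def __post_init__(self):
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}")
        if self.direction not in (HIGH_IS_WORSE, LOW_IS_WORSE):
            raise ValueError(f"bad direction {self.direction!r}")
        c = np.asarray(self.cutoffs, dtype=float)
        if c.ndim != 1 or len(c) < 1 or not np.all(np.isfinite(c)):
            raise ValueError(f"{self.analyte}: invalid cutoffs {self.cutoffs}")
        d = np.diff(c)
        if self.direction == HIGH_IS_WORSE and not np.all(d > 0):
            raise ValueError(f"{self.analyte}: cutoffs must strictly increase")
        if self.direction == LOW_IS_WORSE and not np.all(d < 0):
            raise ValueError(f"{self.analyte}: cutoffs must strictly decrease")
        object.__setattr__(self, "cutoffs", tuple(float(x) for x in c))

    @property
    def max_grade(self) -> int:
        return len(self.cutoffs)

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "direction": self.direction,
            "cutoffs": list(self.cutoffs),
            "units": self.units,
            "scale_factor": self.scale_factor,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalyteScale":
        return cls(
            analyte=d["analyte"],
            direction=d["direction"],
            cutoffs=tuple(d["cutoffs"]),
            units=d["units"],
            scale_factor=float(d.get("scale_factor", 1.0)),
        )


def _default_scales() -> dict:
    return {
        "BIL": AnalyteScale("BIL", HIGH_IS_WORSE, (1.5, 2.25, 4.5, 15.0), "mg/dL"),
        "AST": AnalyteScale("AST", HIGH_IS_WORSE, (35.0, 105.0, 175.0, 700.0), "IU/L"),
        "ALT": AnalyteScale("ALT", HIGH_IS_WORSE, (35.0, 105.0, 175.0, 700.0), "IU/L"),
        "ALKP": AnalyteScale("ALKP", HIGH_IS_WORSE, (120.0, 300.0, 600.0, 2400.0), "IU/L"),
        "INR": AnalyteScale("INR", HIGH_IS_WORSE, (1.2, 1.5, 2.5), "unitless"),
        "ALB": AnalyteScale("ALB", LOW_IS_WORSE, (3.5, 3.0, 2.0), "g/dL"),
    }


#: The default grading scales (scale factor 1.0).
DEFAULT_SCALES = _default_scales()

REQUIRE_COMPLETE = "require_complete"
SUM_AVAILABLE = "sum_available"


@dataclass(frozen=True)
class CompositeDefinition:
    """A composite liver-function score: the sum of member analyte grades."""

    name: str
    members: tuple
    missing_policy: str = REQUIRE_COMPLETE

    def __post_init__(self):
        unknown = [a for a in self.members if a not in ANALYTES]
        if unknown:
            raise ValueError(f"unknown analytes in composite: {unknown}")
        if self.missing_policy not in (REQUIRE_COMPLETE, SUM_AVAILABLE):
            raise ValueError(f"bad missing_policy {self.missing_policy!r}")

    @property
    def max_score(self) -> int:
        return sum(DEFAULT_SCALES[a].max_grade for a in self.members)


ALL6 = CompositeDefinition("ALL6", ("BIL", "AST", "ALT", "ALKP", "INR", "ALB"))
ALL4 = CompositeDefinition("ALL4", ("BIL", "AST", "ALT", "ALKP"))
ALL3 = CompositeDefinition("ALL3", ("BIL", "AST", "ALT"))

COMPOSITES = {"ALL6": ALL6, "ALL4": ALL4, "ALL3": ALL3}


def grade_value(scale: AnalyteScale, value: float) -> int:
    """Grade a single lab value on the scale's cutoff ladder.

    For high-is-worse scales the grade is the number of cutoffs strictly
    below the value; for albumin it is the number of cutoffs strictly above.
    Printed boundary inclusivities (grade 0 at ``value == c1``) follow.
    """
    v = float(value)
    if not np.isfinite(v) or v <= 0:
        raise ValueError(f"{scale.analyte}: lab value must be positive and finite, got {value!r}")
    c = np.asarray(scale.cutoffs)
    if scale.direction == HIGH_IS_WORSE:
        return int(np.sum(v > c))
    return int(np.sum(v < c))


def scale_cutoffs(scale: AnalyteScale, factor: float) -> AnalyteScale:
    """Multiply every cutoff by ``factor`` (sensitivity-analysis transform)."""
    f = float(factor)
    if not np.isfinite(f) or f <= 0:
        raise ValueError(f"cutoff scale factor must be positive, got {factor!r}")
    return replace(
        scale,
        cutoffs=tuple(c * f for c in scale.cutoffs),
        scale_factor=scale.scale_factor * f,
    )


def scaled_scales(factor: float, scales: Optional[Mapping[str, AnalyteScale]] = None) -> dict:
    """Apply one multiplicative factor to every analyte's cutoffs."""
    base = DEFAULT_SCALES if scales is None else scales
    return {a: scale_cutoffs(s, factor) for a, s in base.items()}


def composite_score(grades: Mapping[str, object], definition: CompositeDefinition):
    """Sum member grades into a composite score.

    Returns ``None`` when a member grade is absent under the
    ``require_complete`` policy; under ``sum_available`` returns
    ``(score, complete)`` with the sum over present members.
    """
    present = {}
    for a in definition.members:
        g = grades.get(a)
        if g is None or (isinstance(g, float) and np.isnan(g)):
            continue
        g = int(g)
        if not 0 <= g <= DEFAULT_SCALES[a].max_grade:
            raise ValueError(f"grade {g} out of range for {a}")
        present[a] = g
    complete = len(present) == len(definition.members)
    if definition.missing_policy == REQUIRE_COMPLETE:
        return sum(present.values()) if complete else None
    return sum(present.values()), complete


def grade_series(labs: pd.DataFrame, scales: Optional[Mapping[str, AnalyteScale]] = None) -> pd.DataFrame:
    """Convert long-format lab records to grade records.

    Parameters
    ----------
    labs : DataFrame
        Columns ``patient_id, time_months, analyte, value`` and optionally
        ``unit`` (validated against the scale's units when present).
        Negative times denote pre-treatment tests and pass through.

    Returns
    -------
    DataFrame with columns ``patient_id, time_months, day, analyte, grade``;
    multiple tests of one analyte on one patient-day are collapsed to the
    single worst grade; sorted by patient, analyte, time.
    """
    scales = DEFAULT_SCALES if scales is None else scales
    required = {"patient_id", "time_months", "analyte", "value"}
    missing = required - set(labs.columns)
    if missing:
        raise ValueError(f"lab table missing columns {sorted(missing)}")
    if labs.empty:
        return pd.DataFrame(columns=["patient_id", "time_months", "day", "analyte", "grade"])

    unknown = set(labs["analyte"]) - set(scales)
    if unknown:
        raise ValueError(f"unknown analytes in lab table: {sorted(unknown)}")
    if "unit" in labs.columns:
        for a, grp in labs.groupby("analyte"):
            bad = set(grp["unit"].dropna()) - {scales[a].units}
            if bad:
                raise ValueError(
                    f"{a}: unit mismatch {sorted(bad)} (scale expects {scales[a].units!r})"
                )

    out = labs[["patient_id", "time_months", "analyte", "value"]].copy()
    out["grade"] = [
        grade_value(scales[a], v) for a, v in zip(out["analyte"], out["value"])
    ]
    # calendar-day index; floor keeps pre-treatment days negative
    out["day"] = np.floor(out["time_months"].to_numpy() * DAYS_PER_MONTH + 1e-9).astype(int)
    # worst grade per patient x analyte x day; keep the day's latest time
    out = (
        out.sort_values(["patient_id", "analyte", "day", "grade", "time_months"])
        .groupby(["patient_id", "analyte", "day"], as_index=False, sort=False)
        .last()
    )
    out = out.sort_values(["patient_id", "analyte", "time_months"], kind="mergesort")
    return out[["patient_id", "time_months", "day", "analyte", "grade"]].reset_index(drop=True)


def value_band(scale: AnalyteScale, grade: int):
    """Open/closed value interval realizing ``grade`` on ``scale``.

    Returns ``(low, high)`` such that any value strictly inside maps back to
    ``grade``.  Unbounded ends are closed off at twice (half) the extreme
    cutoff so the band can be sampled.
    """
    if not 0 <= grade <= scale.max_grade:
        raise ValueError(f"grade {grade} out of range for {scale.analyte}")
    c = list(scale.cutoffs)
    if scale.direction == HIGH_IS_WORSE:
        bounds = [c[0] / 2.0] + c + [c[-1] * 2.0]
        return bounds[grade], bounds[grade + 1]
    bounds = [c[0] * 1.5] + c + [c[-1] / 2.0]
    return bounds[grade + 1], bounds[grade]
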