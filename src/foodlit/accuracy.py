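"""Accuracy of eat-domain goal assignment against dietary-intake thresholds.

Five eat-domain goals carry food-based dietary recommendations expressed as
strict intake thresholds (boundary values count as compliant). A goal is
*correctly* assigned when it sits in a respondent's top-3 priority list and
that respondent's intake actually violates the recommendation; accuracy is
the fraction of assigned respondents that are correct. An empty assignment
set reports 100% by reporting convention, flagged as undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .errors import ComputationError, DataError

__all__ = [
    "FFQIntake",
    "EatGoalRecommendation",
    "EAT_GOAL_RECOMMENDATIONS",
    "fails_recommendation",
    "goal_accuracy",
    "accuracy_table",
    "energy_adjust",
    "round_half_up",
    "read_intakes_csv",
    "write_intakes_csv",
    "GoalAccuracy",
    "AccuracyReport",
]

INTAKE_FIELDS = ("meat", "vegetables", "fruit", "water", "ultra_processed")


@dataclass(frozen=True)
class FFQIntake:
    """Daily intakes: grams/day for foods, ml/day for water."""

    meat: float
    vegetables: float
    fruit: float
    water: float
    ultra_processed: float
    energy: Optional[float] = None  # kcal/day

    def __post_init__(self):
        for name in INTAKE_FIELDS:
            if getattr(self, name) is None:
                continue
            if getattr(self, name) < 0:
                raise DataError(f"intake {name} must be >= 0")


@dataclass(frozen=True)
class EatGoalRecommendation:
    goal_id: str
    field: str
    threshold: float
    unit: str
    direction: str  # "fail_if_above" | "fail_if_below"


#: Bundled recommendations, strict inequalities as published.
EAT_GOAL_RECOMMENDATIONS: dict[str, EatGoalRecommendation] = {
    r.goal_id: r
    for r in (
        EatGoalRecommendation("G14", "meat", 100.0, "g/day", "fail_if_above"),
        EatGoalRecommendation("G15", "vegetables", 300.0, "g/day", "fail_if_below"),
        EatGoalRecommendation("G16", "fruit", 250.0, "g/day", "fail_if_below"),
        EatGoalRecommendation("G17", "water", 1500.0, "ml/day", "fail_if_below"),
        EatGoalRecommendation("G18", "ultra_processed", 50.0, "g/day", "fail_if_above"),
    )
}


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves away from zero (report parity)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def fails_recommendation(
    goal: Union[str, EatGoalRecommendation], intake: FFQIntake
) -> bool:
    """True iff the intake strictly violates the goal's threshold."""
    rec = EAT_GOAL_RECOMMENDATIONS[goal] if isinstance(goal, str) else goal
    value = getattr(intake, rec.field, None)
    if value is None:
        raise DataError(f"intake record lacks the {rec.field!r} field needed for {rec.goal_id}")
    if rec.direction == "fail_if_above":
        return value > rec.threshold
    if rec.direction == "fail_if_below":
        return value < rec.threshold
    raise ComputationError(f"unknown direction {rec.direction!r}")


@dataclass(frozen=True)
class GoalAccuracy:
    goal_id: str
    n_top3: int
    n_correct: int
    accuracy_pct: float          # raw fraction * 100
    undefined_by_convention: bool = False

    @property
    def accuracy_int(self) -> int:
        return round_half_up(self.accuracy_pct)


def goal_accuracy(
    top3_assignments: Mapping[str, Iterable[str]],
    intakes: Mapping[str, FFQIntake],
    goal: Union[str, EatGoalRecommendation],
) -> GoalAccuracy:
    """Accuracy for one eat goal over a cohort.

    ``top3_assignments`` maps respondent id to their top-priority goal ids;
    ``intakes`` maps respondent id to the FFQ record. Every respondent
    assigned the goal must have an intake record. When nobody is assigned
    the goal, reports 100 with the undefined-by-convention flag.
    """
    rec = EAT_GOAL_RECOMMENDATIONS[goal] if isinstance(goal, str) else goal
    assigned = [rid for rid, goals in top3_assignments.items() if rec.goal_id in set(goals)]
    missing = [rid for rid in assigned if rid not in intakes]
    if missing:
        raise DataError(
            f"no intake record for respondents assigned {rec.goal_id}: {missing}"
        )
    n_correct = sum(1 for rid in assigned if fails_recommendation(rec, intakes[rid]))
    n = len(assigned)
    if n == 0:
        return GoalAccuracy(rec.goal_id, 0, 0, 100.0, undefined_by_convention=True)
    return GoalAccuracy(rec.goal_id, n, n_correct, 100.0 * n_correct / n)


@dataclass(frozen=True)
class AccuracyReport:
    rows: tuple[GoalAccuracy, ...]

    @property
    def min_accuracy(self) -> int:
        return min(r.accuracy_int for r in self.rows)

    @property
    def max_accuracy(self) -> int:
        return max(r.accuracy_int for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "goal_id": [r.goal_id for r in self.rows],
                "n_top3": [r.n_top3 for r in self.rows],
                "n_correct": [r.n_correct for r in self.rows],
                "accuracy_pct": [r.accuracy_pct for r in self.rows],
                "accuracy_int": [r.accuracy_int for r in self.rows],
                "undefined_by_convention": [r.undefined_by_convention for r in self.rows],
            }
        )

    def to_dict(self) -> dict:
        return {
            "goals": [
                {
                    "goal_id": r.goal_id,
                    "n_top3": r.n_top3,
                    "n_correct": r.n_correct,
                    "accuracy_pct": r.accuracy_pct,
                    "accuracy_int": r.accuracy_int,
                    "undefined_by_convention": r.undefined_by_convention,
                }
                for r in self.rows
            ],
            "min_accuracy": self.min_accuracy,
            "max_accuracy": self.max_accuracy,
        }


def accuracy_table(
    top3_assignments: Mapping[str, Iterable[str]],
    intakes: Mapping[str, FFQIntake],
    goals: Optional[Sequence[Union[str, EatGoalRecommendation]]] = None,
) -> AccuracyReport:
    """One accuracy row per eat goal plus a min/max summary."""
    if goals is None:
        goals = list(EAT_GOAL_RECOMMENDATIONS)
    rows = tuple(goal_accuracy(top3_assignments, intakes, g) for g in goals)
    return AccuracyReport(rows=rows)


def energy_adjust(intake: FFQIntake, reference: float) -> FFQIntake:
    """Scale every food quantity by reference/energy (kcal/day).

    Off by default in every pipeline; available for sensitivity analyses.
    """
    if intake.energy is None or intake.energy <= 0:
        raise DataError("energy_adjust requires a positive energy field")
    factor = reference / intake.energy
    return replace(
        intake,
        **{name: getattr(intake, name) * factor for name in INTAKE_FIELDS},
    )


# ---------------------------------------------------------------------------
# tabular I/O


def read_intakes_csv(path: Union[str, Path]) -> dict[str, FFQIntake]:
    """Read intakes keyed by respondent id from CSV with the five food
    columns (plus optional ``energy``)."""
    df = pd.read_csv(path)
    required = {"respondent_id", *INTAKE_FIELDS}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        energy = row.get("energy")
        out[str(row["respondent_id"])] = FFQIntake(
            meat=float(row["meat"]),
            vegetables=float(row["vegetables"]),
            fruit=float(row["fruit"]),
            water=float(row["water"]),
            ultra_processed=float(row["ultra_processed"]),
            energy=None if energy is None or pd.isna(energy) else float(energy),
        )
    return out


def write_intakes_csv(path: Union[str, Path], intakes: Mapping[str, FFQIntake]) -> None:
    rows = []
    for rid, intake in intakes.items():
        row = {"respondent_id": rid}
        for name in INTAKE_FIELDS:
            row[name] = getattr(intake, name)
        if intake.energy is not None:
            row["energy"] = intake.energy
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
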