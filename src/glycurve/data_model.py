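"""Domain types for the fasting / meal-test / clamp analysis.

A cohort pairs one :class:`SubjectRecord` with an optional
:class:`MealSeries` (liquid mixed-meal tolerance test, LMMTT) and an
optional :class:`ClampSteadyState` (euglycemic-hyperinsulinemic clamp).
Values are stored in canonical units throughout: glucose mmol/l, insulin
mU/l, times in minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: The meal-test sampling grid used by the study protocol, minutes.
CANONICAL_MEAL_GRID: tuple[int, ...] = (0, 30, 60, 90, 120, 240)

#: Inclusion threshold for normoglycemia, mmol/l fasting glucose.
NORMOGLYCEMIA_FG_LIMIT: float = 7.0


@dataclass(frozen=True)
class SubjectRecord:
    """One participant's fasting and anthropometric state.

    ``fasting_glucose`` in mmol/l, ``fasting_insulin`` in mU/l,
    ``lean_body_mass`` in kg, ``waist`` in cm.
    """

    subject_id: str
    group: str
    age: float
    bmi: float
    waist: float
    percent_body_fat: float
    lean_body_mass: float
    fasting_glucose: float
    fasting_insulin: float

    def __post_init__(self) -> None:
        for name in ("fasting_glucose", "fasting_insulin", "lean_body_mass", "age"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(
                    f"subject {self.subject_id!r}: {name} must be positive and "
                    f"finite, got {v}"
                )

    @property
    def normoglycemic(self) -> bool:
        """Whether fasting glucose satisfies the study's <7.0 mmol/l rule."""
        return self.fasting_glucose < NORMOGLYCEMIA_FG_LIMIT


@dataclass(frozen=True)
class MealSeries:
    """Paired glucose/insulin concentrations over a meal-test time grid.

    Any strictly increasing grid starting at 0 is accepted; operations
    needing specific timepoints (e.g. the 30-min sample for the
    insulinogenic index) fail loudly rather than interpolate.
    """

    subject_id: str
    times: tuple[float, ...]
    glucose: tuple[float, ...]
    insulin: tuple[float, ...]

    def __init__(
        self,
        subject_id: str,
        times: Sequence[float],
        glucose: Sequence[float],
        insulin: Sequence[float],
    ):
        t = tuple(float(x) for x in times)
        g = tuple(float(x) for x in glucose)
        i = tuple(float(x) for x in insulin)
        if len(t) < 2:
            raise ValueError(f"subject {subject_id!r}: need >=2 timepoints")
        if t[0] != 0:
            raise ValueError(f"subject {subject_id!r}: first timepoint must be 0")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError(f"subject {subject_id!r}: times must be strictly increasing")
        if len(g) != len(t) or len(i) != len(t):
            raise ValueError(f"subject {subject_id!r}: glucose/insulin length mismatch")
        if any(v <= 0 or not math.isfinite(v) for v in g + i):
            raise ValueError(f"subject {subject_id!r}: concentrations must be positive")
        object.__setattr__(self, "subject_id", subject_id)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "glucose", g)
        object.__setattr__(self, "insulin", i)

    def value_at(self, time: float, analyte: str) -> float:
        """Exact sampled value at ``time``; KeyError if not on the grid."""
        arr = self.glucose if analyte == "glucose" else self.insulin
        for t, v in zip(self.times, arr):
            if t == time:
                return v
        raise KeyError(f"subject {self.subject_id!r}: no sample at t={time} min")

    def has_time(self, time: float) -> bool:
        return time in self.times

    @property
    def on_canonical_grid(self) -> bool:
        return self.times == tuple(float(t) for t in CANONICAL_MEAL_GRID)


@dataclass(frozen=True)
class ClampSteadyState:
    """Final-30-min steady state of the euglycemic-hyperinsulinemic clamp.

    ``mean_gir`` is the absolute dextrose infusion rate in mg/min averaged
    over the final 30 min (normalisation by lean mass happens in the index,
    not here); ``steady_state_insulin`` in mU/l. The protocol constants
    default to the study design: insulin infused at 40 mU·m⁻²·min⁻¹ with
    glucose clamped at 5.0 mmol/l.
    """

    subject_id: str
    mean_gir: float
    steady_state_insulin: float
    lean_body_mass: float
    insulin_infusion_rate: float = 40.0
    target_glucose: float = 5.0

    def __post_init__(self) -> None:
        if self.mean_gir < 0:
            raise ValueError(f"subject {self.subject_id!r}: mean_gir must be >= 0")
        if not self.steady_state_insulin > 0:
            raise ValueError(
                f"subject {self.subject_id!r}: steady_state_insulin must be > 0"
            )
        if not self.lean_body_mass > 0:
            raise ValueError(f"subject {self.subject_id!r}: lean_body_mass must be > 0")


@dataclass
class IndexPanel:
    """The seven-index panel for one subject, plus the intermediate AUCs.

    Indices that could not be derived (missing meal/clamp data, degenerate
    denominators) are ``None`` and carry a reason in ``exclusions``.
    ``oral_di`` always equals ``isi_mat * insulin_secretion_index`` when
    both factors are present.
    """

    subject_id: str
    group: str
    homa_ir: Optional[float] = None
    homa_b: Optional[float] = None
    isi_clamp: Optional[float] = None
    auc_glucose: Optional[float] = None
    auc_insulin: Optional[float] = None
    iauc_glucose: Optional[float] = None
    iauc_insulin: Optional[float] = None
    isi_mat: Optional[float] = None
    insulinogenic_index: Optional[float] = None
    insulin_secretion_index: Optional[float] = None
    oral_di: Optional[float] = None
    metadata: dict = field(default_factory=dict)
    exclusions: list = field(default_factory=list)

    INDEX_FIELDS = (
        "homa_ir",
        "homa_b",
        "isi_clamp",
        "auc_glucose",
        "auc_insulin",
        "iauc_glucose",
        "iauc_insulin",
        "isi_mat",
        "insulinogenic_index",
        "insulin_secretion_index",
        "oral_di",
    )

    def as_dict(self) -> dict:
        d = {"subject_id": self.subject_id, "group": self.group}
        for f in self.INDEX_FIELDS:
            d[f] = getattr(self, f)
        d["exclusion_reason"] = "; ".join(f"{k}: {v}" for k, v in self.exclusions) or None
        return d


@dataclass(frozen=True)
class CohortSubject:
    """One subject with whichever measurement slots are available."""

    subject: SubjectRecord
    meal: Optional[MealSeries] = None
    clamp: Optional[ClampSteadyState] = None

    @property
    def subject_id(self) -> str:
        return self.subject.subject_id


def meal_arrays(series: MealSeries) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Times, glucose and insulin of a series as float arrays."""
    return (
        np.asarray(series.times, dtype=float),
        np.asarray(series.glucose, dtype=float),
        np.asarray(series.insulin, dtype=float),
    )
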