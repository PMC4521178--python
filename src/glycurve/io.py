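"""Readers/writers for the tidy CSV cohort schemas.

Three files describe a cohort:

``subjects.csv``
    subject_id, group, age_years, bmi, waist_cm, percent_body_fat,
    lean_body_mass_kg, fasting_glucose_mmol_l, fasting_insulin_mU_l
``meal_timeseries.csv`` (long format)
    subject_id, time_min, glucose_mmol_l, insulin_mU_l
``clamp.csv``
    subject_id, mean_gir_mg_min, steady_state_insulin_mU_l,
    lean_body_mass_kg

All numeric columns are plain decimal, UTF-8, header row mandatory.
Records are joined on subject_id; a subject missing a meal or clamp
record keeps that slot empty and a warning is logged — no imputation
anywhere.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .data_model import ClampSteadyState, CohortSubject, MealSeries, SubjectRecord

logger = logging.getLogger(__name__)

SUBJECT_COLUMNS = [
    "subject_id",
    "group",
    "age_years",
    "bmi",
    "waist_cm",
    "percent_body_fat",
    "lean_body_mass_kg",
    "fasting_glucose_mmol_l",
    "fasting_insulin_mU_l",
]
MEAL_COLUMNS = ["subject_id", "time_min", "glucose_mmol_l", "insulin_mU_l"]
CLAMP_COLUMNS = [
    "subject_id",
    "mean_gir_mg_min",
    "steady_state_insulin_mU_l",
    "lean_body_mass_kg",
]

PathLike = Union[str, Path]


class SchemaError(ValueError):
    """A CSV file does not match the expected cohort schema."""


def _read_csv(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    numeric = [c for c in required if c not in ("subject_id", "group")]
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            # +2: header line plus 1-based indexing
            line = int(bad.idxmax()) + 2
            raise SchemaError(f"{path}: malformed value in column {col!r} at line {line}")
        df[col] = parsed
    return df


def read_cohort(
    subjects_path: PathLike,
    meal_path: PathLike | None = None,
    clamp_path: PathLike | None = None,
) -> list[CohortSubject]:
    """Read subject, meal and clamp CSVs into a joined cohort.

    Returns one :class:`CohortSubject` per row of ``subjects.csv``, in file
    order. Duplicate ``(subject_id, time_min)`` pairs in the meal file are
    an error; meal/clamp rows for unknown subjects are ignored with a
    warning.
    """
    sdf = _read_csv(subjects_path, SUBJECT_COLUMNS)
    if sdf["subject_id"].duplicated().any():
        dup = sdf.loc[sdf["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise SchemaError(f"{subjects_path}: duplicate subject_id {dup!r}")

    meals: dict[str, MealSeries] = {}
    if meal_path is not None:
        mdf = _read_csv(meal_path, MEAL_COLUMNS)
        dups = mdf.duplicated(subset=["subject_id", "time_min"])
        if dups.any():
            sid = mdf.loc[dups, "subject_id"].iloc[0]
            t = mdf.loc[dups, "time_min"].iloc[0]
            raise SchemaError(
                f"{meal_path}: duplicate (subject_id, time) = ({sid!r}, {t})"
            )
        for sid, grp in mdf.groupby("subject_id", sort=False):
            grp = grp.sort_values("time_min")
            meals[str(sid)] = MealSeries(
                str(sid),
                grp["time_min"].tolist(),
                grp["glucose_mmol_l"].tolist(),
                grp["insulin_mU_l"].tolist(),
            )

    clamps: dict[str, ClampSteadyState] = {}
    if clamp_path is not None:
        cdf = _read_csv(clamp_path, CLAMP_COLUMNS)
        for _, row in cdf.iterrows():
            sid = str(row["subject_id"])
            kwargs = {}
            for opt in ("insulin_infusion_rate", "target_glucose"):
                if opt in cdf.columns:
                    kwargs[opt] = float(row[opt])
            clamps[sid] = ClampSteadyState(
                sid,
                float(row["mean_gir_mg_min"]),
                float(row["steady_state_insulin_mU_l"]),
                float(row["lean_body_mass_kg"]),
                **kwargs,
            )

    cohort: list[CohortSubject] = []
    for _, row in sdf.iterrows():
        sid = str(row["subject_id"])
        subject = SubjectRecord(
            subject_id=sid,
            group=str(row["group"]),
            age=float(row["age_years"]),
            bmi=float(row["bmi"]),
            waist=float(row["waist_cm"]),
            percent_body_fat=float(row["percent_body_fat"]),
            lean_body_mass=float(row["lean_body_mass_kg"]),
            fasting_glucose=float(row["fasting_glucose_mmol_l"]),
            fasting_insulin=float(row["fasting_insulin_mU_l"]),
        )
        meal = meals.pop(sid, None)
        clamp = clamps.pop(sid, None)
        if meal_path is not None and meal is None:
            logger.warning("subject %s: no meal series found in %s", sid, meal_path)
        if clamp_path is not None and clamp is None:
            logger.warning("subject %s: no clamp record found in %s", sid, clamp_path)
        cohort.append(CohortSubject(subject=subject, meal=meal, clamp=clamp))

    for sid in list(meals) + list(clamps):
        logger.warning("measurement rows for unknown subject %s ignored", sid)
    return cohort


def write_cohort(
    cohort: Iterable[CohortSubject],
    subjects_path: PathLike,
    meal_path: PathLike | None = None,
    clamp_path: PathLike | None = None,
) -> None:
    """Write a cohort back to the three CSV schemas (inverse of read_cohort)."""
    cohort = list(cohort)
    srows, mrows, crows = [], [], []
    for cs in cohort:
        s = cs.subject
        srows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "age_years": s.age,
                "bmi": s.bmi,
                "waist_cm": s.waist,
                "percent_body_fat": s.percent_body_fat,
                "lean_body_mass_kg": s.lean_body_mass,
                "fasting_glucose_mmol_l": s.fasting_glucose,
                "fasting_insulin_mU_l": s.fasting_insulin,
            }
        )
        if cs.meal is not None:
            for t, g, i in zip(cs.meal.times, cs.meal.glucose, cs.meal.insulin):
                mrows.append(
                    {
                        "subject_id": cs.subject_id,
                        "time_min": t,
                        "glucose_mmol_l": g,
                        "insulin_mU_l": i,
                    }
                )
        if cs.clamp is not None:
            c = cs.clamp
            crows.append(
                {
                    "subject_id": c.subject_id,
                    "mean_gir_mg_min": c.mean_gir,
                    "steady_state_insulin_mU_l": c.steady_state_insulin,
                    "lean_body_mass_kg": c.lean_body_mass,
                    "insulin_infusion_rate": c.insulin_infusion_rate,
                    "target_glucose": c.target_glucose,
                }
            )
    pd.DataFrame(srows, columns=SUBJECT_COLUMNS).to_csv(subjects_path, index=False)
    if meal_path is not None:
        pd.DataFrame(mrows, columns=MEAL_COLUMNS).to_csv(meal_path, index=False)
    if clamp_path is not None:
        cols = CLAMP_COLUMNS + ["insulin_infusion_rate", "target_glucose"]
        pd.DataFrame(crows, columns=cols).to_csv(clamp_path, index=False)
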