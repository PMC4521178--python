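"""The seven-index panel of insulin sensitivity and beta-cell function.

Fasting surrogates (HOMA-IR, HOMA-B), the clamp sensitivity index
(ISI-clamp), and the meal-test derivatives (total/incremental AUC,
Matsuda ISI, insulinogenic index, insulin secretion index, and their
product — the oral disposition index, DI).

Conventions
-----------
* Glucose in mmol/l, insulin in mU/l, everywhere.
* ISI-clamp is reported ×100 by default: the raw quotient
  (M/LBM)/I_ss for physiologic values (~10 mg·kg⁻¹·min⁻¹ over
  ~70 mU/l) is ~0.14, and the ×100 display scaling puts it on the
  conventional ~10–15 scale. Pass ``scale=1`` for the raw quotient.
* The Matsuda index here follows the composite form
  10000 / sqrt(FG × FI × IAUC_glucose × IAUC_insulin), i.e. the square
  root over the full four-term product, which is the dimensionally
  balanced reading. ``matsuda_grouping="fasting-only"`` restricts the
  root to FG×FI. The classic mean-concentration Matsuda variant is a
  separately named function so the two cannot be silently conflated.
"""

from __future__ import annotations

import logging
import math
from typing import Optional

import pandas as pd

from .curves import incremental_auc, total_auc
from .data_model import ClampSteadyState, CohortSubject, IndexPanel, MealSeries, SubjectRecord
from .units import GLUCOSE_MGDL_PER_MMOLL

logger = logging.getLogger(__name__)

HOMA_IR_DENOMINATOR = 22.5
HOMA_B_GLUCOSE_OFFSET = 3.5
ISI_CLAMP_DEFAULT_SCALE = 100.0


def _require_positive(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not (v > 0) or not math.isfinite(v):
            raise ValueError(f"{name} must be positive and finite, got {v}")


def homa_ir(fasting_insulin: float, fasting_glucose: float) -> float:
    """HOMA insulin resistance: FI [mU/l] × FG [mmol/l] / 22.5."""
    _require_positive(fasting_insulin=fasting_insulin, fasting_glucose=fasting_glucose)
    return fasting_insulin * fasting_glucose / HOMA_IR_DENOMINATOR


def homa_b(fasting_insulin: float, fasting_glucose: float) -> float:
    """HOMA beta-cell function: 20 × FI / (FG − 3.5).

    Undefined at FG ≤ 3.5 mmol/l (the model's hypoglycemic singularity).
    """
    _require_positive(fasting_insulin=fasting_insulin, fasting_glucose=fasting_glucose)
    if fasting_glucose <= HOMA_B_GLUCOSE_OFFSET:
        raise ValueError(
            f"HOMA-B undefined for fasting glucose <= {HOMA_B_GLUCOSE_OFFSET} mmol/l "
            f"(hypoglycemic singularity), got {fasting_glucose}"
        )
    return 20.0 * fasting_insulin / (fasting_glucose - HOMA_B_GLUCOSE_OFFSET)


def isi_clamp(
    mean_gir: float,
    lean_body_mass: float,
    steady_state_insulin: float,
    scale: float = ISI_CLAMP_DEFAULT_SCALE,
) -> float:
    """Clamp sensitivity index: (M / lean mass) / steady-state insulin × scale.

    ``mean_gir`` is the absolute glucose infusion rate (mg/min) averaged
    over the final 30 min of the clamp; the result is in
    mg·kg⁻¹(lean)·min⁻¹ per mU/l, ×``scale``.
    """
    _require_positive(
        mean_gir=mean_gir,
        lean_body_mass=lean_body_mass,
        steady_state_insulin=steady_state_insulin,
        scale=scale,
    )
    return (mean_gir / lean_body_mass) / steady_state_insulin * scale


def matsuda_isi(
    fasting_glucose: float,
    fasting_insulin: float,
    iauc_glucose: float,
    iauc_insulin: float,
    grouping: str = "full",
) -> float:
    """Composite meal-test sensitivity index from fasting values and IAUCs.

    ``grouping="full"`` (default): 10000 / sqrt(FG×FI×IAUC_g×IAUC_i).
    ``grouping="fasting-only"``: 10000 / (sqrt(FG×FI) × IAUC_g × IAUC_i).
    """
    _require_positive(
        fasting_glucose=fasting_glucose,
        fasting_insulin=fasting_insulin,
        iauc_glucose=iauc_glucose,
        iauc_insulin=iauc_insulin,
    )
    if grouping == "full":
        return 10000.0 / math.sqrt(
            fasting_glucose * fasting_insulin * iauc_glucose * iauc_insulin
        )
    if grouping == "fasting-only":
        return 10000.0 / (
            math.sqrt(fasting_glucose * fasting_insulin) * iauc_glucose * iauc_insulin
        )
    raise ValueError(f"grouping must be 'full' or 'fasting-only', got {grouping!r}")


def matsuda_isi_classic(series: MealSeries, fasting_insulin: Optional[float] = None) -> float:
    """Classic mean-concentration Matsuda index.

    10000 / sqrt(G0×I0 × Ḡ×Ī) with glucose in mg/dl and the means taken
    over the sampled meal-test values. Provided for comparison with the
    IAUC-based :func:`matsuda_isi`; the two are different statistics.
    """
    g0_mgdl = series.glucose[0] * GLUCOSE_MGDL_PER_MMOLL
    i0 = fasting_insulin if fasting_insulin is not None else series.insulin[0]
    g_mean = sum(series.glucose) / len(series.glucose) * GLUCOSE_MGDL_PER_MMOLL
    i_mean = sum(series.insulin) / len(series.insulin)
    _require_positive(g0=g0_mgdl, i0=i0, g_mean=g_mean, i_mean=i_mean)
    return 10000.0 / math.sqrt(g0_mgdl * i0 * g_mean * i_mean)


def insulinogenic_index(series: MealSeries) -> Optional[float]:
    """Early-phase insulin response: (I30 − I0) / (G30 − G0).

    Returns ``None`` (caller logs an exclusion) when the 0→30-min glucose
    change is zero; raises if the 30-min sample is absent.
    """
    if not series.has_time(30):
        raise ValueError(
            f"subject {series.subject_id!r}: insulinogenic index needs a 30-min sample"
        )
    dg = series.value_at(30, "glucose") - series.value_at(0, "glucose")
    di = series.value_at(30, "insulin") - series.value_at(0, "insulin")
    if dg == 0:
        return None
    return di / dg


def insulin_secretion_index(series: MealSeries) -> float:
    """Total insulin response: total AUC insulin / total AUC glucose."""
    return total_auc(series.times, series.insulin) / total_auc(series.times, series.glucose)


def oral_di(isi_mat: float, secretion_index: float) -> float:
    """Oral disposition index: ISI-Mat × insulin secretion index.

    Constant along the hyperbola of appropriate beta-cell compensation;
    invariant to a uniform rescaling of every insulin measurement.
    """
    _require_positive(isi_mat=isi_mat, secretion_index=secretion_index)
    return isi_mat * secretion_index


def compute_panel(
    subject: SubjectRecord,
    meal: Optional[MealSeries] = None,
    clamp: Optional[ClampSteadyState] = None,
    iauc_convention: str = "net",
    matsuda_grouping: str = "full",
    isi_clamp_scale: float = ISI_CLAMP_DEFAULT_SCALE,
) -> IndexPanel:
    """Every derivable index for one subject; missing inputs yield nulls.

    Per-index domain errors (HOMA-B singularity, non-positive net IAUC,
    flat 0→30-min glucose) become ``None`` entries with a recorded reason
    rather than aborting the cohort.
    """
    panel = IndexPanel(subject_id=subject.subject_id, group=subject.group)
    panel.metadata = {
        "iauc_convention": iauc_convention,
        "matsuda_grouping": matsuda_grouping,
        "isi_clamp_scale": isi_clamp_scale,
    }

    def attempt(field: str, fn, *args, **kwargs):
        try:
            value = fn(*args, **kwargs)
        except ValueError as exc:
            panel.exclusions.append((field, str(exc)))
            logger.info("subject %s: %s excluded (%s)", subject.subject_id, field, exc)
            return None
        if value is None:
            panel.exclusions.append((field, "degenerate denominator"))
            logger.info("subject %s: %s degenerate", subject.subject_id, field)
        else:
            setattr(panel, field, value)
        return value

    attempt("homa_ir", homa_ir, subject.fasting_insulin, subject.fasting_glucose)
    attempt("homa_b", homa_b, subject.fasting_insulin, subject.fasting_glucose)

    if clamp is not None:
        attempt(
            "isi_clamp",
            isi_clamp,
            clamp.mean_gir,
            clamp.lean_body_mass,
            clamp.steady_state_insulin,
            isi_clamp_scale,
        )
    else:
        panel.exclusions.append(("isi_clamp", "no clamp record"))

    if meal is not None:
        panel.auc_glucose = total_auc(meal.times, meal.glucose)
        panel.auc_insulin = total_auc(meal.times, meal.insulin)
        panel.iauc_glucose = incremental_auc(meal.times, meal.glucose, iauc_convention)
        panel.iauc_insulin = incremental_auc(meal.times, meal.insulin, iauc_convention)
        attempt(
            "isi_mat",
            matsuda_isi,
            subject.fasting_glucose,
            subject.fasting_insulin,
            panel.iauc_glucose,
            panel.iauc_insulin,
            matsuda_grouping,
        )
        attempt("insulinogenic_index", insulinogenic_index, meal)
        attempt("insulin_secretion_index", insulin_secretion_index, meal)
        if panel.isi_mat is not None and panel.insulin_secretion_index is not None:
            panel.oral_di = oral_di(panel.isi_mat, panel.insulin_secretion_index)
        else:
            panel.exclusions.append(("oral_di", "missing ISI-Mat or secretion index"))
    else:
        for f in ("auc", "iauc"):
            panel.exclusions.append((f, "no meal series"))
        panel.exclusions.append(("isi_mat", "no meal series"))
        panel.exclusions.append(("oral_di", "no meal series"))
    return panel


def panel_frame(cohort: list[CohortSubject], **kwargs) -> pd.DataFrame:
    """Compute panels for a whole cohort and return them as a tidy DataFrame.

    One row per subject: subject_id, group, the index columns, and an
    ``exclusion_reason`` column describing any null entries.
    """
    rows = [compute_panel(cs.subject, cs.meal, cs.clamp, **kwargs).as_dict() for cs in cohort]
    return pd.DataFrame(rows)
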