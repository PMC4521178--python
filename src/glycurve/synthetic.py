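"""Seedable synthetic cohorts with known sensitivity/secretion ground truth.

The generative model mirrors the structure the downstream analysis
assumes. Per subject i in group g:

* true clamp-scale sensitivity ``S_i`` ~ lognormal with the group's
  arithmetic mean/SD;
* true secretion ``B_i = δ_g · k_g / S_i · exp(ε_i)``, ε_i ~ N(0, σ_B²):
  beta-cell output compensates sensitivity along the hyperbola with
  constant k_g, shorted by the compensation deficit δ_g ≤ 1 (δ < 1
  places the whole group "off the curve");
* fasting insulin anti-correlates with sensitivity,
  ``FI_i = c_FI / S_i × lognormal noise``;
* the meal glucose curve is ``G(t) = FG_i + A_i·h(t)`` with a fixed
  unimodal kernel h (gamma-density shape, peak at 45 min, h(0)=0,
  h(240)≈0) and excursion amplitude ``A_i ∝ 1/(S_i·B_i)`` — low
  disposition index means high post-meal excursion — normalised per
  group to a target mean incremental glucose AUC;
* the meal insulin curve is ``I(t) = FI_i + β_i·h(t − lag)`` with the
  amplitude β_i solved so that total-AUC(insulin) = B_i × total-AUC
  (glucose) on the sampling grid: the computed insulin secretion index
  then equals the ground-truth B_i exactly in the noiseless limit;
* the clamp record is ``M_i = S_i · I_ss,i · LBM_i / 100`` with steady-
  state insulin I_ss ~ N(70, 8²) mU/l, so the computed ISI-clamp
  (×100 scaling) recovers S_i exactly.

Positivity and inclusion bounds (normoglycemic fasting glucose, lean
BMI) are enforced by resampling, not clipping, to preserve distribution
shape near the bounds. All draws come from one seeded generator, so a
cohort is byte-reproducible from its seed.

``chinese_like``, ``malay_like`` and ``indian_like`` presets encode
group sizes 14/21/24 and moment targets for a lean young Asian male
cohort (sensitivity means 14.2/12.9/8.8, glucose-IAUC targets
157/306/224.6, fasting glucose ~4.1–4.4 mmol/l); SDs are reconstructed
from standard errors at those group sizes. A ``null`` preset gives three
identical groups for type-I-error studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import CANONICAL_MEAL_GRID, ClampSteadyState, CohortSubject, MealSeries, SubjectRecord

#: Meal-curve kernel shape: gamma-density form, peak time (min) and shape.
KERNEL_PEAK_MIN = 45.0
KERNEL_SHAPE = 2.0
#: Delay of the insulin excursion behind the glucose excursion, minutes.
INSULIN_LAG_MIN = 10.0
#: ISI-clamp display scaling used when inverting S into a clamp record.
CLAMP_SCALE = 100.0


def excursion_kernel(t: np.ndarray) -> np.ndarray:
    """Fixed unimodal meal-excursion shape, normalised to peak 1.

    h(t) = (t/tp)^a · exp(a·(1 − t/tp)) with tp=45 min, a=2; h(0)=0 and
    h(240) ≈ 0.005, a smooth gamma-density-like excursion returning to
    baseline by the end of the test. Zero for t < 0.
    """
    t = np.asarray(t, dtype=float)
    x = np.clip(t / KERNEL_PEAK_MIN, 0.0, None)
    return np.where(t > 0, x**KERNEL_SHAPE * np.exp(KERNEL_SHAPE * (1.0 - x)), 0.0)


@dataclass(frozen=True)
class GroupConfig:
    """Generating parameters for one group of subjects.

    ``s_mean``/``s_sd`` are the arithmetic mean and SD of true clamp-scale
    sensitivity; ``di_constant`` (k_g) the hyperbola constant in
    (ISI-clamp × secretion-index) units; ``compensation_deficit`` (δ_g)
    the multiplicative beta-cell shortfall, 1 = appropriate compensation;
    ``iauc_glucose`` the target group-mean incremental glucose AUC in
    mmol·min/l. Sigmas are log-scale SDs of the lognormal noises.
    """

    label: str
    n: int
    s_mean: float
    s_sd: float
    di_constant: float
    compensation_deficit: float = 1.0
    secretion_sigma: float = 0.25
    iauc_glucose: float = 230.0
    excursion_sigma: float = 0.35
    fi_constant: float = 69.0
    fi_sigma: float = 0.35
    fg_mean: float = 4.2
    fg_sd: float = 0.40
    age_mean: float = 25.0
    age_sd: float = 3.0
    bmi_mean: float = 21.3
    bmi_sd: float = 1.4
    waist_mean: float = 76.0
    waist_sd: float = 4.5
    body_fat_mean: float = 19.0
    body_fat_sd: float = 4.8
    lean_mass_mean: float = 52.0
    lean_mass_sd: float = 5.0
    clamp_insulin_mean: float = 70.0
    clamp_insulin_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.label!r}: n must be >= 1")
        if not 0 < self.compensation_deficit <= 1:
            raise ValueError(f"group {self.label!r}: compensation_deficit must be in (0, 1]")
        for name in ("s_mean", "di_constant", "fi_constant", "fg_mean",
                     "age_mean", "lean_mass_mean", "clamp_insulin_mean",
                     "iauc_glucose"):
            if not getattr(self, name) > 0:
                raise ValueError(f"group {self.label!r}: {name} must be positive")
        for name in ("s_sd", "fg_sd", "age_sd", "lean_mass_sd", "secretion_sigma",
                     "excursion_sigma", "fi_sigma", "clamp_insulin_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"group {self.label!r}: {name} must be >= 0")


# Presets for a lean young Asian male cohort at the study's group sizes;
# SDs reconstructed as SE×√n at n = 14/21/24. Hyperbola constants come
# from the sensitivity×secretion moment products (14.2×10.5, 8.8×12.3);
# the off-curve group's k is the geometric mean of the two on-curve
# constants with δ chosen to match its own product (12.9×9.1).
_K_CHINESE = 14.2 * 10.5        # 149.1
_K_INDIAN = 8.8 * 12.3          # 108.24
_K_REFERENCE = float(np.sqrt(_K_CHINESE * _K_INDIAN))
_DELTA_MALAY = (12.9 * 9.1) / _K_REFERENCE

PRESETS: dict[str, GroupConfig] = {
    "chinese_like": GroupConfig(
        label="chinese_like", n=14, s_mean=14.2, s_sd=4.49,
        di_constant=_K_CHINESE, compensation_deficit=1.0, iauc_glucose=157.0,
        fg_mean=4.41, fg_sd=0.34, age_mean=29.6, age_sd=6.4,
        bmi_mean=21.5, bmi_sd=1.5, waist_mean=75.8, waist_sd=4.1,
        body_fat_mean=19.4, body_fat_sd=5.2,
    ),
    "malay_like": GroupConfig(
        label="malay_like", n=21, s_mean=12.9, s_sd=5.50,
        di_constant=_K_REFERENCE, compensation_deficit=_DELTA_MALAY,
        iauc_glucose=306.0,
        fg_mean=4.12, fg_sd=0.46, age_mean=25.2, age_sd=3.2,
        bmi_mean=20.9, bmi_sd=1.4, waist_mean=73.9, waist_sd=4.6,
        body_fat_mean=17.5, body_fat_sd=4.6,
    ),
    "indian_like": GroupConfig(
        label="indian_like", n=24, s_mean=8.8, s_sd=2.94,
        di_constant=_K_INDIAN, compensation_deficit=1.0, iauc_glucose=224.6,
        fg_mean=4.12, fg_sd=0.34, age_mean=24.3, age_sd=3.4,
        bmi_mean=21.6, bmi_sd=1.5, waist_mean=78.7, waist_sd=4.4,
        body_fat_mean=20.4, body_fat_sd=4.9,
    ),
}


def study_presets() -> list[GroupConfig]:
    """The three calibrated group presets at the study's n = 14/21/24."""
    return [PRESETS["chinese_like"], PRESETS["malay_like"], PRESETS["indian_like"]]


def null_presets(n_per_group: int = 20, n_groups: int = 3) -> list[GroupConfig]:
    """Identical groups (no group effect) for type-I-error studies."""
    base = GroupConfig(
        label="g", n=n_per_group, s_mean=12.0, s_sd=4.0, di_constant=130.0,
        compensation_deficit=1.0, iauc_glucose=230.0,
    )
    return [replace(base, label=f"g{i + 1}") for i in range(n_groups)]


@dataclass
class SimulatedCohort:
    """A generated cohort plus its per-subject ground truth."""

    cohort: list[CohortSubject]
    ground_truth: pd.DataFrame
    seed: int
    configs: list[GroupConfig] = field(default_factory=list)


def _truncated_normal(rng, mean, sd, low=-np.inf, high=np.inf, max_tries=1000):
    """Resample (never clip) a normal draw into (low, high)."""
    if sd == 0:
        if not (low < mean < high):
            raise ValueError(f"degenerate draw: mean {mean} outside ({low}, {high})")
        return mean
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if low < x < high:
            return x
    raise RuntimeError(f"could not draw N({mean}, {sd}) within ({low}, {high})")


def _lognormal_mean_sd(rng, mean, sd):
    """Lognormal draw parametrised by arithmetic mean and SD."""
    if sd == 0:
        return mean
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def simulate_cohort(
    configs: Sequence[GroupConfig],
    seed: int,
    times: Sequence[float] = CANONICAL_MEAL_GRID,
) -> SimulatedCohort:
    """Generate subjects, meal series and clamp records for each group.

    Deterministic under ``seed``. Ground truth stores S_i, B_i and the
    secretion noise ε_i exactly as drawn, plus the group's k_g and δ_g.
    """
    configs = list(configs)
    if not configs:
        raise ValueError("need at least one GroupConfig")
    labels = [c.label for c in configs]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate group labels: {labels}")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    duration = t[-1] - t[0]
    h_g = excursion_kernel(t)
    h_i = excursion_kernel(t - INSULIN_LAG_MIN)
    H_g = float(np.trapezoid(h_g, t))   # glucose-kernel area on the grid
    H_i = float(np.trapezoid(h_i, t))   # lagged insulin-kernel area

    cohort: list[CohortSubject] = []
    truth_rows = []
    counter = 0
    for cfg in configs:
        dk = cfg.compensation_deficit * cfg.di_constant
        for _ in range(cfg.n):
            counter += 1
            sid = f"S{counter:04d}"
            for _ in range(1000):
                S = _lognormal_mean_sd(rng, cfg.s_mean, cfg.s_sd)
                eps = rng.normal(0.0, cfg.secretion_sigma)
                B = dk / S * np.exp(eps)
                FG = _truncated_normal(rng, cfg.fg_mean, cfg.fg_sd, low=3.6, high=7.0)
                FI = cfg.fi_constant / S * np.exp(
                    rng.normal(0.0, cfg.fi_sigma) - cfg.fi_sigma**2 / 2
                )
                # A ∝ 1/(S·B) within group = exp(-ε)/dk; normalised so the
                # group-mean incremental glucose AUC hits the target.
                eta = rng.normal(0.0, cfg.excursion_sigma)
                A = (cfg.iauc_glucose / H_g) * np.exp(
                    -eps + eta - (cfg.secretion_sigma**2 + cfg.excursion_sigma**2) / 2
                )
                auc_glucose = FG * duration + A * H_g
                beta = (B * auc_glucose - FI * duration) / H_i
                if beta > 0 and FI > 0:
                    break
            else:
                raise RuntimeError(f"group {cfg.label!r}: could not satisfy positivity")

            glucose = FG + A * h_g
            insulin = FI + beta * h_i
            age = _truncated_normal(rng, cfg.age_mean, cfg.age_sd, low=18.0)
            bmi = _truncated_normal(rng, cfg.bmi_mean, cfg.bmi_sd, low=16.0, high=23.0)
            waist = _truncated_normal(rng, cfg.waist_mean, cfg.waist_sd, low=50.0)
            pbf = _truncated_normal(rng, cfg.body_fat_mean, cfg.body_fat_sd, low=3.0)
            lbm = _truncated_normal(rng, cfg.lean_mass_mean, cfg.lean_mass_sd, low=30.0)
            i_ss = _truncated_normal(
                rng, cfg.clamp_insulin_mean, cfg.clamp_insulin_sd, low=1.0
            )
            mean_gir = S * i_ss * lbm / CLAMP_SCALE

            subject = SubjectRecord(
                subject_id=sid, group=cfg.label, age=age, bmi=bmi, waist=waist,
                percent_body_fat=pbf, lean_body_mass=lbm,
                fasting_glucose=FG, fasting_insulin=FI,
            )
            meal = MealSeries(sid, t, glucose, insulin)
            clamp = ClampSteadyState(
                sid, mean_gir=mean_gir, steady_state_insulin=i_ss, lean_body_mass=lbm
            )
            cohort.append(CohortSubject(subject=subject, meal=meal, clamp=clamp))
            truth_rows.append(
                {
                    "subject_id": sid, "group": cfg.label,
                    "S_true": S, "B_true": B, "epsilon": eps,
                    "amplitude": A,
                    "k": cfg.di_constant, "delta": cfg.compensation_deficit,
                }
            )
    return SimulatedCohort(
        cohort=cohort,
        ground_truth=pd.DataFrame(truth_rows),
        seed=seed,
        configs=configs,
    )


def recovery_report(
    panels: pd.DataFrame,
    ground_truth: pd.DataFrame,
    fit_scale: str = "log",
) -> dict:
    """How well the computed indices recover the generator's ground truth.

    Returns Spearman rank correlations between true sensitivity S and
    each sensitivity index (ISI-clamp, ISI-Mat, 1/HOMA-IR), between true
    secretion B and each secretion index, and the per-group relative
    error of the fitted hyperbola constant k̂ against the generating
    δ_g·k_g.
    """
    from scipy.stats import spearmanr

    from .di_hyperbola import fit_hyperbola

    if ground_truth is None or ground_truth.empty:
        raise ValueError("ground truth is required for a recovery report")
    df = panels.merge(ground_truth, on=["subject_id", "group"], validate="1:1")

    def rho(a: str, b: str, invert: bool = False) -> float:
        sub = df[[a, b]].dropna()
        x = sub[a].to_numpy(dtype=float)
        y = sub[b].to_numpy(dtype=float)
        if invert:
            y = 1.0 / y
        return float(spearmanr(x, y).statistic)

    report: dict = {
        "spearman_S": {
            "isi_clamp": rho("S_true", "isi_clamp"),
            "isi_mat": rho("S_true", "isi_mat"),
            "inv_homa_ir": rho("S_true", "homa_ir", invert=True),
        },
        "spearman_B": {
            "insulin_secretion_index": rho("B_true", "insulin_secretion_index"),
            "insulinogenic_index": rho("B_true", "insulinogenic_index"),
        },
        "k_recovery": {},
    }
    for g, grp in df.groupby("group"):
        sub = grp.dropna(subset=["isi_clamp", "insulin_secretion_index"])
        if len(sub) < 3:
            continue
        fit = fit_hyperbola(
            sub["isi_clamp"].to_numpy(), sub["insulin_secretion_index"].to_numpy(),
            scale=fit_scale,
        )
        target = float(grp["delta"].iloc[0] * grp["k"].iloc[0])
        report["k_recovery"][g] = {
            "k_hat": fit.k,
            "target": target,
            "rel_error": fit.k / target - 1.0,
        }
    return report
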