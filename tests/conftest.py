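import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import glycurve as gc

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_sim() -> gc.SimulatedCohort:
    """One simulated cohort at the study's group sizes (14/21/24)."""
    return gc.simulate_cohort(gc.study_presets(), seed=1234)


@pytest.fixture(scope="session")
def study_panels(study_sim) -> pd.DataFrame:
    return gc.panel_frame(study_sim.cohort)


@pytest.fixture(scope="session")
def hundred_seed_group_means() -> pd.DataFrame:
    """Group means of the key indices across 100 simulated cohorts.

    One row per (seed, group); shared by the calibration tests so the
    100 simulations run once per session.
    """
    rows = []
    for seed in range(100):
        sim = gc.simulate_cohort(gc.study_presets(), seed=seed)
        pf = gc.panel_frame(sim.cohort)
        m = pf.groupby("group")[["isi_clamp", "iauc_glucose", "oral_di"]].mean()
        m = m.reset_index()
        m["seed"] = seed
        rows.append(m)
    return pd.concat(rows, ignore_index=True)


def make_meal(sid="S1", glucose=(4.4, 6.5, 7.0, 6.0, 5.0, 4.5),
              insulin=(5.0, 40.0, 55.0, 45.0, 30.0, 8.0)):
    return gc.MealSeries(sid, gc.CANONICAL_MEAL_GRID, glucose, insulin)


def make_subject(sid="S1", group="g1", fg=4.4, fi=5.0, **kw):
    defaults = dict(age=25.0, bmi=21.0, waist=75.0, percent_body_fat=18.0,
                    lean_body_mass=52.0)
    defaults.update(kw)
    return gc.SubjectRecord(subject_id=sid, group=group, fasting_glucose=fg,
                            fasting_insulin=fi, **defaults)


def make_clamp(sid="S1", mean_gir=560.0, ss_insulin=70.0, lbm=56.0):
    return gc.ClampSteadyState(sid, mean_gir=mean_gir,
                               steady_state_insulin=ss_insulin,
                               lean_body_mass=lbm)


@pytest.fixture
def tiny_cohort():
    """Three hand-built subjects with meal and clamp slots filled."""
    cohort = []
    for i, (fg, fi) in enumerate([(4.4, 5.0), (4.1, 6.0), (4.6, 7.5)], start=1):
        sid = f"S{i}"
        cohort.append(
            gc.CohortSubject(
                subject=make_subject(sid, group="g1" if i < 3 else "g2", fg=fg, fi=fi),
                meal=make_meal(sid),
                clamp=make_clamp(sid, mean_gir=500.0 + 30 * i),
            )
        )
    return cohort
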