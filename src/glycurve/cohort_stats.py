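"""Group-comparison statistics for the cohort.

Three layers:

* :func:`ancova_group_test` — one-way comparison of a per-subject outcome
  across groups with an optional numeric covariate (age, in this study's
  design), F test of the group factor, covariate-adjusted group means at
  the grand covariate mean, and Bonferroni pairwise contrasts.
* :func:`rm_anova_interaction` — split-plot (mixed between–within)
  repeated-measures ANOVA of the post-meal excursion matrix, with the
  group×time interaction, Greenhouse–Geisser sphericity correction, and
  per-timepoint pairwise contrasts.
* :func:`bootstrap_group_di` — subject-level percentile bootstrap of a
  per-group mean (disposition-index summaries with uncertainty).

All p-values are two-sided; the 0.05 threshold is a report annotation,
never a filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm


@dataclass
class GroupComparison:
    """One outcome compared across groups, optionally covariate-adjusted."""

    outcome: str
    f_statistic: float
    p_value: float
    df_num: int
    df_den: int
    adjusted_means: dict
    pairwise: pd.DataFrame
    n_per_group: dict
    covariates: tuple


@dataclass
class RmAnovaResult:
    """Split-plot repeated-measures ANOVA with a group×time interaction."""

    time_F: float
    time_p: float
    group_F: float
    group_p: float
    interaction_F: float
    interaction_p: float
    gg_epsilon: float
    time_p_gg: float
    interaction_p_gg: float
    ss: dict
    df: dict
    timepoint_contrasts: pd.DataFrame
    group_F_adjusted: Optional[float] = None
    group_p_adjusted: Optional[float] = None
    covariate: Optional[str] = None


def bonferroni(raw_p: float, n_comparisons: int) -> float:
    """min(1, p × m) — monotone in p, never exceeds 1."""
    return min(1.0, raw_p * n_comparisons)


def ancova_group_test(
    values: Sequence[float],
    groups: Sequence[str],
    covariate: Optional[Sequence[float]] = None,
    outcome_name: str = "outcome",
    covariate_name: str = "age",
) -> GroupComparison:
    """Compare a continuous outcome across groups, adjusting for a covariate.

    Fits the linear model ``y ~ group + covariate`` and tests the group
    factor by a partial F test. Adjusted group means are evaluated at the
    grand covariate mean; pairwise group contrasts use the model's
    standard errors with Bonferroni correction over the number of pairs.
    A constant (or absent) covariate reduces the model exactly to one-way
    ANOVA.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray([str(x) for x in groups])
    if y.shape != g.shape or y.ndim != 1:
        raise ValueError("values and groups must be 1-D of equal length")
    if np.isnan(y).any():
        raise ValueError("values contain NaN; exclude those subjects first")
    levels = sorted(str(x) for x in set(g))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    counts = {lv: int((g == lv).sum()) for lv in levels}
    small = [lv for lv, n in counts.items() if n < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 subjects: {small}")
    if np.ptp(y) == 0:
        raise ValueError("constant outcome: F statistic undefined")

    df = pd.DataFrame({"y": y, "g": pd.Categorical(g, categories=levels)})
    use_cov = False
    if covariate is not None:
        x = np.asarray(covariate, dtype=float)
        if x.shape != y.shape:
            raise ValueError("covariate length mismatch")
        if np.ptp(x) > 0:  # constant covariate would be collinear with intercept
            df["x"] = x
            use_cov = True

    formula = "y ~ C(g) + x" if use_cov else "y ~ C(g)"
    fit = smf.ols(formula, data=df).fit()
    table = anova_lm(fit, typ=2)
    row = table.loc["C(g)"]
    f_stat = float(row["F"])
    p_val = float(row["PR(>F)"])
    df_num = int(row["df"])
    df_den = int(table.loc["Residual", "df"])

    # Adjusted means at the grand covariate mean
    params = fit.params
    ref = levels[0]
    xbar = float(df["x"].mean()) if use_cov else 0.0
    slope = float(params.get("x", 0.0))
    adjusted = {}
    for lv in levels:
        eff = 0.0 if lv == ref else float(params[f"C(g)[T.{lv}]"])
        adjusted[lv] = float(params["Intercept"]) + eff + slope * xbar

    # Pairwise contrasts on the group effects
    pairs = list(combinations(levels, 2))
    names = list(fit.params.index)
    rows = []
    for a, b in pairs:
        vec = np.zeros(len(names))
        if a != ref:
            vec[names.index(f"C(g)[T.{a}]")] = 1.0
        if b != ref:
            vec[names.index(f"C(g)[T.{b}]")] = -1.0
        tt = fit.t_test(vec)
        raw = float(np.squeeze(tt.pvalue))
        rows.append(
            {
                "group1": a,
                "group2": b,
                "estimate": float(np.squeeze(tt.effect)),
                "raw_p": raw,
                "bonferroni_p": bonferroni(raw, len(pairs)),
            }
        )
    return GroupComparison(
        outcome=outcome_name,
        f_statistic=f_stat,
        p_value=p_val,
        df_num=df_num,
        df_den=df_den,
        adjusted_means=adjusted,
        pairwise=pd.DataFrame(rows),
        n_per_group=counts,
        covariates=(covariate_name,) if use_cov else (),
    )


def _gg_epsilon(resid: np.ndarray, df_resid: int) -> float:
    """Greenhouse–Geisser epsilon from pooled within-group residuals."""
    T = resid.shape[1]
    if T < 3:
        return 1.0
    S = resid.T @ resid / df_resid
    C = np.eye(T) - np.ones((T, T)) / T
    A = C @ S @ C
    denom = (T - 1) * np.sum(A * A)
    if denom <= 0:  # zero within-subject variance
        return 1.0
    eps = np.trace(A) ** 2 / denom
    return float(np.clip(eps, 1.0 / (T - 1), 1.0))


def rm_anova_interaction(
    values: np.ndarray,
    groups: Sequence[str],
    covariate: Optional[Sequence[float]] = None,
    times: Optional[Sequence[float]] = None,
    covariate_name: str = "age",
) -> RmAnovaResult:
    """Split-plot ANOVA of a complete subject × timepoint matrix.

    ``values`` has one row per subject, one column per timepoint; every
    cell must be present (subjects with missing cells should be excluded
    beforehand — no imputation). Group is the between-subject factor,
    time the within-subject factor. The sums of squares partition

        SS_total = SS_group + SS_subj(group) + SS_time + SS_group×time + SS_error

    is exact. A numeric covariate, when given, enters the between-subject
    stratum only (ANCOVA on the subject means); the within-subject F
    tests are unchanged by a time-constant covariate, so the adjusted
    group F is reported alongside the unadjusted one. Greenhouse–Geisser
    epsilon (from the pooled within-group covariance) corrects the
    within-stratum degrees of freedom for non-sphericity.

    Per-timepoint pairwise group contrasts use the pooled within-group
    error at that timepoint with Bonferroni correction over pairs only.
    """
    Y = np.asarray(values, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ValueError("values must be a 2-D subject × timepoint matrix, >=2 timepoints")
    if np.isnan(Y).any():
        bad = np.where(np.isnan(Y).any(axis=1))[0]
        raise ValueError(
            f"missing cells for subject rows {bad.tolist()}: exclude these subjects "
            "(no imputation is performed)"
        )
    g = np.asarray([str(x) for x in groups])
    if g.shape[0] != Y.shape[0]:
        raise ValueError("groups length must match number of subject rows")
    levels = sorted(set(g))
    J, (N, T) = len(levels), Y.shape
    if J < 2:
        raise ValueError("need at least 2 groups")
    t_labels = list(times) if times is not None else list(range(T))
    if len(t_labels) != T:
        raise ValueError("times length must match number of columns")

    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    time_means = Y.mean(axis=0)
    group_masks = {lv: g == lv for lv in levels}
    n_j = {lv: int(m.sum()) for lv, m in group_masks.items()}

    ss_total = float(((Y - grand) ** 2).sum())
    ss_between_subj = float(T * ((subj_means - grand) ** 2).sum())
    ss_group = float(T * sum(n_j[lv] * (subj_means[m].mean() - grand) ** 2
                             for lv, m in group_masks.items()))
    ss_subj_within = ss_between_subj - ss_group
    ss_time = float(N * ((time_means - grand) ** 2).sum())
    cell_means = np.vstack([Y[m].mean(axis=0) for m in group_masks.values()])
    ss_cells = float(sum(n_j[lv] * ((cell_means[i] - grand) ** 2).sum()
                         for i, lv in enumerate(levels)))
    ss_inter = ss_cells - ss_group - ss_time
    ss_error = ss_total - ss_between_subj - ss_time - ss_inter

    df_group, df_subj = J - 1, N - J
    df_time, df_inter, df_err = T - 1, (J - 1) * (T - 1), (N - J) * (T - 1)

    ms_group = ss_group / df_group
    ms_subj = ss_subj_within / df_subj
    ms_time = ss_time / df_time
    ms_inter = ss_inter / df_inter
    ms_err = ss_error / df_err

    def _f(ms_num: float, ms_den: float) -> float:
        # a zero-variance stratum (e.g. perfectly flat curves) carries no
        # evidence: report F = 0 rather than 0/0
        if ms_num <= 0:
            return 0.0
        if ms_den <= 0:
            return float("inf")
        return ms_num / ms_den

    F_group = _f(ms_group, ms_subj)
    F_time = _f(ms_time, ms_err)
    F_inter = _f(ms_inter, ms_err)
    p_group = float(sps.f.sf(F_group, df_group, df_subj))
    p_time = float(sps.f.sf(F_time, df_time, df_err))
    p_inter = float(sps.f.sf(F_inter, df_inter, df_err))

    # residuals about the group × time cell means, for the GG epsilon
    resid = Y - np.vstack([cell_means[levels.index(lv)] for lv in g])
    eps = _gg_epsilon(resid, df_subj)
    p_time_gg = float(sps.f.sf(F_time, eps * df_time, eps * df_err))
    p_inter_gg = float(sps.f.sf(F_inter, eps * df_inter, eps * df_err))

    # per-timepoint pairwise contrasts, pooled within-group error per time
    pairs = list(combinations(levels, 2))
    crows = []
    for ti in range(T):
        col = Y[:, ti]
        sse = sum(((col[m] - col[m].mean()) ** 2).sum() for m in group_masks.values())
        mse = sse / (N - J)
        for a, b in pairs:
            diff = col[group_masks[a]].mean() - col[group_masks[b]].mean()
            se = np.sqrt(mse * (1 / n_j[a] + 1 / n_j[b]))
            tstat = diff / se if se > 0 else np.nan
            raw = float(2 * sps.t.sf(abs(tstat), N - J)) if se > 0 else np.nan
            crows.append(
                {
                    "time": t_labels[ti],
                    "group1": a,
                    "group2": b,
                    "estimate": float(diff),
                    "raw_p": raw,
                    "bonferroni_p": bonferroni(raw, len(pairs)) if se > 0 else np.nan,
                }
            )

    result = RmAnovaResult(
        time_F=float(F_time),
        time_p=p_time,
        group_F=float(F_group),
        group_p=p_group,
        interaction_F=float(F_inter),
        interaction_p=p_inter,
        gg_epsilon=eps,
        time_p_gg=p_time_gg,
        interaction_p_gg=p_inter_gg,
        ss={
            "group": ss_group,
            "subjects_within_groups": ss_subj_within,
            "time": ss_time,
            "interaction": ss_inter,
            "error": ss_error,
            "total": ss_total,
        },
        df={
            "group": df_group,
            "subjects_within_groups": df_subj,
            "time": df_time,
            "interaction": df_inter,
            "error": df_err,
        },
        timepoint_contrasts=pd.DataFrame(crows),
    )

    if covariate is not None:
        comp = ancova_group_test(
            subj_means, g, covariate, outcome_name="subject_mean",
            covariate_name=covariate_name,
        )
        result.group_F_adjusted = comp.f_statistic
        result.group_p_adjusted = comp.p_value
        result.covariate = covariate_name
    return result


def bootstrap_group_di(
    panels: pd.DataFrame,
    value_col: str = "oral_di",
    group_col: str = "group",
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Percentile bootstrap CI of each group's mean disposition index.

    Resamples subjects within group with replacement; reproducible under
    ``seed``. Returns a frame with group, n, mean, ci_low, ci_high. A
    group of size 1 gets NaN bounds and a warning.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for a stable percentile CI")
    rng = np.random.default_rng(seed)
    alpha = (1 - ci_level) / 2
    rows = []
    for lv, grp in panels.dropna(subset=[value_col]).groupby(group_col, sort=True):
        x = grp[value_col].to_numpy(dtype=float)
        n = x.size
        if n < 2:
            import warnings

            warnings.warn(f"group {lv!r} has {n} subject(s); CI undefined")
            lo = hi = np.nan
        else:
            idx = rng.integers(0, n, size=(n_boot, n))
            means = x[idx].mean(axis=1)
            lo, hi = np.quantile(means, [alpha, 1 - alpha])
        rows.append(
            {"group": lv, "n": n, "mean": float(x.mean()),
             "ci_low": float(lo), "ci_high": float(hi)}
        )
    return pd.DataFrame(rows)
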