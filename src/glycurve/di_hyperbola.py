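"""Hyperbolic secretion–sensitivity curve and "falling off the curve".

Appropriate beta-cell compensation means the secretion index B and the
sensitivity index S of healthy subjects trace a constant-product
hyperbola B = k/S. The module fits k across subjects and scores each
subject (or group) by the log-compensation residual
r = log(S·B) − log k: r = 0 on the curve, r < 0 below it
(under-compensation, "falling off the DI curve").

Two losses are available. The default log-scale fit is the least-squares
solution of log B = log k − log S, whose closed form is the geometric
mean of the products S_i·B_i — appropriate for multiplicative
physiologic noise and exactly equivariant under rescaling of either
axis. The linear-scale fit minimises Σ(B_i − k/S_i)² with closed form
k = Σ(B_i/S_i) / Σ(1/S_i²). The hyperbola exponent is fixed at −1; no
free-exponent power law is fitted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FIT_SCALES = ("log", "linear")


@dataclass
class DICurveFit:
    """A fitted constant-product hyperbola B = k/S.

    ``residuals`` are per-subject log-compensation scores
    log(S_i·B_i) − log k; on the log scale they average to zero by
    construction of the estimator.
    """

    k: float
    fit_scale: str
    residuals: np.ndarray
    group_points: pd.DataFrame = field(default_factory=pd.DataFrame)

    def predict_secretion(self, sensitivity: np.ndarray) -> np.ndarray:
        """Secretion on the fitted curve at the given sensitivity values."""
        return self.k / np.asarray(sensitivity, dtype=float)


def _validated_pairs(sensitivity, secretion) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(sensitivity, dtype=float)
    b = np.asarray(secretion, dtype=float)
    if s.shape != b.shape or s.ndim != 1:
        raise ValueError("sensitivity and secretion must be 1-D arrays of equal length")
    if s.size < 3:
        raise ValueError(f"need at least 3 pairs to fit, got {s.size}")
    if np.any(s <= 0) or np.any(b <= 0) or not (np.isfinite(s).all() and np.isfinite(b).all()):
        raise ValueError("all sensitivity/secretion pairs must be positive and finite")
    return s, b


def fit_hyperbola(sensitivity, secretion, scale: str = "log") -> DICurveFit:
    """Fit B = k/S across subjects by least squares on the chosen scale."""
    s, b = _validated_pairs(sensitivity, secretion)
    if scale == "log":
        k = float(np.exp(np.mean(np.log(s * b))))
    elif scale == "linear":
        k = float(np.sum(b / s) / np.sum(1.0 / s**2))
    else:
        raise ValueError(f"scale must be one of {FIT_SCALES}, got {scale!r}")
    residuals = np.log(s * b) - math.log(k)
    return DICurveFit(k=k, fit_scale=scale, residuals=residuals)


def off_curve_score(sensitivity: float, secretion: float, fit: DICurveFit) -> float:
    """Log-compensation score r = log(S·B) − log k for one point.

    Negative values lie below the fitted hyperbola (beta-cell response
    lower than the prevailing sensitivity warrants); zero is on-curve.
    """
    if not (sensitivity > 0 and secretion > 0):
        raise ValueError("sensitivity and secretion must be positive")
    if not fit.k > 0:
        raise ValueError("invalid fit: k must be positive")
    return math.log(sensitivity * secretion) - math.log(fit.k)


def group_curve_placement(
    panels: pd.DataFrame,
    sensitivity_col: str = "isi_clamp",
    secretion_col: str = "insulin_secretion_index",
    group_col: str = "group",
    scale: str = "log",
) -> DICurveFit:
    """Fit the cohort hyperbola and place each group's mean on/off it.

    ``panels`` is a tidy per-subject frame (e.g. from
    :func:`glycurve.indices.panel_frame`). Subjects missing either axis
    are dropped; groups left empty are omitted with a warning. The
    returned fit's ``group_points`` holds, per group, the arithmetic mean
    (S̄, B̄) coordinates, the mean per-subject off-curve score, and n —
    sorted ascending by mean score, so the worst-compensating group comes
    first.
    """
    df = panels[[group_col, sensitivity_col, secretion_col]].dropna()
    empty = set(panels[group_col].unique()) - set(df[group_col].unique())
    for g in sorted(empty):
        logger.warning("group %s has no complete (S, B) pairs; omitted", g)
    fit = fit_hyperbola(df[sensitivity_col].to_numpy(), df[secretion_col].to_numpy(), scale)
    scores = np.log(
        df[sensitivity_col].to_numpy() * df[secretion_col].to_numpy()
    ) - math.log(fit.k)
    df = df.assign(_score=scores)
    gp = (
        df.groupby(group_col)
        .agg(
            mean_sensitivity=(sensitivity_col, "mean"),
            mean_secretion=(secretion_col, "mean"),
            mean_off_curve_score=("_score", "mean"),
            n=("_score", "size"),
        )
        .sort_values("mean_off_curve_score")
        .reset_index()
    )
    fit.group_points = gp
    return fit
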