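"""Total and incremental area under the curve by the trapezoidal rule.

The incremental AUC (IAUC) measures the excursion above the fasting
baseline (the value at t=0). Two conventions are supported:

``net``
    total AUC minus the baseline rectangle, ``AUC - v0*(t_last - t0)``.
    Dips below baseline subtract area; the result can be negative.
``positive_only``
    trapezoidal area of ``max(v - v0, 0)`` with exact linear
    interpolation of the baseline crossings (the Wolever-style cut-off);
    never negative and never smaller than the net value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CONVENTIONS = ("net", "positive_only")


@dataclass(frozen=True)
class AucResult:
    """Total and incremental AUC for one series, with its convention."""

    total_auc: float
    incremental_auc: float
    baseline: float
    duration: float
    convention: str


def _validated(times, values) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("need at least 2 timepoints")
    if v.shape != t.shape:
        raise ValueError("times and values must have the same length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return t, v


def total_auc(times, values) -> float:
    """Trapezoidal total area under the sampled curve."""
    t, v = _validated(times, values)
    return float(np.trapezoid(v, t))


def incremental_auc(times, values, convention: str = "net") -> float:
    """Area above the t=0 baseline, by the chosen convention."""
    t, v = _validated(times, values)
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}, got {convention!r}")
    baseline = v[0]
    if convention == "net":
        return float(np.trapezoid(v, t) - baseline * (t[-1] - t[0]))
    # positive_only: integrate max(v - baseline, 0) segment by segment,
    # splitting segments at the exact baseline crossing.
    d = v - baseline
    area = 0.0
    for i in range(t.size - 1):
        dt = t[i + 1] - t[i]
        a, b = d[i], d[i + 1]
        if a >= 0 and b >= 0:
            area += dt * (a + b) / 2.0
        elif a <= 0 and b <= 0:
            continue
        else:
            # one endpoint above, one below: triangle on the positive side
            pos = a if a > 0 else b
            frac = pos / (abs(a) + abs(b))
            area += 0.5 * pos * frac * dt
    return float(area)


def auc_result(times, values, convention: str = "net") -> AucResult:
    """Bundle total and incremental AUC for one series."""
    t, v = _validated(times, values)
    return AucResult(
        total_auc=total_auc(t, v),
        incremental_auc=incremental_auc(t, v, convention),
        baseline=float(v[0]),
        duration=float(t[-1] - t[0]),
        convention=convention,
    )
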