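"""Unit conversions at the I/O boundary.

All internal computation uses mmol/l for glucose and mU/l for insulin;
conversion to and from the clinical alternatives happens only here.
The glucose factor is fixed at 18.0 mg/dl per mmol/l so that the common
clinical equivalence 90 mg/dl = 5 mmol/l holds exactly (the molar-mass
value 18.016 would not). The insulin factor 6.0 pmol/l per mU/l is the
usual clinical convention; both are module constants and can be overridden
per call for assays calibrated differently.
"""

from __future__ import annotations

GLUCOSE_MGDL_PER_MMOLL: float = 18.0
INSULIN_PMOLL_PER_MUL: float = 6.0

_GLUCOSE_UNITS = ("mg/dl", "mmol/l")
_INSULIN_UNITS = ("pmol/l", "mU/l")


class UnknownUnitError(ValueError):
    """Raised for a unit string outside the supported set."""

    def __init__(self, unit: str, allowed: tuple[str, ...]):
        super().__init__(f"unknown unit {unit!r}; expected one of {allowed}")
        self.unit = unit


def _normalize(unit: str) -> str:
    return unit.strip().lower().replace("μ", "u")


def convert_glucose(
    value: float,
    from_unit: str,
    to_unit: str,
    factor: float = GLUCOSE_MGDL_PER_MMOLL,
) -> float:
    """Convert a glucose concentration between mg/dl and mmol/l.

    Parameters
    ----------
    value : non-negative concentration.
    from_unit, to_unit : ``"mg/dl"`` or ``"mmol/l"`` (case-insensitive).
    factor : mg/dl per mmol/l, default 18.0.
    """
    fu, tu = _normalize(from_unit), _normalize(to_unit)
    for u, raw in ((fu, from_unit), (tu, to_unit)):
        if u not in _GLUCOSE_UNITS:
            raise UnknownUnitError(raw, _GLUCOSE_UNITS)
    if value < 0:
        raise ValueError(f"concentration must be >= 0, got {value}")
    if fu == tu:
        return value
    return value * factor if tu == "mg/dl" else value / factor


def convert_insulin(
    value: float,
    from_unit: str,
    to_unit: str,
    factor: float = INSULIN_PMOLL_PER_MUL,
) -> float:
    """Convert an insulin concentration between pmol/l and mU/l.

    ``factor`` is pmol/l per mU/l, default 6.0.
    """
    fu = _normalize(from_unit).replace("mu/l", "mU/l")
    tu = _normalize(to_unit).replace("mu/l", "mU/l")
    for u, raw in ((fu, from_unit), (tu, to_unit)):
        if u not in _INSULIN_UNITS:
            raise UnknownUnitError(raw, _INSULIN_UNITS)
    if value < 0:
        raise ValueError(f"concentration must be >= 0, got {value}")
    if fu == tu:
        return value
    return value * factor if tu == "pmol/l" else value / factor
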