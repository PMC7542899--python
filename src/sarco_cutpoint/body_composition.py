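"""Estimated lean body mass (LBM) and lean mass index (LMI) from anthropometry.

LBM for dialysis patients is estimated from sex, height, weight, handgrip
strength (HGS) and dialysis vintage with a published linear equation::

    LBM (kg) = 4.72*[male] + 0.28*height_cm + 0.27*weight_kg
               + 0.02*HGS_N - 0.04*duration_months - 26.84

The equation takes grip strength in Newtons while dynamometers report kg of
force, so the kg reading is multiplied by standard gravity (9.80665 N/kg)
exactly once.  LMI is LBM divided by height squared (kg/m^2), the muscle-mass
analogue of BMI.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "STANDARD_GRAVITY",
    "AnthropometryInput",
    "LBMCoefficients",
    "estimate_lbm",
    "compute_lmi",
    "baseline_average",
]

#: Standard gravity, N per kg of force reading; converts dynamometer kg to N.
STANDARD_GRAVITY = 9.80665


@dataclass(frozen=True)
class AnthropometryInput:
    """Raw anthropometry for one patient.

    Parameters
    ----------
    male : bool
        True for male, False for female.
    height : float
        Standing height in cm; must be positive.
    weight : float
        Body weight in kg; must be positive.
    hgs : float
        Handgrip strength as the dynamometer kg reading; non-negative.
    dialysis_duration : float
        Time on dialysis in months; non-negative.
    """

    male: bool
    height: float
    weight: float
    hgs: float
    dialysis_duration: float = 0.0

    def __post_init__(self) -> None:
        if not self.height > 0:
            raise ValueError(f"height must be positive, got {self.height}")
        if not self.weight > 0:
            raise ValueError(f"weight must be positive, got {self.weight}")
        if self.hgs < 0:
            raise ValueError(f"hgs must be non-negative, got {self.hgs}")
        if self.dialysis_duration < 0:
            raise ValueError(
                f"dialysis_duration must be non-negative, got {self.dialysis_duration}"
            )


@dataclass(frozen=True)
class LBMCoefficients:
    """Fixed coefficients of the LBM estimating equation (all in kg-scale units)."""

    male_offset: float = 4.72
    height_coef: float = 0.28
    weight_coef: float = 0.27
    hgs_coef: float = 0.02
    duration_coef: float = 0.04
    intercept: float = 26.84
    gravity: float = STANDARD_GRAVITY


def estimate_lbm(
    a: AnthropometryInput, c: LBMCoefficients = LBMCoefficients()
) -> float:
    """Estimated lean body mass in kg.

    The grip-strength term converts the kg reading to Newtons via ``c.gravity``
    before applying ``c.hgs_coef``.  The equation is linear and unbounded; a
    negative result is arithmetically possible for extreme inputs and is
    returned as-is with a warning.
    """
    lbm = (
        c.male_offset * (1.0 if a.male else 0.0)
        + c.height_coef * a.height
        + c.weight_coef * a.weight
        + c.hgs_coef * (a.hgs * c.gravity)
        - c.duration_coef * a.dialysis_duration
        - c.intercept
    )
    if lbm < 0:
        warnings.warn(
            f"estimated LBM is negative ({lbm:.2f} kg); inputs are outside the "
            "range the equation was developed on",
            stacklevel=2,
        )
    return lbm


def compute_lmi(lbm: float, height: float) -> float:
    """Lean mass index in kg/m^2: LBM divided by height (cm) squared in metres."""
    if not height > 0:
        raise ValueError(f"height must be positive, got {height}")
    return lbm / (height / 100.0) ** 2


def baseline_average(
    measurements: list[tuple[float, float]], window: float = 3.0
) -> float:
    """Mean of the (time, value) measurements taken at time <= ``window`` months.

    Baseline exposure values are averages over an initial window (3 months by
    default); later measurements are ignored.  Returns NaN when no measurement
    falls inside the window.
    """
    if not window > 0:
        raise ValueError(f"window must be positive, got {window}")
    in_window = [v for t, v in measurements if t <= window]
    if not in_window:
        return math.nan
    return sum(in_window) / len(in_window)
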