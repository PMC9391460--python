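"""PAMPA permeability calibration and classification.

Membrane-permeation simulations yield a dimensionless log-permeability
score per compound; a linear calibration against experimental PAMPA
log10(P_eff / P0) values (P0 = 1 cm/s) converts new scores into effective
permeabilities.  The calibration is an ordinary least-squares line on a
reference compound set (nine compounds in the canonical design); a
prediction's uncertainty combines the calibration residual scatter with
the propagated score uncertainty in quadrature.

Permeability classes follow the PAMPA banding convention:
low (< 0.7e-6 cm/s), low-to-medium [0.7e-6, 2.1e-6], medium
(2.1e-6, 4.7e-6], high (> 4.7e-6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .equilibria import UncertainValue

__all__ = ["CalibrationPoint", "CalibrationModel", "PermeabilityCalibration",
           "fit_calibration", "predict_log_peff", "log_to_peff",
           "classify_permeability", "PERMEABILITY_BANDS"]

#: class bands in cm/s: (upper bound, label); upper edges inclusive
PERMEABILITY_BANDS = [
    (0.7e-6, "low"),
    (2.1e-6, "low-to-medium"),
    (4.7e-6, "medium"),
    (math.inf, "high"),
]


@dataclass(frozen=True)
class CalibrationPoint:
    """One reference compound: computed score vs experimental log10(Peff/P0)."""

    compound: str
    x_computed: float
    y_experimental: float

    def __post_init__(self):
        if not (math.isfinite(self.x_computed) and
                math.isfinite(self.y_experimental)):
            raise ValueError("calibration values must be finite")


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted linear map y = slope*x + intercept with residual scatter."""

    slope: float
    intercept: float
    residual_sd: float
    n_points: int

    def summary(self) -> str:
        return (f"permeability calibration (n = {self.n_points}): "
                f"log10(Peff/P0) = {self.slope:.4g} * x + {self.intercept:.4g}"
                f"  (residual sd {self.residual_sd:.3g})")


class PermeabilityCalibration:
    """OLS calibration of computed log-permeability scores."""

    def __init__(self, points: Sequence[CalibrationPoint]):
        if len(points) < 3:
            raise ValueError("need at least 3 calibration points")
        self.points = list(points)

    def fit(self) -> CalibrationModel:
        x = np.array([p.x_computed for p in self.points])
        y = np.array([p.y_experimental for p in self.points])
        if np.ptp(x) == 0:
            raise ValueError("degenerate calibration: zero variance in x")
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        dof = max(len(x) - 2, 1)
        return CalibrationModel(slope=float(slope), intercept=float(intercept),
                                residual_sd=float(np.sqrt(resid @ resid / dof)),
                                n_points=len(x))


def fit_calibration(points: Sequence[CalibrationPoint]) -> CalibrationModel:
    return PermeabilityCalibration(points).fit()


def predict_log_peff(model: CalibrationModel, x: float,
                     x_sd: float | None = None) -> UncertainValue:
    """Predicted log10(Peff/P0) with combined uncertainty.

    sd = sqrt(residual_sd^2 + (slope * x_sd)^2); with no score uncertainty
    the residual scatter alone is reported.
    """
    value = model.slope * x + model.intercept
    var = model.residual_sd ** 2
    if x_sd is not None:
        var += (model.slope * x_sd) ** 2
    return UncertainValue(value=float(value), sd=float(math.sqrt(var)))


def log_to_peff(log10_value: float) -> float:
    """Effective permeability in cm/s from log10(Peff / 1 cm s^-1)."""
    if not math.isfinite(log10_value):
        raise ValueError("log10 permeability must be finite")
    return 10.0 ** log10_value


def classify_permeability(p_eff: float) -> str:
    """Permeability class label for an effective permeability in cm/s."""
    if p_eff < 0:
        raise ValueError("p_eff must be >= 0")
    if p_eff < PERMEABILITY_BANDS[0][0]:
        return PERMEABILITY_BANDS[0][1]
    for upper, label in PERMEABILITY_BANDS[1:]:
        if p_eff <= upper:
            return label
    raise AssertionError("unreachable")  # pragma: no cover
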