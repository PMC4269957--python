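"""Pneumatic impactor calibration: air pressure -> piston velocity/energy.

The impactor is calibrated by firing the piston at a series of air
pressures and measuring its exit velocity (three replicates per pressure);
a 2nd-order polynomial is least-squares fitted to the replicate points in
the velocity domain.  Impact energy at any pressure follows from
``E = 0.5 * m_piston * v(p)^2``, and the pressure required for a target
energy is obtained by inverting the fitted curve within the calibrated
range (extrapolation is refused).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["CalibrationCurve", "fit_calibration", "required_pressure"]


@dataclass(frozen=True)
class CalibrationCurve:
    """Quadratic pressure (psi) -> piston exit velocity (m/s) fit."""

    coefficients: tuple[float, float, float]  # highest power first
    piston_mass: float  # kg
    r_squared: float
    n_points: int
    pressure_range: tuple[float, float]

    def predict_velocity(self, pressure) -> np.ndarray | float:
        return np.polyval(self.coefficients, pressure)

    def predict_energy(self, pressure) -> np.ndarray | float:
        """Impact energy E = 0.5 * m * v(p)^2 (J)."""
        v = np.polyval(self.coefficients, pressure)
        return 0.5 * self.piston_mass * np.square(v)

    @property
    def energy_range(self) -> tuple[float, float]:
        lo, hi = self.pressure_range
        return (float(self.predict_energy(lo)), float(self.predict_energy(hi)))


def fit_calibration(table: pd.DataFrame, piston_mass: float) -> CalibrationCurve:
    """Least-squares quadratic fit of exit velocity against air pressure.

    ``table`` needs columns ``pressure_psi`` and ``velocity_m_s``;
    replicates enter the fit individually.  ``r_squared`` is the ordinary
    coefficient of determination on the same points.  Requires at least
    three distinct pressures (a quadratic is underdetermined otherwise).
    """
    if piston_mass <= 0:
        raise ValueError("piston mass must be positive")
    p = np.asarray(table["pressure_psi"], dtype=float)
    v = np.asarray(table["velocity_m_s"], dtype=float)
    if np.unique(p).size < 3:
        raise ValueError("need at least 3 distinct pressures for a quadratic fit")
    coeffs = np.polyfit(p, v, deg=2)
    resid = v - np.polyval(coeffs, p)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationCurve(
        coefficients=tuple(float(c) for c in coeffs),
        piston_mass=float(piston_mass),
        r_squared=float(r2),
        n_points=int(p.size),
        pressure_range=(float(p.min()), float(p.max())),
    )


def required_pressure(curve: CalibrationCurve, target_energy: float) -> float:
    """Air pressure whose predicted impact energy equals ``target_energy``.

    Solves ``0.5 * m * v(p)^2 = E`` for ``p`` by root-finding on the fitted
    curve, restricted to the calibrated pressure interval; targets whose
    energy falls outside the calibrated range raise (extrapolation
    refused).
    """
    if target_energy <= 0:
        raise ValueError("target energy must be positive")
    lo, hi = curve.pressure_range
    e_lo, e_hi = curve.energy_range
    e_min, e_max = min(e_lo, e_hi), max(e_lo, e_hi)
    if not e_min <= target_energy <= e_max:
        raise ValueError(
            f"target energy {target_energy:.4g} J outside the calibrated range "
            f"[{e_min:.4g}, {e_max:.4g}] J; extrapolation refused"
        )
    v_target = float(np.sqrt(2.0 * target_energy / curve.piston_mass))

    def residual(p: float) -> float:
        return float(curve.predict_velocity(p)) - v_target

    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo == 0.0:
        return lo
    if r_hi == 0.0:
        return hi
    if r_lo * r_hi > 0:
        raise ValueError(
            "fitted curve is not monotone across the calibrated range for "
            "this target; cannot invert uniquely"
        )
    return float(optimize.brentq(residual, lo, hi))
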