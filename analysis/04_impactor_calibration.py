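"""Calibrate the pneumatic impactor: air pressure -> piston velocity/energy.

Generates a synthetic calibration table over the study's eight pressures
(0.5-10 psi, three replicate shots each) with small velocity measurement
noise, fits the 2nd-order polynomial in the velocity domain, and inverts
the curve for the pressure delivering the 0.5 J input energy used for the
mouse impacts (50 g piston).

Writes results/calibration_curve.json and results/calibration_lookup.csv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from impactkit.calibration import fit_calibration, required_pressure
from impactkit.synthio import gen_calibration_table

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

PISTON_MASS_KG = 0.050
TARGET_ENERGY_J = 0.5
NOISE_SD = 0.02  # m/s, velocity-tracking repeatability at 10,000 frames/s


def main(seed: int = 0) -> None:
    table = gen_calibration_table(noise_sd=NOISE_SD, seed=seed)
    curve = fit_calibration(table, piston_mass=PISTON_MASS_KG)
    p_half_joule = required_pressure(curve, TARGET_ENERGY_J)

    pressures = np.linspace(*curve.pressure_range, 39)
    lookup = pd.DataFrame(
        {
            "pressure_psi": pressures,
            "velocity_m_s": curve.predict_velocity(pressures),
            "energy_J": curve.predict_energy(pressures),
        }
    )
    RESULTS.mkdir(exist_ok=True)
    lookup.to_csv(RESULTS / "calibration_lookup.csv", index=False)
    out = {
        "coefficients_v_of_p": list(curve.coefficients),
        "r_squared": curve.r_squared,
        "n_points": curve.n_points,
        "pressure_range_psi": list(curve.pressure_range),
        "energy_range_J": list(curve.energy_range),
        "pressure_for_0.5_J_psi": p_half_joule,
    }
    (RESULTS / "calibration_curve.json").write_text(json.dumps(out, indent=2))

    print(f"fit over {curve.n_points} replicate shots: r^2 = {curve.r_squared:.4f}")
    print("v(p) = {:.4f} p^2 + {:.4f} p + {:.4f}  (m/s, p in psi)".format(*curve.coefficients))
    print(f"usable energy range: {curve.energy_range[0]:.3f} - {curve.energy_range[1]:.3f} J")
    print(f"pressure for the {TARGET_ENERGY_J} J impact: {p_half_joule:.2f} psi "
          f"(piston {PISTON_MASS_KG*1e3:.0f} g, v = {float(curve.predict_velocity(p_half_joule)):.3f} m/s)")


if __name__ == "__main__":
    main()
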