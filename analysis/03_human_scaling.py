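"""Scale the mouse peak kinematics to human-equivalent values.

Equal-stress/equal-velocity scaling with lambda = (human brain mass /
mouse brain mass)^(1/3) = 13.8: velocity is species-invariant, lengths and
times scale up by lambda, linear acceleration and angular velocity down by
lambda, angular acceleration down by lambda^2.

Reads results/peak_table.json (from 02), writes results/human_equivalent.csv.
"""

import json
from pathlib import Path

import pandas as pd

from impactkit.kinematics import GRAVITY, Peak, PeakTable
from impactkit.scaling import MOUSE_TO_HUMAN, scale_kinematics

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

REPORT = {
    "displacement": ("displacement (mm)", 1e3),
    "deflection": ("deflection (rad)", 1.0),
    "linear_velocity": ("linear velocity (m/s)", 1.0),
    "linear_acceleration": ("linear acceleration (g)", 1.0 / GRAVITY),
    "angular_velocity": ("angular velocity (rad/s)", 1.0),
    "angular_acceleration": ("angular acceleration (krad/s^2)", 1e-3),
}


def main() -> None:
    data = json.loads((RESULTS / "peak_table.json").read_text())
    table = PeakTable(
        peaks={q: Peak(v["value"], v["time"]) for q, v in data["peaks"].items()},
        delta_v=data["delta_v"],
        cv=data["cv"],
    )
    human = scale_kinematics(table, MOUSE_TO_HUMAN)
    rows = []
    for q, (label, mult) in REPORT.items():
        rows.append(
            {
                "quantity": label,
                "mouse": table[q].value * mult,
                "human_equivalent": human[q].value * mult,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "human_equivalent.csv", index=False)
    print(f"lambda = {MOUSE_TO_HUMAN.lambda_} ({MOUSE_TO_HUMAN.source_species} -> "
          f"{MOUSE_TO_HUMAN.target_species})")
    print(df.to_string(index=False, float_format=lambda v: f"{v:0.3f}"))
    print(f"\ndelta-V is invariant: {human.delta_v:.2f} m/s in both species")


if __name__ == "__main__":
    main()
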