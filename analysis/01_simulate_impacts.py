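"""Simulate the kinematics cohort: 8 mice, 2 impacts each, 24 h apart.

Each impact is a synthetic two-marker head trajectory at 5,000 frames/s
whose underlying motion satisfies the measured peak-kinematics constraints
(49.6 mm, 2.6 rad, 6.6 m/s, 385.3 g, 305.8 rad/s, 253.6 krad/s^2 at their
measured times), plus 0.05 mm Gaussian tracking jitter per marker per
frame.  Tracks are written as CSV to scratch/tracks/ (large, regenerable);
downstream scripts consume them from there.
"""

from dataclasses import replace
from pathlib import Path

from impactkit import io
from impactkit.synthio import DEFAULT_NOISE_SD, MOUSE_IMPACT_PEAKS, gen_impact_trajectory

N_ANIMALS = 8
N_IMPACTS = 2
OUT = Path(__file__).resolve().parents[1] / "scratch" / "tracks"


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = replace(MOUSE_IMPACT_PEAKS, noise_sd=DEFAULT_NOISE_SD)
    n = 0
    for animal in range(1, N_ANIMALS + 1):
        for impact in range(1, N_IMPACTS + 1):
            track = gen_impact_trajectory(
                spec,
                seed=seed + 100 * animal + impact,
                animal_id=f"mouse{animal:02d}",
                impact_index=impact,
            )
            io.write_track(track, OUT / f"mouse{animal:02d}_impact{impact}.csv")
            n += 1
    print(f"wrote {n} impact tracks ({N_ANIMALS} animals x {N_IMPACTS} impacts) to {OUT}")
    print(f"frame rate {spec.frame_rate:.0f} frames/s, {spec.duration*1e3:.0f} ms per track, "
          f"tracking noise sd {spec.noise_sd*1e3:.2f} mm")


if __name__ == "__main__":
    main()
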