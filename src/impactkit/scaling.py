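"""Interspecies kinematic scaling (equal-stress / equal-velocity law).

Rodent head kinematics are converted to human-equivalent values with a
single length-scale ratio ``lambda = (target brain mass / source brain
mass)^(1/3)``.  Under equal stress / equal velocity, velocity is invariant
across species while lengths and times scale by ``lambda``, linear and
angular accelerations by ``1/lambda``, angular velocity by ``1/lambda``,
and angular acceleration by ``1/lambda^2``.  The mouse->human factor is
13.8.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .kinematics import Peak, PeakTable

__all__ = ["ScalingFactor", "MOUSE_TO_HUMAN", "scale_kinematics"]


@dataclass(frozen=True)
class ScalingFactor:
    """Dimensionless length-scale ratio between two species."""

    lambda_: float
    source_species: str = "mouse"
    target_species: str = "human"

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError("lambda must be positive")

    @classmethod
    def from_brain_masses(
        cls, source_mass: float, target_mass: float, source="source", target="target"
    ) -> "ScalingFactor":
        """lambda = (target brain mass / source brain mass)^(1/3)."""
        if source_mass <= 0 or target_mass <= 0:
            raise ValueError("brain masses must be positive")
        return cls(
            lambda_=(target_mass / source_mass) ** (1.0 / 3.0),
            source_species=source,
            target_species=target,
        )

    @property
    def inverse(self) -> "ScalingFactor":
        return ScalingFactor(
            lambda_=1.0 / self.lambda_,
            source_species=self.target_species,
            target_species=self.source_species,
        )


#: mouse -> human length-scale ratio, (human brain mass / mouse brain mass)^(1/3)
MOUSE_TO_HUMAN = ScalingFactor(lambda_=13.8, source_species="mouse", target_species="human")

# per-quantity exponent e of lambda: scaled value = value * lambda**e
_VALUE_EXPONENTS = {
    "displacement": 1,  # length ~ lambda
    "deflection": 0,  # angle is dimensionless
    "linear_velocity": 0,  # velocity does not scale
    "linear_acceleration": -1,  # L/T^2 ~ lambda / lambda^2
    "angular_velocity": -1,  # 1/T
    "angular_acceleration": -2,  # 1/T^2
}


def scale_kinematics(
    peaks: PeakTable, factor: ScalingFactor, force: bool = False
) -> PeakTable:
    """Convert a peak table to target-species-equivalent values.

    Velocity (peak and ``delta_v``) is unchanged, lengths and times scale
    by ``lambda``, linear acceleration and angular velocity by
    ``1/lambda``, and angular acceleration by ``1/lambda^2``.  The
    returned table is flagged ``scaled``; scaling an already-scaled table
    is refused unless ``force`` is given (e.g. to undo a scaling with the
    inverse factor).
    """
    if peaks.scaled and not force:
        raise ValueError("peak table is already scaled; refusing to scale twice")
    lam = factor.lambda_
    scaled = {
        q: Peak(value=p.value * lam ** _VALUE_EXPONENTS[q], time=p.time * lam)
        for q, p in peaks.peaks.items()
    }
    return replace(peaks, peaks=scaled, delta_v=peaks.delta_v, scaled=True)
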