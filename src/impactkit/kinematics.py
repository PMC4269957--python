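"""Head kinematics from two-marker high-speed-video tracks.

A closed-head impact is recorded at several thousand frames per second with
two markers fixed to the head: a paint mark on the cheek (marker 1, used for
linear kinematics) and a dental-floss mark on the snout (marker 2).  The
marker coordinates are low-pass filtered, differentiated to velocities and
accelerations, and summarized as per-impact peak values, a change in head
velocity ``dV``, repeatability statistics, and the kinetic energy transferred
to the head.

Internal units are SI throughout (m, s, rad); conversion to the customary
reporting units (mm, ms, g, krad/s^2) is left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "MarkerTrack",
    "KinematicSeries",
    "Peak",
    "PeakTable",
    "EnergyResult",
    "QUANTITIES",
    "GRAVITY",
    "filter_track",
    "derive_kinematics",
    "detect_onset",
    "summarize_peaks",
    "impact_energy",
]

#: standard gravity used to express linear acceleration in g
GRAVITY = 9.81

#: the six kinematic quantities summarized per impact
QUANTITIES = (
    "displacement",
    "deflection",
    "linear_velocity",
    "linear_acceleration",
    "angular_velocity",
    "angular_acceleration",
)

_TIME_STEP_TOL = 1e-9
_MIN_FRAMES = 50


@dataclass
class MarkerTrack:
    """Two-marker head trajectory for a single impact.

    ``marker1`` is the cheek paint mark (linear kinematics), ``marker2`` the
    snout floss mark; both are ``(n, 2)`` arrays of X (caudal->rostral) and
    Y (up) coordinates in meters, sampled uniformly at ``frame_rate``.
    """

    time: np.ndarray
    marker1: np.ndarray
    marker2: np.ndarray
    frame_rate: float
    animal_id: str = "animal"
    impact_index: int = 1

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.marker1 = np.asarray(self.marker1, dtype=float)
        self.marker2 = np.asarray(self.marker2, dtype=float)
        n = self.time.size
        if n < _MIN_FRAMES:
            raise ValueError(f"track must have >= {_MIN_FRAMES} frames, got {n}")
        if self.marker1.shape != (n, 2) or self.marker2.shape != (n, 2):
            raise ValueError("marker arrays must have shape (n_frames, 2)")
        if not (np.isfinite(self.marker1).all() and np.isfinite(self.marker2).all()):
            raise ValueError("marker coordinates must be finite (no missing frames)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        dt = np.diff(self.time)
        if np.any(np.abs(dt - 1.0 / self.frame_rate) > _TIME_STEP_TOL):
            raise ValueError("time must be uniformly sampled at 1/frame_rate")

    @property
    def n_frames(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate


@dataclass
class KinematicSeries:
    """Filtered kinematic time series for one impact.

    ``displacement`` is the resultant (Euclidean) distance of the cheek
    marker from its pre-impact baseline; ``deflection`` the unwrapped angle
    of the marker2->marker1 line above the horizon, baseline-subtracted.
    Linear velocity/acceleration are resultant magnitudes (non-negative);
    angular velocity/acceleration are signed derivatives of the deflection.
    """

    time: np.ndarray
    displacement: np.ndarray
    deflection: np.ndarray
    linear_velocity: np.ndarray
    linear_acceleration: np.ndarray
    angular_velocity: np.ndarray
    angular_acceleration: np.ndarray
    frame_rate: float
    animal_id: str = "animal"
    impact_index: int = 1

    def series(self, quantity: str) -> np.ndarray:
        if quantity not in QUANTITIES:
            raise KeyError(f"unknown kinematic quantity {quantity!r}")
        return getattr(self, quantity)


@dataclass(frozen=True)
class Peak:
    """A peak value and its time-to-peak from impactor contact (s)."""

    value: float
    time: float


@dataclass
class PeakTable:
    """Per-quantity peak summary across one or more impacts.

    ``peaks`` maps each quantity to the mean peak (value, time-to-peak)
    across animals; ``delta_v`` is the change in head velocity, equal to the
    peak resultant velocity for a head that starts at rest; ``cv`` holds the
    coefficient of variation (SD/mean) of the per-animal peak values.
    """

    peaks: dict[str, Peak]
    delta_v: float
    cv: dict[str, float] = field(default_factory=dict)
    n_impacts: int = 1
    n_animals: int = 1
    scaled: bool = False

    def __getitem__(self, quantity: str) -> Peak:
        return self.peaks[quantity]

    def to_dict(self) -> dict:
        return {
            "peaks": {q: {"value": p.value, "time": p.time} for q, p in self.peaks.items()},
            "delta_v": self.delta_v,
            "cv": dict(self.cv),
            "n_impacts": self.n_impacts,
            "n_animals": self.n_animals,
            "scaled": self.scaled,
        }


@dataclass(frozen=True)
class EnergyResult:
    """Kinetic energy transferred to the head: KE = 0.5 * M_e * dV^2."""

    effective_mass: float
    delta_v: float
    kinetic_energy: float

    @property
    def reported(self) -> float:
        """Energy rounded to two decimals in joules, as customarily reported."""
        return round(self.kinetic_energy, 2)


def _butter_cutoff(cutoff_hz: float, order: int, prewarp: bool) -> float:
    """Cutoff to hand the filter designer so the -3 dB point survives filtfilt.

    A forward-backward pass squares the magnitude response, moving the -3 dB
    point below the design cutoff; raising the design cutoff by
    ``(2**(1/2) - 1)**(-1/(2n))`` restores it.
    """
    if not prewarp:
        return cutoff_hz
    return cutoff_hz * (2.0 ** 0.5 - 1.0) ** (-1.0 / (2.0 * order))


def filter_track(
    track: MarkerTrack,
    cutoff_hz: float = 400.0,
    order: int = 4,
    prewarp: bool = True,
) -> MarkerTrack:
    """Low-pass Butterworth filter both marker coordinate series.

    Applied forward-backward (zero phase distortion, DC gain exactly 1) so
    times-to-peak are not shifted by the filter.  ``cutoff_hz`` is the
    effective -3 dB point of the bidirectional filter when ``prewarp`` is on.
    """
    nyquist = track.frame_rate / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency {nyquist} Hz"
        )
    design = _butter_cutoff(cutoff_hz, order, prewarp)
    if design >= nyquist:
        raise ValueError(
            f"pre-warped cutoff {design:.1f} Hz reaches the Nyquist frequency"
        )
    sos = signal.butter(order, design, btype="low", fs=track.frame_rate, output="sos")

    def _apply(coords: np.ndarray) -> np.ndarray:
        return signal.sosfiltfilt(sos, coords, axis=0)

    return replace(track, marker1=_apply(track.marker1), marker2=_apply(track.marker2))


def _marker_angle(track: MarkerTrack) -> np.ndarray:
    """Unwrapped angle of the marker2->marker1 line with the horizon (rad)."""
    d = track.marker1 - track.marker2
    return np.unwrap(np.arctan2(d[:, 1], d[:, 0]))


def derive_kinematics(track: MarkerTrack, baseline_frames: int = 5) -> KinematicSeries:
    """Differentiate a (filtered) two-marker track into kinematic series.

    Linear kinematics come from the cheek marker: displacement is the
    Euclidean distance from the pre-impact baseline (mean of the first
    ``baseline_frames`` frames), velocity and acceleration are magnitudes of
    the central-difference derivatives of the X,Y components (one-sided at
    the ends).  Deflection is the unwrapped marker-line angle minus its
    baseline; its derivatives give angular velocity and acceleration.
    """
    if baseline_frames < 1:
        raise ValueError("baseline_frames must be >= 1")
    if track.n_frames < baseline_frames:
        raise ValueError(
            f"track has {track.n_frames} frames, fewer than the "
            f"{baseline_frames} required pre-impact baseline frames"
        )
    dt = track.dt
    pos = track.marker1
    baseline = pos[:baseline_frames].mean(axis=0)
    displacement = np.linalg.norm(pos - baseline, axis=1)

    vel_xy = np.gradient(pos, dt, axis=0)
    acc_xy = np.gradient(vel_xy, dt, axis=0)
    linear_velocity = np.linalg.norm(vel_xy, axis=1)
    linear_acceleration = np.linalg.norm(acc_xy, axis=1)

    angle = _marker_angle(track)
    deflection = angle - angle[:baseline_frames].mean()
    angular_velocity = np.gradient(deflection, dt)
    angular_acceleration = np.gradient(angular_velocity, dt)

    return KinematicSeries(
        time=track.time.copy(),
        displacement=displacement,
        deflection=deflection,
        linear_velocity=linear_velocity,
        linear_acceleration=linear_acceleration,
        angular_velocity=angular_velocity,
        angular_acceleration=angular_acceleration,
        frame_rate=track.frame_rate,
        animal_id=track.animal_id,
        impact_index=track.impact_index,
    )


def detect_onset(series: KinematicSeries, onset_frac: float = 0.05) -> int:
    """Index of impactor contact: first frame whose resultant linear
    acceleration exceeds ``onset_frac`` of its global maximum (interior
    frames only; the one-sided end estimates are ignored)."""
    if not 0.0 < onset_frac < 1.0:
        raise ValueError("onset_frac must lie in (0, 1)")
    acc = series.linear_acceleration[1:-1]
    threshold = onset_frac * acc.max()
    idx = np.nonzero(acc > threshold)[0]
    if idx.size == 0:
        return 1
    return int(idx[0]) + 1


def _series_peaks(series: KinematicSeries, onset_frac: float) -> dict[str, Peak]:
    """Per-quantity peak magnitude and time-to-peak for one impact.

    The search starts at the detected impactor contact and excludes the
    first/last frame (one-sided difference estimates).  Angular quantities
    are signed series; their peak is the peak magnitude.
    """
    onset = detect_onset(series, onset_frac)
    t0 = series.time[onset]
    lo, hi = max(onset, 1), series.time.size - 1
    if hi <= lo:
        raise ValueError("no interior frames after onset to search for peaks")
    out: dict[str, Peak] = {}
    for q in QUANTITIES:
        mag = np.abs(series.series(q)[lo:hi])
        i = int(np.argmax(mag))
        out[q] = Peak(value=float(mag[i]), time=float(series.time[lo + i] - t0))
    return out


def summarize_peaks(
    series_per_impact: list[KinematicSeries],
    onset_frac: float = 0.05,
    cv_mode: str = "animal_day_mean",
) -> PeakTable:
    """Summarize peak kinematics across impacts.

    Each impact contributes a peak (value, time) per quantity, measured from
    impactor contact.  With ``cv_mode="animal_day_mean"`` (default) every
    animal first contributes the average of its repeated impacts (day 1 /
    day 2), and the table reports the mean and CV = SD/mean (sample SD)
    over those per-animal values; ``"pooled"`` treats every impact as an
    independent observation.  ``delta_v`` is set to the peak resultant
    linear velocity (the head starts at rest, so the velocity change equals
    the peak velocity).
    """
    if not series_per_impact:
        raise ValueError("need at least one KinematicSeries")
    if cv_mode not in ("animal_day_mean", "pooled"):
        raise ValueError(f"unknown cv_mode {cv_mode!r}")

    per_impact = [_series_peaks(s, onset_frac) for s in series_per_impact]

    if cv_mode == "animal_day_mean":
        groups: dict[str, list[dict[str, Peak]]] = {}
        for s, peaks in zip(series_per_impact, per_impact):
            groups.setdefault(s.animal_id, []).append(peaks)
        units = [
            {
                q: Peak(
                    value=float(np.mean([p[q].value for p in plist])),
                    time=float(np.mean([p[q].time for p in plist])),
                )
                for q in QUANTITIES
            }
            for plist in groups.values()
        ]
    else:
        units = per_impact

    peaks: dict[str, Peak] = {}
    cv: dict[str, float] = {}
    for q in QUANTITIES:
        values = np.array([u[q].value for u in units])
        times = np.array([u[q].time for u in units])
        mean = float(values.mean())
        peaks[q] = Peak(value=mean, time=float(times.mean()))
        if values.size > 1 and mean != 0.0:
            cv[q] = float(values.std(ddof=1) / mean)
        else:
            cv[q] = 0.0

    return PeakTable(
        peaks=peaks,
        delta_v=peaks["linear_velocity"].value,
        cv=cv,
        n_impacts=len(series_per_impact),
        n_animals=len(units),
        scaled=False,
    )


def impact_energy(effective_mass: float, delta_v: float) -> EnergyResult:
    """Kinetic energy transferred to the head, KE = 0.5 * M_e * dV^2.

    ``effective_mass`` is approximated by head mass (kg); ``delta_v`` is the
    change in resultant head velocity (m/s), equal to the peak velocity for
    a head initially at rest.
    """
    if effective_mass <= 0:
        raise ValueError("effective mass must be positive")
    if delta_v < 0:
        raise ValueError("delta_v must be non-negative")
    ke = 0.5 * effective_mass * delta_v**2
    return EnergyResult(effective_mass=effective_mass, delta_v=delta_v, kinetic_energy=ke)
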