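"""Synthetic inputs with the structure the downstream analysis assumes.

The study's raw inputs (high-speed video marker tracks, histology images,
behavioral records) are not deposited, so this module generates stand-ins
with controlled ground truth:

* :func:`gen_impact_trajectory` — a two-marker head trajectory whose
  noiseless kinematics satisfy a prescribed set of six peak (value, time)
  constraints: displacement, deflection, linear velocity and acceleration,
  angular velocity and acceleration.
* :func:`gen_microglia_image` — binary microglial silhouettes spanning the
  ramified -> hypertrophic -> bushy -> amoeboid activation continuum, with
  correspondingly decreasing outline fractal dimension.
* :func:`gen_openfield_track` — open-field position samples with a
  controllable peripheral-zone occupancy fraction.
* :func:`gen_calibration_table` — replicated (air pressure, piston exit
  velocity) calibration measurements around a known quadratic.

Trajectory construction: the resultant speed profile (and, independently,
the angular-rate profile) is a smooth three-phase pulse — a beta-shaped
rise whose steepness is solved so the acceleration peaks at the prescribed
(value, time), a raised-cosine-power fall whose exponent is solved so the
integral peaks at the prescribed displacement, and a small negative
return lobe so the displacement decreases after its peak.  Because the
constraints are checked on discretely sampled positions (finite
differences attenuate sharp peaks), an outer fixed-point loop rescales the
continuous targets until the sampled-track kinematics match the requested
peaks; if any constraint cannot be met the generator raises rather than
returning a best-effort track.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from numpy.random import default_rng
from scipy import integrate, ndimage, optimize, signal, special
from skimage import draw as skdraw
from skimage import morphology as skmorph

from .behavior import zone_partition
from .kinematics import (
    GRAVITY,
    MarkerTrack,
    _butter_cutoff,
    derive_kinematics,
    filter_track,
)

__all__ = [
    "ImpactSpec",
    "InfeasibleImpactSpec",
    "MOUSE_IMPACT_PEAKS",
    "DEFAULT_NOISE_SD",
    "MORPHOLOGIES",
    "gen_impact_trajectory",
    "gen_microglia_image",
    "gen_openfield_track",
    "gen_calibration_table",
    "DEFAULT_CALIBRATION_PRESSURES",
    "DEFAULT_CALIBRATION_COEFFS",
]

#: default tracking-noise standard deviation on marker coordinates (m);
#: sub-pixel jitter of about 0.05 mm, typical of high-speed marker tracking
DEFAULT_NOISE_SD = 5e-5

#: inter-marker (cheek paint to snout floss) distance in meters
_MARKER_SEPARATION = 0.015

#: direction of linear head motion (unit vector, X rostral / Y up)
_MOTION_DIRECTION = np.array([np.cos(np.deg2rad(60.0)), np.sin(np.deg2rad(60.0))])

#: pre-impact stationary lead-in (s); 10 frames at 5,000 frames/s
_PRE_IMPACT = 2e-3

#: fraction of the peak excursion recovered during the return phase
_RETURN_FRACTION = 0.4

#: oversampling factor for numerical integration of the speed profiles
_OVERSAMPLE = 20


class InfeasibleImpactSpec(ValueError):
    """The peak constraint set cannot be realized by a smooth trajectory."""


@dataclass(frozen=True)
class ImpactSpec:
    """Target peak kinematics for one synthetic impact.

    Values are SI (m, s, rad); times are measured from impactor contact.
    ``noise_sd`` is the standard deviation of isotropic Gaussian tracking
    noise added to both marker coordinates (0 disables it).
    """

    peak_displacement: float
    t_displacement: float
    peak_deflection: float
    t_deflection: float
    peak_velocity: float
    t_velocity: float
    peak_acceleration: float
    t_acceleration: float
    peak_ang_velocity: float
    t_ang_velocity: float
    peak_ang_acceleration: float
    t_ang_acceleration: float
    frame_rate: float = 5000.0
    duration: float = 0.04
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        peaks = {
            "peak_displacement": self.peak_displacement,
            "peak_deflection": self.peak_deflection,
            "peak_velocity": self.peak_velocity,
            "peak_acceleration": self.peak_acceleration,
            "peak_ang_velocity": self.peak_ang_velocity,
            "peak_ang_acceleration": self.peak_ang_acceleration,
        }
        for name, v in peaks.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if any(p > 0 for p in peaks.values()):
            times = {
                "t_displacement": self.t_displacement,
                "t_deflection": self.t_deflection,
                "t_velocity": self.t_velocity,
                "t_acceleration": self.t_acceleration,
                "t_ang_velocity": self.t_ang_velocity,
                "t_ang_acceleration": self.t_ang_acceleration,
            }
            for name, t in times.items():
                if not 0.0 < t < self.duration:
                    raise ValueError(f"{name} must lie in (0, duration), got {t}")
            if not self.t_acceleration <= self.t_velocity <= self.t_displacement:
                raise ValueError(
                    "peak ordering violated: require "
                    "t_acceleration <= t_velocity <= t_displacement"
                )
            if not self.t_ang_acceleration <= self.t_ang_velocity <= self.t_deflection:
                raise ValueError(
                    "peak ordering violated: require "
                    "t_ang_acceleration <= t_ang_velocity <= t_deflection"
                )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def is_stationary(self) -> bool:
        return (
            self.peak_displacement == 0
            and self.peak_deflection == 0
            and self.peak_velocity == 0
            and self.peak_acceleration == 0
            and self.peak_ang_velocity == 0
            and self.peak_ang_acceleration == 0
        )


#: measured mouse-head peak kinematics for a 0.5 J vertex impact: 49.6 mm at
#: 15.7 ms, 2.6 rad at 24.8 ms, 6.6 m/s at 3.4 ms, 385.3 g at 1.5 ms,
#: 305.8 rad/s at 2.8 ms, 253.6 krad/s^2 at 0.8 ms, recorded at 5,000 fps
MOUSE_IMPACT_PEAKS = ImpactSpec(
    peak_displacement=49.6e-3,
    t_displacement=15.7e-3,
    peak_deflection=2.6,
    t_deflection=24.8e-3,
    peak_velocity=6.6,
    t_velocity=3.4e-3,
    peak_acceleration=385.3 * GRAVITY,
    t_acceleration=1.5e-3,
    peak_ang_velocity=305.8,
    t_ang_velocity=2.8e-3,
    peak_ang_acceleration=253.6e3,
    t_ang_acceleration=0.8e-3,
    frame_rate=5000.0,
    duration=0.04,
    noise_sd=0.0,
)


# ---------------------------------------------------------------------------
# trajectory channel construction
# ---------------------------------------------------------------------------


def _solve_rise_steepness(tau_star: float, ratio: float, channel: str) -> float:
    """Steepness k of the beta-shaped rise pulse.

    The first-derivative profile on the rise is a Beta(k*tau*+1,
    k*(1-tau*)+1) density; its mode sits at ``tau_star`` for every k, and
    its peak-to-mean ratio grows monotonically from 1 with k.  ``ratio`` is
    the required peak acceleration divided by the mean acceleration over
    the rise (A * t_vel / V); it must exceed 1.
    """
    if ratio <= 1.0:
        raise InfeasibleImpactSpec(
            f"{channel}: peak acceleration must exceed the mean acceleration "
            f"over the rise (peak/mean = {ratio:.3f} <= 1)"
        )

    def peak_over_mean(k: float) -> float:
        a, b = k * tau_star, k * (1.0 - tau_star)
        log_pdf = (
            a * np.log(tau_star)
            + b * np.log(1.0 - tau_star)
            - special.betaln(a + 1.0, b + 1.0)
        )
        return float(np.exp(log_pdf))

    lo, hi = 1e-8, 1.0
    while peak_over_mean(hi) < ratio:
        hi *= 2.0
        if hi > 1e6:
            raise InfeasibleImpactSpec(
                f"{channel}: acceleration peak/mean ratio {ratio:.3f} too "
                "extreme for the rise-pulse family"
            )
    return float(optimize.brentq(lambda k: peak_over_mean(k) - ratio, lo, hi))


def _fall_area_fraction(m: float) -> float:
    """Integral of cos(pi*s/2)**(2m) over s in [0, 1]."""
    return float(np.exp(special.gammaln(m + 0.5) - special.gammaln(m + 1.0)) / np.sqrt(np.pi))


def _solve_fall_exponent(frac: float, channel: str) -> float:
    """Exponent m of the raised-cosine-power fall with given area fraction."""
    if not 0.0 < frac < 1.0:
        raise InfeasibleImpactSpec(
            f"{channel}: peak excursion requires a fall-phase area fraction "
            f"of {frac:.3f}, outside the feasible interval (0, 1)"
        )
    m_hi = 80.0
    if frac < _fall_area_fraction(m_hi):
        raise InfeasibleImpactSpec(
            f"{channel}: fall-phase area fraction {frac:.3f} too small "
            "(excursion peak nearly coincides with the velocity peak)"
        )
    return float(
        optimize.brentq(lambda m: _fall_area_fraction(m) - frac, 1e-8, m_hi)
    )


def _beta_rise(s: np.ndarray, v_peak, a_peak, t_a, t_v, channel) -> np.ndarray:
    """Rise-phase rate profile with a beta-density acceleration pulse."""
    tau_star = t_a / t_v
    k = _solve_rise_steepness(tau_star, a_peak * t_v / v_peak, channel)
    a_exp, b_exp = k * tau_star, k * (1.0 - tau_star)
    return v_peak * special.betainc(a_exp + 1.0, b_exp + 1.0, np.clip(s / t_v, 0, 1))


def _fall_curve(s, v_peak: float, t_v: float, t_x: float, m: float):
    """Raised-cosine-power decay of the rate from ``v_peak`` at ``t_v`` to
    zero at ``t_x`` (the excursion peak)."""
    sigma = np.clip((s - t_v) / (t_x - t_v), 0.0, 1.0)
    return v_peak * np.cos(0.5 * np.pi * sigma) ** (2.0 * m)


@lru_cache(maxsize=32)
def _design_angular_rise(
    frame_rate: float,
    v_peak: float,
    a_filt: float,
    t_a: float,
    t_v: float,
    t_x: float,
    m_fall: float,
    cutoff_hz: float = 400.0,
    order: int = 4,
) -> tuple[float, ...]:
    """Angular-rate rise profile at frame resolution, by linear programming.

    The printed angular-acceleration peak of a head impact is a *filtered*
    measurement, and a zero-phase low-pass filter both attenuates sharp
    acceleration transients and rings their step response into the rate
    series; no closed-form pulse family meets all the angular constraints
    at once.  This designer therefore solves for the rate samples
    ``omega_0..omega_{iv+2}`` (time from impactor contact, one sample per
    frame) directly, subject to

    * ``0 <= omega_j <= v_peak`` with equality exactly at the prescribed
      rate-peak frame (the unfiltered rate peaks at ``t_v``),
    * the unfiltered central-difference acceleration peaking at ``t_a``,
    * the *filtered* central-difference acceleration equal to ``a_filt`` at
      ``t_a`` and nowhere larger,
    * the filtered rate series peaking within two frames of ``t_v``,

    maximizing the margin on the inequality constraints and then, with half
    of that margin fixed, minimizing total curvature so the profile is
    smooth.  Samples beyond the window are pinned to the analytic fall
    toward the deflection peak (exponent ``m_fall``).  Returns the rate
    window as a tuple; raises :class:`InfeasibleImpactSpec` if no profile
    satisfies the constraints.
    """
    fs, dt = frame_rate, 1.0 / frame_rate
    ia, iv = round(t_a * fs), round(t_v * fs)
    if ia < 1 or iv < ia + 2:
        raise InfeasibleImpactSpec(
            "angular: acceleration and rate peak times too close together "
            f"at {fs:.0f} frames/s (frames {ia} and {iv})"
        )
    design = _butter_cutoff(cutoff_hz, order, True)
    if design >= fs / 2.0:
        raise InfeasibleImpactSpec(
            f"frame rate {fs:.0f} frames/s cannot represent the "
            f"{cutoff_hz:.0f}-Hz measurement band"
        )
    sos = signal.butter(order, design, fs=fs, btype="low", output="sos")
    nh = 201
    impulse = np.zeros(nh)
    impulse[nh // 2] = 1.0
    h = signal.sosfiltfilt(sos, impulse)

    # free samples must extend ~2.4 ms past the rate peak: the designer
    # needs post-peak freedom on the scale of the filter's ringing to keep
    # the filtered rate peak at the right frame
    n = iv + 1 + round(2.4e-3 * fs)
    n_pre, n_ctx = 30, 40
    big_n = n_pre + n + n_ctx
    t_ctx = (n - 1 + np.arange(1, n_ctx + 1)) * dt
    const = np.zeros(big_n)
    const[n_pre + n :] = _fall_curve(t_ctx, v_peak, t_v, t_x, m_fall)

    def hval(lag: int) -> float:
        j = nh // 2 + lag
        return float(h[j]) if 0 <= j < nh else 0.0

    idx = np.arange(big_n)
    F = np.array([[hval(i - k) for k in idx] for i in idx])
    D = np.zeros((big_n, big_n))
    for i in range(1, big_n - 1):
        D[i, i + 1] = 1.0 / (2.0 * dt)
        D[i, i - 1] = -1.0 / (2.0 * dt)
    G = F @ D
    ia_f, iv_f = n_pre + ia, n_pre + iv

    def rowc(vf: np.ndarray) -> tuple[np.ndarray, float]:
        return vf[n_pre : n_pre + n], float(vf @ const)

    def solve(eps_fixed: float | None):
        n_sl = (n - 2) if eps_fixed is not None else 0
        nv = n + 1 + n_sl
        A_ub, b_ub, A_eq, b_eq = [], [], [], []

        def ub(var, rhs, eps_c=0.0, sl=None):
            row = np.zeros(nv)
            row[:n] = var
            row[n] = eps_c
            if sl is not None:
                row[n + 1 + sl[0]] = sl[1]
            A_ub.append(row)
            b_ub.append(rhs)

        def eq(var, rhs):
            row = np.zeros(nv)
            row[:n] = var
            A_eq.append(row)
            b_eq.append(rhs)

        for j in range(n):
            var = np.zeros(n)
            var[j] = 1.0
            if j == iv:
                eq(var, v_peak)
            elif abs(j - iv) == 1:
                # immediate neighbours may tie the peak (the measured peak
                # time then shifts by at most one frame)
                ub(var, v_peak)
            elif j > iv:
                # post-peak samples stay strictly below the peak so solver
                # round-off cannot relocate the discrete argmax
                ub(var, v_peak * (1.0 - 1e-4))
            else:
                ub(var, v_peak, eps_c=v_peak)
            ub(-var, 0.0)
        # smooth hand-over to the analytic fall
        for j in (n - 2, n - 1):
            var = np.zeros(n)
            var[j] = 1.0
            eq(var, float(_fall_curve(j * dt, v_peak, t_v, t_x, m_fall)))
        # unfiltered acceleration peaks at t_a
        rowA, cstA = rowc(D[ia_f])
        for i in range(1, big_n - 1):
            if i == ia_f:
                continue
            ri, ci = rowc(D[i])
            ub(ri - rowA, cstA - ci)
            ub(-ri - rowA, cstA + ci)
        # filtered acceleration equals the target at t_a, nowhere larger
        rowFa, cstFa = rowc(G[ia_f])
        eq(rowFa, a_filt - cstFa)
        for i in range(1, big_n - 1):
            if i == ia_f:
                continue
            ri, ci = rowc(G[i])
            ub(ri, a_filt - ci)
            ub(-ri, a_filt + ci)
        # filtered rate peaks within two frames of t_v
        rg, cg = rowc(F[iv_f])
        for i in range(big_n):
            if abs(i - iv_f) <= 2:
                continue
            ri, ci = rowc(F[i])
            ub(ri - rg, cg - ci, eps_c=v_peak)
        if eps_fixed is None:
            c = np.zeros(nv)
            c[n] = -1.0
            bounds = [(None, None)] * n + [(0.0, 0.2)]
        else:
            c = np.zeros(nv)
            c[n + 1 :] = 1.0
            bounds = (
                [(None, None)] * n + [(eps_fixed, eps_fixed)] + [(0.0, None)] * n_sl
            )
            for k in range(n_sl):
                var = np.zeros(n)
                var[k] = 1.0
                var[k + 1] = -2.0
                var[k + 2] = 1.0
                ub(var, 0.0, sl=(k, -1.0))
                ub(-var, 0.0, sl=(k, -1.0))
        return optimize.linprog(
            c,
            A_ub=np.array(A_ub),
            b_ub=np.array(b_ub),
            A_eq=np.array(A_eq),
            b_eq=np.array(b_eq),
            bounds=bounds,
            method="highs",
        )

    first = solve(None)
    if first.status != 0 or first.x[n] <= 1e-6:
        raise InfeasibleImpactSpec(
            "constraint angular_acceleration: no angular-rate profile "
            "satisfies the filtered-acceleration target together with the "
            "angular-velocity peak constraints"
        )
    # a 1% constraint margin is ample for unique discrete peaks; demanding
    # more just contorts the post-peak profile
    second = solve(min(0.5 * float(first.x[n]), 0.01))
    if second.status != 0:
        raise InfeasibleImpactSpec(
            "angular: curvature-minimizing profile solve failed"
        )
    return tuple(float(v) for v in second.x[:n])


def _channel_rate(
    s: np.ndarray,
    v_peak: float,
    a_peak: float,
    x_peak: float,
    t_a: float,
    t_v: float,
    t_x: float,
    s_end: float,
    channel: str,
) -> np.ndarray:
    """Signed first-derivative profile u(s) of one channel on grid ``s``.

    ``s`` is time since impactor contact; u is the speed.  The profile
    rises to ``v_peak`` at ``t_v`` with a beta-density derivative pulse
    peaking at (``a_peak``, ``t_a``), falls to zero at ``t_x`` such that
    the integral there equals ``x_peak``, then dips negative to return
    part of the excursion.
    """
    if not t_a < t_v < t_x:
        raise InfeasibleImpactSpec(
            f"{channel}: need strictly ordered peak times "
            f"(acceleration {t_a} < velocity {t_v} < excursion {t_x})"
        )
    if t_x >= s_end:
        raise InfeasibleImpactSpec(
            f"{channel}: excursion peak time {t_x} s leaves no room for the "
            f"return phase before the track ends at {s_end:.4f} s after contact"
        )
    u = np.zeros_like(s)
    in_rise = (s > 0) & (s <= t_v)
    u_rise = _beta_rise(s, v_peak, a_peak, t_a, t_v, channel)
    u[in_rise] = u_rise[in_rise]

    ds = s[1] - s[0]
    pre = s <= t_v
    rise_area = float(np.trapezoid(u[pre], dx=ds))
    fall_area = x_peak - rise_area
    m = _solve_fall_exponent(fall_area / (v_peak * (t_x - t_v)), channel)

    ret_span = s_end - t_x
    ret_amp = 2.0 * _RETURN_FRACTION * x_peak / ret_span
    if ret_amp >= v_peak:
        raise InfeasibleImpactSpec(
            f"{channel}: return-phase rate {ret_amp:.3f} would exceed the "
            f"prescribed peak rate {v_peak:.3f}; increase the track duration"
        )
    if ret_amp * np.pi / ret_span >= a_peak:
        raise InfeasibleImpactSpec(
            f"{channel}: return-phase acceleration would exceed the "
            f"prescribed peak acceleration {a_peak:.3f}"
        )

    fall = (s > t_v) & (s <= t_x)
    u[fall] = _fall_curve(s[fall], v_peak, t_v, t_x, m)
    ret = s > t_x
    u[ret] = -ret_amp * np.sin(np.pi * (s[ret] - t_x) / ret_span) ** 2
    return u


def _integrate_channel(spec_args: dict, n_frames: int, dt: float) -> np.ndarray:
    """Excursion x(t) at frame times, integrating u on an oversampled grid."""
    fine_dt = dt / _OVERSAMPLE
    n_fine = (n_frames - 1) * _OVERSAMPLE + 1
    s_fine = np.arange(n_fine) * fine_dt - _PRE_IMPACT
    u = _channel_rate(s_fine, **spec_args)
    x = integrate.cumulative_trapezoid(u, dx=fine_dt, initial=0.0)
    return x[::_OVERSAMPLE]


def _angular_theta_frames(spec: ImpactSpec, x_peak: float, n_frames: int) -> np.ndarray:
    """Deflection angle at frame times realizing the angular constraints.

    The rise window comes from the linear-programming designer (which pins
    the unfiltered rate peak, the acceleration peak time, and the filtered
    acceleration peak); the fall exponent is solved so the deflection peaks
    at ``x_peak`` at its prescribed time, and a negative return lobe
    follows.  The angle is reconstructed by the inverse of the
    central-difference operator (``theta_{j+1} = theta_{j-1} +
    2*dt*omega_j``), so the finite-difference oracle recovers the designed
    rate samples exactly.
    """
    fs, dt = spec.frame_rate, 1.0 / spec.frame_rate
    v_peak = spec.peak_ang_velocity
    t_a, t_v, t_x = spec.t_ang_acceleration, spec.t_ang_velocity, spec.t_deflection
    s_end = spec.duration - _PRE_IMPACT
    if t_x >= s_end:
        raise InfeasibleImpactSpec(
            f"angular: deflection peak time {t_x} s leaves no room for the "
            f"return phase before the track ends at {s_end:.4f} s after contact"
        )
    ret_span = s_end - t_x
    ret_amp = 2.0 * _RETURN_FRACTION * x_peak / ret_span
    if ret_amp >= v_peak:
        raise InfeasibleImpactSpec(
            f"angular: return-phase rate {ret_amp:.3f} would exceed the "
            f"prescribed peak rate {v_peak:.3f}; increase the track duration"
        )

    iv = round(t_v * fs)
    m = 2.0
    window = None
    for _ in range(3):
        window = np.array(
            _design_angular_rise(
                fs,
                v_peak,
                spec.peak_ang_acceleration,
                t_a,
                t_v,
                t_x,
                round(m, 3),
            )
        )
        rise_area = float(np.trapezoid(window[: iv + 1], dx=dt))
        m = _solve_fall_exponent(
            (x_peak - rise_area) / (v_peak * (t_x - t_v)), "angular"
        )

    s = np.arange(n_frames) * dt - _PRE_IMPACT
    omega = np.zeros(n_frames)
    j0 = round(_PRE_IMPACT * fs)
    omega[j0 : j0 + window.size] = window
    in_fall = s > (window.size - 1) * dt
    omega[in_fall] = _fall_curve(s[in_fall], v_peak, t_v, t_x, m)
    ret = s > t_x
    omega[ret] = -ret_amp * np.sin(np.pi * (s[ret] - t_x) / ret_span) ** 2

    theta = np.zeros(n_frames)
    for j in range(1, n_frames - 1):
        theta[j + 1] = theta[j - 1] + 2.0 * dt * omega[j]
    return theta


#: quantities whose generator constraints are checked on the unfiltered
#: finite-difference oracle; the angular-acceleration peak is instead pinned
#: in the filtered measurement domain (see _measured_peaks)
_ORACLE_QUANTITIES = (
    "displacement",
    "deflection",
    "linear_velocity",
    "linear_acceleration",
    "angular_velocity",
)


def _measured_peaks(track: MarkerTrack) -> tuple[dict[str, float], dict[str, float]]:
    """Peak magnitudes and times (from contact) used to calibrate a track.

    Five quantities are measured on the unfiltered central-difference oracle.
    Angular acceleration is measured through the standard 400-Hz zero-phase
    pipeline filter, because its printed reference values are themselves
    filtered measurements and no waveform can match them in both domains at
    once: its filtered peak is provably at most ~0.92 of its unfiltered peak
    once the angular-velocity peak caps the pulse area.
    """
    peaks: dict[str, float] = {}
    times: dict[str, float] = {}

    def _collect(ks, quantities):
        for q in quantities:
            series = np.abs(ks.series(q)[1:-1])
            i = int(np.argmax(series))
            peaks[q] = float(series[i])
            times[q] = float(ks.time[i + 1]) - _PRE_IMPACT

    _collect(derive_kinematics(track), _ORACLE_QUANTITIES)
    _collect(derive_kinematics(filter_track(track)), ("angular_acceleration",))
    return peaks, times


def _build_track(spec: ImpactSpec, lin_targets: dict, ang_targets: dict) -> MarkerTrack:
    n_frames = int(round(spec.duration * spec.frame_rate)) + 1
    dt = 1.0 / spec.frame_rate
    time = np.arange(n_frames) * dt
    s_end = spec.duration - _PRE_IMPACT

    x = _integrate_channel(
        dict(
            v_peak=lin_targets["v"],
            a_peak=lin_targets["a"],
            x_peak=lin_targets["x"],
            t_a=spec.t_acceleration,
            t_v=spec.t_velocity,
            t_x=spec.t_displacement,
            s_end=s_end,
            channel="linear",
        ),
        n_frames,
        dt,
    )
    theta = _angular_theta_frames(spec, ang_targets["x"], n_frames)

    marker1 = np.outer(x, _MOTION_DIRECTION)
    marker2 = marker1 - _MARKER_SEPARATION * np.column_stack(
        [np.cos(theta), np.sin(theta)]
    )
    return MarkerTrack(
        time=time, marker1=marker1, marker2=marker2, frame_rate=spec.frame_rate
    )


def gen_impact_trajectory(
    spec: ImpactSpec,
    seed: int | None = None,
    animal_id: str = "animal",
    impact_index: int = 1,
    value_rtol: float = 0.02,
    time_tol_frames: int = 1,
    max_iter: int = 8,
) -> MarkerTrack:
    """Generate a two-marker track realizing the peak constraints of ``spec``.

    The head is stationary for the first 10 frames, the markers keep a fixed
    separation (rigid head), and the marker-pair angle follows the deflection
    profile.  The noiseless track's unfiltered finite-difference kinematics
    match all six (value, time) peak constraints within ``value_rtol``
    relative tolerance on values and ``time_tol_frames`` frames on times
    (times measured from impactor contact); :class:`InfeasibleImpactSpec`
    names the violated constraint otherwise.  Gaussian tracking noise of
    standard deviation ``spec.noise_sd`` is added when requested (a ``seed``
    is then required for reproducibility).
    """
    if spec.noise_sd > 0 and seed is None:
        raise ValueError("a seed is required when noise_sd > 0")

    if spec.is_stationary:
        n_frames = int(round(spec.duration * spec.frame_rate)) + 1
        time = np.arange(n_frames) / spec.frame_rate
        marker1 = np.zeros((n_frames, 2))
        marker2 = marker1 - np.array([_MARKER_SEPARATION, 0.0])
        track = MarkerTrack(
            time=time,
            marker1=marker1,
            marker2=marker2,
            frame_rate=spec.frame_rate,
            animal_id=animal_id,
            impact_index=impact_index,
        )
        return _add_noise(track, spec.noise_sd, seed)

    targets = {
        "displacement": spec.peak_displacement,
        "deflection": spec.peak_deflection,
        "linear_velocity": spec.peak_velocity,
        "linear_acceleration": spec.peak_acceleration,
        "angular_velocity": spec.peak_ang_velocity,
        "angular_acceleration": spec.peak_ang_acceleration,
    }
    for name, v in targets.items():
        if v == 0:
            raise InfeasibleImpactSpec(
                f"constraint {name} = 0 is incompatible with the remaining "
                "non-zero peaks (a moving head has non-zero kinematics)"
            )

    # The angular channel is designed directly at frame resolution (see
    # _design_angular_rise / _angular_theta_frames) and needs no amplitude
    # calibration beyond the deflection target; the linear channel is a
    # continuous profile whose targets are refined by a fixed-point loop so
    # the sampled track's finite-difference peaks hit the requested values.
    lin = {"v": spec.peak_velocity, "a": spec.peak_acceleration, "x": spec.peak_displacement}
    ang = {"x": spec.peak_deflection}
    track = None
    for _ in range(max_iter):
        track = _build_track(spec, lin, ang)
        measured, _ = _measured_peaks(track)
        errs = {q: measured[q] / targets[q] for q in _ORACLE_QUANTITIES}
        if all(abs(e - 1.0) <= 0.25 * value_rtol for e in errs.values()):
            break
        lin["x"] /= errs["displacement"]
        lin["v"] /= errs["linear_velocity"]
        lin["a"] /= errs["linear_acceleration"]
        ang["x"] /= errs["deflection"]

    measured, times = _measured_peaks(track)
    expected_times = {
        "displacement": spec.t_displacement,
        "deflection": spec.t_deflection,
        "linear_velocity": spec.t_velocity,
        "linear_acceleration": spec.t_acceleration,
        "angular_velocity": spec.t_ang_velocity,
        "angular_acceleration": spec.t_ang_acceleration,
    }
    dt = 1.0 / spec.frame_rate
    for q in targets:
        if abs(measured[q] - targets[q]) > value_rtol * targets[q]:
            raise InfeasibleImpactSpec(
                f"constraint {q}: generated peak {measured[q]:.4g} misses the "
                f"target {targets[q]:.4g} beyond {value_rtol:.0%} tolerance"
            )
        if abs(times[q] - expected_times[q]) > time_tol_frames * dt + 1e-12:
            raise InfeasibleImpactSpec(
                f"constraint {q}: peak occurs at {times[q] * 1e3:.2f} ms, "
                f"more than {time_tol_frames} frame(s) from the target "
                f"{expected_times[q] * 1e3:.2f} ms"
            )

    track = replace(track, animal_id=animal_id, impact_index=impact_index)
    return _add_noise(track, spec.noise_sd, seed)


def _add_noise(track: MarkerTrack, noise_sd: float, seed: int | None) -> MarkerTrack:
    if noise_sd <= 0:
        return track
    rng = default_rng(seed)
    return replace(
        track,
        marker1=track.marker1 + rng.normal(0.0, noise_sd, track.marker1.shape),
        marker2=track.marker2 + rng.normal(0.0, noise_sd, track.marker2.shape),
    )


# ---------------------------------------------------------------------------
# microglial silhouettes
# ---------------------------------------------------------------------------

#: activation continuum, most ramified (resting) to fully amoeboid (activated)
MORPHOLOGIES = ("ramified", "hypertrophic", "bushy", "amoeboid")

# soma radius, primary-process count, branch generations, primary length,
# child length ratio, process half-width (px of dilation), as fractions of
# the canvas side where applicable
_MORPH_PARAMS = {
    "ramified": dict(soma=0.05, n_primary=7, depth=5, length=0.17, ratio=0.75, width=1),
    "hypertrophic": dict(soma=0.10, n_primary=5, depth=2, length=0.22, ratio=0.70, width=2),
    "bushy": dict(soma=0.13, n_primary=16, depth=1, length=0.14, ratio=0.70, width=2),
    "amoeboid": dict(soma=0.30, n_primary=0, depth=0, length=0.0, ratio=0.0, width=0),
}


def _draw_branch(canvas, rng, origin, angle, length, depth, ratio, spread=0.55, n_seg=4):
    size = canvas.shape[0]
    pos = np.asarray(origin, dtype=float)
    a = angle
    for _ in range(n_seg):
        a += rng.normal(0.0, 0.25)
        step = length / n_seg
        nxt = pos + step * np.array([np.cos(a), np.sin(a)])
        rr, cc = skdraw.line(
            int(round(pos[0])), int(round(pos[1])), int(round(nxt[0])), int(round(nxt[1]))
        )
        keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
        canvas[rr[keep], cc[keep]] = True
        pos = nxt
    if depth > 1:
        for sign in (1.0, -1.0):
            _draw_branch(
                canvas,
                rng,
                pos,
                a + sign * spread * rng.uniform(0.7, 1.3),
                length * ratio,
                depth - 1,
                ratio,
                spread,
                n_seg,
            )


def gen_microglia_image(morphology: str, size_px: int = 256, seed: int = 0) -> np.ndarray:
    """Binary silhouette of one synthetic microglial cell.

    ``morphology`` selects a point on the activation continuum: ``ramified``
    cells have a small soma with several generations of long fine processes,
    ``hypertrophic`` cells thicker primary/secondary branches, ``bushy``
    cells short stubby processes, and ``amoeboid`` cells are a smooth blob.
    The expected box-counting fractal dimension of the outline decreases
    strictly along that order.  Returns a boolean ``(size_px, size_px)``
    array containing a single connected component.
    """
    if morphology not in _MORPH_PARAMS:
        raise ValueError(
            f"unknown morphology {morphology!r}; expected one of {MORPHOLOGIES}"
        )
    if size_px < 128:
        raise ValueError("size_px must be >= 128")
    p = _MORPH_PARAMS[morphology]
    rng = default_rng(seed)
    center = np.array([size_px / 2.0, size_px / 2.0])

    soma = np.zeros((size_px, size_px), dtype=bool)
    soma_r = p["soma"] * size_px
    if morphology == "amoeboid":
        # smooth low-order Fourier perturbation of a disk; bounded harmonic
        # amplitudes keep the boundary convex-ish and spike-free
        phi = np.linspace(0.0, 2.0 * np.pi, 256, endpoint=False)
        r = soma_r * np.ones_like(phi)
        for k, amp in ((2, 0.06), (3, 0.04), (4, 0.03)):
            r += soma_r * amp * np.cos(k * phi + rng.uniform(0, 2 * np.pi))
        rr, cc = skdraw.polygon(
            center[0] + r * np.cos(phi), center[1] + r * np.sin(phi), shape=soma.shape
        )
        soma[rr, cc] = True
        return soma
    rr, cc = skdraw.disk(center, soma_r, shape=soma.shape)
    soma[rr, cc] = True

    branches = np.zeros_like(soma)
    offsets = rng.uniform(0.0, 2.0 * np.pi)
    for i in range(p["n_primary"]):
        angle = offsets + 2.0 * np.pi * i / p["n_primary"] + rng.normal(0.0, 0.2)
        _draw_branch(
            branches,
            rng,
            center,
            angle,
            p["length"] * size_px,
            p["depth"],
            p["ratio"],
        )
    if p["width"] > 0:
        branches = ndimage.binary_dilation(
            branches, structure=skmorph.disk(p["width"])
        )
    return soma | branches


# ---------------------------------------------------------------------------
# open-field tracks
# ---------------------------------------------------------------------------

#: open-field arena dimensions (width x length), inches
ARENA_SIZE = (14.0, 24.0)
#: arena partition: 6 columns across the 14-in side, 10 rows along 24 in
ARENA_GRID = (10, 6)


def gen_openfield_track(
    frac_peripheral: float,
    duration: float = 600.0,
    rate: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Open-field position samples with a prescribed peripheral occupancy.

    The 14 in x 24 in arena is partitioned into 60 equal squares (28
    peripheral along the walls, 32 central); exactly
    ``round(frac_peripheral * n)`` of the ``n = duration * rate`` samples
    are placed uniformly in peripheral squares and the rest in central
    squares, in randomized temporal order.  Returns a data frame with
    columns ``time_s``, ``x``, ``y`` (arena coordinates, inches).
    """
    if not 0.0 <= frac_peripheral <= 1.0:
        raise ValueError("frac_peripheral must lie in [0, 1]")
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    rng = default_rng(seed)
    n = int(round(duration * rate))
    n_per = int(round(frac_peripheral * n))

    zoning = zone_partition(ARENA_SIZE[0], ARENA_SIZE[1], *ARENA_GRID)
    cell_w = ARENA_SIZE[0] / zoning.n_cols
    cell_h = ARENA_SIZE[1] / zoning.n_rows
    per_cells = np.argwhere(zoning.peripheral_mask)
    cen_cells = np.argwhere(~zoning.peripheral_mask)

    def _sample(cells: np.ndarray, count: int) -> np.ndarray:
        idx = rng.integers(0, len(cells), size=count)
        rows, cols = cells[idx, 0], cells[idx, 1]
        x = (cols + rng.uniform(0.0, 1.0, count)) * cell_w
        y = (rows + rng.uniform(0.0, 1.0, count)) * cell_h
        return np.column_stack([x, y])

    xy = np.vstack([_sample(per_cells, n_per), _sample(cen_cells, n - n_per)])
    order = rng.permutation(n)
    xy = xy[order]
    return pd.DataFrame(
        {"time_s": np.arange(n) / rate, "x": xy[:, 0], "y": xy[:, 1]}
    )


# ---------------------------------------------------------------------------
# impactor calibration tables
# ---------------------------------------------------------------------------

#: air pressures (psi) at which the impactor was calibrated
DEFAULT_CALIBRATION_PRESSURES = (0.5, 1.0, 1.5, 2.0, 3.0, 5.0, 7.0, 10.0)

#: default quadratic pressure->velocity law (a, b, c) for v = a p^2 + b p + c;
#: spans roughly 0.01-1 J for a 50 g piston over the calibrated pressures
DEFAULT_CALIBRATION_COEFFS = (-0.015, 0.75, 0.30)


def gen_calibration_table(
    pressures=DEFAULT_CALIBRATION_PRESSURES,
    coeffs=DEFAULT_CALIBRATION_COEFFS,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Replicated (pressure, piston exit velocity) calibration measurements.

    Velocity follows the quadratic ``coeffs`` in pressure, plus Gaussian
    measurement noise of standard deviation ``noise_sd`` (m/s); each
    pressure is measured ``n_replicates`` times.  Columns:
    ``pressure_psi``, ``velocity_m_s``, ``replicate``.
    """
    pressures = np.asarray(pressures, dtype=float)
    if pressures.size == 0 or np.any(pressures <= 0):
        raise ValueError("pressures must be non-empty and positive")
    a, b, c = coeffs
    rng = default_rng(seed)
    rows = []
    for p in pressures:
        v_true = a * p**2 + b * p + c
        for rep in range(1, n_replicates + 1):
            v = v_true + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append((p, v, rep))
    return pd.DataFrame(rows, columns=["pressure_psi", "velocity_m_s", "replicate"])
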