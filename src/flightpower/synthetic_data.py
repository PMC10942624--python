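"""Seeded synthetic dove flights: kinematics, aerodynamic forces and muscle traces.

This module stands in for the in vivo recordings the analysis chain was built
for.  It emulates a ringneck dove (*Streptopelia risoria*) in slow flight just
after takeoff: a ~9.8 Hz wingbeat with a 61.8 ms downstroke, an angle-of-attack
waveform with two peaks flanking a pronounced mid-downstroke dip, vertical
aerodynamic force calibrated so its wingbeat average exactly supports
bodyweight, and a pectoralis strain trace that is phase-locked to the wingbeat
(shortening onset mid-upstroke, peak strain 0.23).

All randomness is seeded; with zero per-channel noise (the default) a given
(morphology, params, n_wingbeats, seed) tuple is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import CubicSpline, PchipInterpolator

from .util import G, RHO_AIR, span_average, unit

# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

LANDMARK_NAMES = (
    "XP9", "S7", "shoulder", "wrist", "back", "foot_l", "foot_r",
    "eye_l", "eye_r", "beak_tip", "beak_base", "head",
)


@dataclass
class BirdMorphology:
    """Masses, lengths and muscle architecture for one bird or species.

    Units are SI throughout (kg, m, m**2, Hz, degrees for angles).
    """

    body_mass: float
    wing_mass_single: float
    pect_mass_single: float
    supra_mass_single: float
    wing_radius: float            # shoulder -> wingtip, outstretched
    wingspan_tip_to_tip: float
    radius_of_gyration: float
    wing_area_single: float
    flap_frequency: float
    fiber_rest_length: float      # pectoralis fascicle rest length
    pennation_angle: float        # deg
    pcsa: float                   # physiological cross-sectional area
    name: str = "bird"

    def __post_init__(self) -> None:
        positive = (
            "body_mass", "wing_mass_single", "pect_mass_single",
            "supra_mass_single", "wing_radius", "wingspan_tip_to_tip",
            "radius_of_gyration", "wing_area_single", "flap_frequency",
            "fiber_rest_length", "pcsa",
        )
        for f_ in positive:
            if not getattr(self, f_) > 0:
                raise ValueError(f"BirdMorphology.{f_} must be strictly positive")
        if not self.radius_of_gyration < self.wing_radius:
            raise ValueError("radius_of_gyration must be smaller than wing_radius")

    @property
    def bodyweight(self) -> float:
        """Weight in newtons."""
        return self.body_mass * G


# Dove means (N = 4 birds).  Wing mass is not part of the published
# morphology table; the default is the value used by the distributed wing
# mass model (see docs/methods.md).
_DOVE = dict(
    body_mass=0.1616,
    wing_mass_single=0.0042,
    pect_mass_single=0.01466,
    supra_mass_single=0.00326,
    wing_radius=0.2258,
    wingspan_tip_to_tip=0.5003,
    radius_of_gyration=0.368 * 0.2258,
    wing_area_single=0.01826,
    flap_frequency=9.80,
    fiber_rest_length=0.01712,
    pennation_angle=33.58,
    pcsa=690.1e-6,
    name="dove",
)


def make_morphology(preset: str = "dove", seed: int | None = None,
                    variability: float = 0.0, **overrides) -> BirdMorphology:
    """Build a morphology from a named preset.

    ``preset='dove'`` returns the study-mean dove.  ``preset='parametric'``
    starts from the dove and draws each field from a lognormal perturbation
    with relative sd ``variability`` (seeded), after which explicit keyword
    overrides are applied.
    """
    if preset not in ("dove", "parametric"):
        raise ValueError(f"unknown morphology preset {preset!r}; expected 'dove' or 'parametric'")
    fields = dict(_DOVE)
    if preset == "parametric":
        if variability < 0:
            raise ValueError("variability must be >= 0")
        rng = np.random.default_rng(seed)
        for key, val in fields.items():
            if isinstance(val, float) and variability > 0:
                fields[key] = val * float(rng.lognormal(0.0, variability))
        fields["name"] = "parametric"
    unknown = set(overrides) - set(fields)
    if unknown:
        raise ValueError(f"unknown morphology fields: {sorted(unknown)}")
    fields.update(overrides)
    return BirdMorphology(**fields)


@dataclass
class GenerationParams:
    """Waveform and sampling parameters for one synthetic flight.

    Angle-of-attack control points are (fraction of stroke, degrees) pairs;
    fractions are measured from the start of the downstroke over the full
    wingbeat, matching the convention used to report the in vivo waveform.
    """

    aoa_peak1: tuple[float, float] = (0.071, 54.0)
    aoa_dip: tuple[float, float] = (0.277, 30.5)
    aoa_peak2: tuple[float, float] = (0.494, 68.4)
    aoa_reversal: float = 45.0        # deg at stroke reversals
    aoa_upstroke: float = 40.0        # deg mid-upstroke (high variance in vivo)
    downstroke_duration: float = 0.06180   # s
    upstroke_duration: float = 0.04065     # s
    stroke_amplitude: float = 125.0   # deg, total angular sweep
    stroke_plane_angle: float = 40.0  # deg, plane inclination from horizontal
    deviation_amplitude: float = 4.0  # deg
    forward_speed: float = 1.23       # m/s
    strain_max: float = 0.23
    strain_min: float = -0.05
    shortening_onset: float = 0.80    # stroke fraction, mid-upstroke
    strain_creep: float = 0.12        # fraction of the excursion shortened before
                                      # the downstroke (isometric-like pre-tension)
    strain_stop: float = 0.88         # shortening complete at this fraction of the
                                      # downstroke (velocity zero before upstroke)
    strain_arrest_ramp: float = 0.05  # falling ramp of the fiber-rate profile
    upstroke_fold: float = 0.84       # wingtip radius factor mid-upstroke
    fold_start: float = 0.50          # stroke fraction where folding begins
    fold_min_at: float = 0.80         # maximally folded mid-upstroke
    fold_end: float = 1.15            # fully re-extended early-mid downstroke (wraps)
    stroke_accel_ramp: float = 0.28   # downstroke: acceleration out of the reversal
    stroke_decel_ramp: float = 0.30   # downstroke: deceleration in the last third
    upstroke_ramp: float = 0.45       # upstroke: near-sinusoidal speed profile
    cl_max: float = 1.8               # quasi-steady polar: CL = cl_max sin(2a)
    cd_min: float = 0.30              # CD = cd_min + cd_amp sin(a)^2
    cd_amp: float = 1.05
    upstroke_force_factor: float = 0.12  # force attenuation of the feathered upstroke
    cop_fraction: float = 0.7         # spanwise station of the reference section
    noise_sd: dict = field(default_factory=lambda: {"landmarks": 0.0, "forces": 0.0, "muscle": 0.0})
    sample_rates: dict = field(default_factory=lambda: {"landmarks": 1000.0, "forces": 2000.0, "muscle": 10000.0})

    def __post_init__(self) -> None:
        fracs = [self.aoa_peak1[0], self.aoa_dip[0], self.aoa_peak2[0]]
        if not all(0.0 < f_ < 1.0 for f_ in fracs):
            raise ValueError("angle-of-attack control fractions must lie in (0, 1)")
        if not fracs == sorted(fracs) or len(set(fracs)) != 3:
            raise ValueError("angle-of-attack control fractions out of order")
        if self.downstroke_duration <= 0 or self.upstroke_duration <= 0:
            raise ValueError("stroke durations must be positive")
        for name, rate in self.sample_rates.items():
            if rate <= 0:
                raise ValueError(f"sample rate for {name!r} must be positive")
        if not 0 < self.upstroke_fold <= 1:
            raise ValueError("upstroke_fold must lie in (0, 1]")

    @property
    def period(self) -> float:
        return self.downstroke_duration + self.upstroke_duration

    @property
    def downstroke_fraction(self) -> float:
        return self.downstroke_duration / self.period


@dataclass
class FlightRecording:
    """One synthetic flight: raw traces plus the generating configuration.

    ``truth`` carries generator-internal ground truth (waveforms, per-wing 3D
    forces, calibration constants) for validation; it is not written to disk.
    """

    landmarks: pd.DataFrame
    forces: pd.DataFrame
    muscle: pd.DataFrame
    morphology: BirdMorphology
    params: GenerationParams
    n_wingbeats: int
    seed: int
    truth: dict = field(default_factory=dict, repr=False)


# --------------------------------------------------------------------------
# waveform primitives
# --------------------------------------------------------------------------

def _plateau_profile(xi: np.ndarray, ramp: float,
                     ramp_down: float | None = None) -> np.ndarray:
    """Smooth velocity profile on [0, 1]: quarter-sine ramps around a plateau.

    Zero value at both endpoints with maximal slope there, as in simple
    harmonic motion: stroke reversals carry peak angular acceleration.
    ``ramp``/``ramp_down`` are the rise and fall widths (fall defaults to
    the rise).
    """
    xi = np.asarray(xi, dtype=float)
    r1 = ramp
    r2 = ramp if ramp_down is None else ramp_down
    v = np.ones_like(xi)
    lo = xi < r1
    hi = xi > 1.0 - r2
    v[lo] = np.sin(0.5 * np.pi * xi[lo] / r1)
    v[hi] = np.sin(0.5 * np.pi * (1.0 - xi[hi]) / r2)
    return v


def _plateau_position(xi: np.ndarray, ramp: float,
                      ramp_down: float | None = None) -> np.ndarray:
    """Normalized integral of :func:`_plateau_profile` (0 at xi=0, 1 at xi=1)."""
    xi = np.asarray(xi, dtype=float)
    r1 = ramp
    r2 = ramp if ramp_down is None else ramp_down
    c = 2.0 / np.pi
    total = 1.0 - (1.0 - c) * (r1 + r2)
    pos = np.empty_like(xi)
    lo = xi < r1
    hi = xi > 1.0 - r2
    mid = ~(lo | hi)
    pos[lo] = c * r1 * (1.0 - np.cos(0.5 * np.pi * xi[lo] / r1))
    pos[mid] = c * r1 + (xi[mid] - r1)
    xr = 1.0 - xi[hi]
    pos[hi] = total - c * r2 * (1.0 - np.cos(0.5 * np.pi * xr / r2))
    return pos / total


def stroke_phase(t: np.ndarray, params: GenerationParams) -> np.ndarray:
    """Stroke fraction in [0, 1): 0 at each downstroke start."""
    return np.mod(np.asarray(t, dtype=float), params.period) / params.period


def stroke_angle_waveform(phi: np.ndarray, params: GenerationParams) -> np.ndarray:
    """Stroke angle (deg): +A/2 at downstroke start, -A/2 at stroke reversal.

    The downstroke velocity profile is asymmetric: a brief acceleration out
    of the top reversal, a broad speed maximum around mid-downstroke, and a
    deceleration spread over the second half of the downstroke.
    """
    phi = np.asarray(phi, dtype=float)
    a = params.stroke_amplitude
    fd = params.downstroke_fraction
    theta = np.empty_like(phi)
    down = phi < fd
    xi_d = phi[down] / fd
    theta[down] = a / 2 - a * _plateau_position(
        xi_d, params.stroke_accel_ramp, params.stroke_decel_ramp)
    xi_u = (phi[~down] - fd) / (1.0 - fd)
    theta[~down] = -a / 2 + a * _plateau_position(xi_u, params.upstroke_ramp)
    return theta


def fold_waveform(phi: np.ndarray, params: GenerationParams) -> np.ndarray:
    """Wingtip radius factor through the stroke.

    The wing folds inward starting late downstroke, is maximally flexed
    mid-upstroke, and re-extends through the early downstroke, so span and
    area peak mid-downstroke.  Smooth (C1) everywhere.
    """
    phi = np.mod(np.asarray(phi, dtype=float), 1.0)
    s, m, e = params.fold_start, params.fold_min_at, params.fold_end
    depth = 1.0 - params.upstroke_fold
    # unwrap the fold interval [s, e] (e may exceed 1)
    x = np.where(phi < s, phi + 1.0, phi)
    bump = np.zeros_like(x)
    rising = (x >= s) & (x < m)
    falling = (x >= m) & (x < e)
    bump[rising] = np.sin(0.5 * np.pi * (x[rising] - s) / (m - s)) ** 2
    bump[falling] = np.sin(0.5 * np.pi * (e - x[falling]) / (e - m)) ** 2
    return 1.0 - depth * bump


def aoa_waveform(phi: np.ndarray, params: GenerationParams) -> np.ndarray:
    """Angle of attack (deg) through the stroke via periodic monotone splines.

    Passes exactly through the three configured (fraction, angle) control
    points, so the waveform attains the configured dip at the configured
    stroke fraction.
    """
    fd = params.downstroke_fraction
    knots_x = np.array([0.0, params.aoa_peak1[0], params.aoa_dip[0],
                        params.aoa_peak2[0], fd, (fd + 1.0) / 2.0])
    knots_y = np.array([params.aoa_reversal, params.aoa_peak1[1], params.aoa_dip[1],
                        params.aoa_peak2[1], params.aoa_reversal, params.aoa_upstroke])
    # periodic extension for smooth wrap-around
    x = np.concatenate([knots_x - 1.0, knots_x, knots_x + 1.0])
    y = np.tile(knots_y, 3)
    return PchipInterpolator(x, y)(np.mod(np.asarray(phi, dtype=float), 1.0))


def strain_waveform(phi: np.ndarray, params: GenerationParams) -> np.ndarray:
    """Pectoralis fiber strain through the stroke.

    The fiber length is mechanically slaved to the wing stroke during the
    downstroke (the pectoralis shortens as the humerus depresses, so the
    shortening velocity tracks wing angular speed and peaks mid-downstroke).
    Shortening onsets earlier, mid-upstroke, as a slow quasi-isometric creep
    (series compliance while force develops); strain peaks at ``strain_max``
    at the onset and re-lengthening occupies the early upstroke.
    """
    phi = np.mod(np.asarray(phi, dtype=float), 1.0)
    fd = params.downstroke_fraction
    on = params.shortening_onset
    ds = params.strain_max - params.strain_min
    creep = params.strain_creep * ds
    top = params.strain_max - creep     # strain at the start of the downstroke
    s = np.empty_like(phi)
    down = phi < fd
    xi_d = np.minimum(phi[down] / (fd * params.strain_stop), 1.0)
    s[down] = top - (top - params.strain_min) * _plateau_position(
        xi_d, params.stroke_accel_ramp / params.strain_stop,
        params.strain_arrest_ramp)
    leng = (phi >= fd) & (phi < on)
    xi_l = (phi[leng] - fd) / (on - fd)
    s[leng] = params.strain_min + (params.strain_max - params.strain_min) \
        * 0.5 * (1.0 - np.cos(np.pi * xi_l))
    cr = phi >= on
    xi_c = (phi[cr] - on) / (1.0 - on)
    s[cr] = params.strain_max - creep * 0.5 * (1.0 - np.cos(np.pi * xi_c))
    return s


# --------------------------------------------------------------------------
# 3D geometry of the flapping wing
# --------------------------------------------------------------------------

_WRIST_FRACTION = 0.45  # wrist station along the shoulder->tip line


def _plane_basis(params: GenerationParams):
    chi = np.deg2rad(params.stroke_plane_angle)
    n_hat = np.array([np.sin(chi), 0.0, np.cos(chi)])     # plane normal
    e_hat = np.array([-np.cos(chi), 0.0, np.sin(chi)])    # in-plane, up-back
    return n_hat, e_hat


def _wing_geometry(t: np.ndarray, morph: BirdMorphology, params: GenerationParams):
    """Left-wing span direction, fold factor and shoulder position over time."""
    phi = stroke_phase(t, params)
    theta = np.deg2rad(stroke_angle_waveform(phi, params))
    delta = np.deg2rad(params.deviation_amplitude * np.sin(2 * np.pi * phi))
    rho = fold_waveform(phi, params)
    n_hat, e_hat = _plane_basis(params)
    y_hat = np.array([0.0, 1.0, 0.0])
    u_hat = (np.cos(delta)[:, None]
             * (np.cos(theta)[:, None] * y_hat + np.sin(theta)[:, None] * e_hat)
             + np.sin(delta)[:, None] * n_hat)
    shoulder = np.column_stack([
        params.forward_speed * t,
        np.full_like(t, 0.02),
        np.full_like(t, 1.0),
    ])
    return phi, u_hat, rho, shoulder, n_hat


def _station_velocity(t, shoulder, u_hat, rho, radius):
    pos = shoulder + (radius * rho)[:, None] * u_hat
    vel = np.gradient(pos, t, axis=0)
    return pos, vel


# --------------------------------------------------------------------------
# flight generation
# --------------------------------------------------------------------------

def generate_flight(morph: BirdMorphology, params: GenerationParams | None = None,
                    n_wingbeats: int = 3, seed: int = 0) -> FlightRecording:
    """Generate one synthetic flight with ``n_wingbeats`` full wingbeats.

    The vertical force trace is scaled so that its average over the whole
    (integer-wingbeat) recording equals bodyweight exactly on the written
    grid — the calibration contract every downstream stage relies on.
    """
    if params is None:
        params = GenerationParams()
    if n_wingbeats < 1:
        raise ValueError("n_wingbeats must be >= 1")
    rng = np.random.default_rng(seed)
    T = params.period
    t_total = n_wingbeats * T

    def grid(rate):
        # one sample past the last full wingbeat so integer-wingbeat
        # averages are defined on every channel's grid
        n = int(np.floor(t_total * rate)) + 2
        return np.arange(n) / rate

    # ---- landmarks (structured-light rate) --------------------------------
    t_lm = grid(params.sample_rates["landmarks"])
    phi, u_hat, rho, shoulder, n_hat = _wing_geometry(t_lm, morph, params)
    R = morph.wing_radius
    wrist = shoulder + _WRIST_FRACTION * R * u_hat
    tip = shoulder + (R * rho)[:, None] * u_hat

    # chord construction at the outer-wing section: the trailing-edge landmark
    # (seventh secondary) is placed so the angle between the chord line and the
    # local velocity equals the configured angle-of-attack waveform.
    sec_base, sec_vel = _station_velocity(t_lm, shoulder, u_hat, rho, 0.55 * R)
    v_hat, w_hat = _section_frame(sec_vel, u_hat)
    alpha = np.deg2rad(aoa_waveform(phi, params))
    chord_te = -(np.cos(alpha)[:, None] * v_hat + np.sin(alpha)[:, None] * w_hat)
    chord_len = 0.8 * morph.wing_area_single / morph.wing_radius
    s7 = sec_base + chord_len * chord_te

    body = {
        "back": shoulder + np.array([-0.02, -0.02, -0.01]),
        "head": shoulder + np.array([0.05, -0.02, 0.03]),
        "eye_l": shoulder + np.array([0.045, -0.005, 0.025]),
        "eye_r": shoulder + np.array([0.045, -0.035, 0.025]),
        "beak_tip": shoulder + np.array([0.085, -0.02, 0.02]),
        "beak_base": shoulder + np.array([0.06, -0.02, 0.022]),
        "foot_l": shoulder + np.array([-0.03, 0.0, -0.06]),
        "foot_r": shoulder + np.array([-0.03, -0.04, -0.06]),
    }
    cols = {"time": t_lm}
    coords = {"XP9": tip, "S7": s7, "shoulder": shoulder, "wrist": wrist, **body}
    sd_lm = params.noise_sd.get("landmarks", 0.0)
    for name in LANDMARK_NAMES:
        arr = coords[name]
        if sd_lm > 0:
            arr = arr + rng.normal(0.0, sd_lm, arr.shape)
        for i, ax in enumerate("xyz"):
            cols[f"{name}_{ax}"] = arr[:, i]
    landmarks = pd.DataFrame(cols)

    # ---- forces (force-platform rate) -------------------------------------
    t_f = grid(params.sample_rates["forces"])
    phi_f, u_f, rho_f, sh_f, _ = _wing_geometry(t_f, morph, params)
    _, v_ref = _station_velocity(t_f, sh_f, u_f, rho_f, params.cop_fraction * R)
    v_hat_f, w_hat_f = _section_frame(v_ref, u_f)
    alpha_f = np.deg2rad(aoa_waveform(phi_f, params))
    q = 0.5 * RHO_AIR * np.sum(v_ref ** 2, axis=1)
    s_eff = morph.wing_area_single * rho_f
    cl = params.cl_max * np.sin(2 * alpha_f)
    cd = params.cd_min + params.cd_amp * np.sin(alpha_f) ** 2
    # feathered-upstroke attenuation (through-flow between splayed feathers)
    fd = params.downstroke_fraction
    envelope = np.ones_like(phi_f)
    up = phi_f >= fd
    xi = (phi_f[up] - fd) / (1.0 - fd)
    envelope[up] = 1.0 - (1.0 - params.upstroke_force_factor) * np.sin(np.pi * xi) ** 0.5
    # unit drag opposes span-perpendicular velocity; lift completes the triad
    v_perp = v_ref - np.sum(v_ref * u_f, axis=1)[:, None] * u_f
    d_hat = -unit(v_perp)
    l_hat = unit(np.cross(u_f, d_hat))
    l_hat *= np.sign(l_hat[:, 2:3] + 1e-300)  # lift points upward
    lift_mag = q * s_eff * cl * envelope
    drag_mag = q * s_eff * cd * envelope
    f_left = lift_mag[:, None] * l_hat + drag_mag[:, None] * d_hat
    # mirrored right wing: x and z double, lateral components cancel
    fx_net = 2.0 * f_left[:, 0]
    fz_net = 2.0 * f_left[:, 2]
    k = morph.bodyweight / span_average(t_f, fz_net, t_total)
    fx_net, fz_net, f_left = k * fx_net, k * fz_net, k * f_left
    lift_mag, drag_mag = k * lift_mag, k * drag_mag
    sd_f = params.noise_sd.get("forces", 0.0)
    forces = pd.DataFrame({
        "time": t_f,
        "Fx": fx_net + (rng.normal(0.0, sd_f, t_f.shape) if sd_f > 0 else 0.0),
        "Fz": fz_net + (rng.normal(0.0, sd_f, t_f.shape) if sd_f > 0 else 0.0),
    })

    # ---- muscle (sonomicrometry / EMG rate) -------------------------------
    t_m = grid(params.sample_rates["muscle"])
    phi_m = stroke_phase(t_m, params)
    strain = strain_waveform(phi_m, params)
    fiber_length = morph.fiber_rest_length * (1.0 + strain)
    emg = _emg_envelope(phi_m, params)
    sd_m = params.noise_sd.get("muscle", 0.0)
    muscle = pd.DataFrame({
        "time": t_m,
        "fiber_length_m": fiber_length + (rng.normal(0.0, sd_m, t_m.shape) if sd_m > 0 else 0.0),
        "emg_mV": emg,
    })

    truth = {
        "force_scale": k,
        "stroke_plane_normal": n_hat,
        "stroke_angle_deg": stroke_angle_waveform(phi, params),
        "aoa_deg": np.rad2deg(alpha),
        "f_left_3d": f_left,
        "lift_left": lift_mag,
        "drag_left": drag_mag,
        "fz_cycle_mean": span_average(t_f, fz_net, t_total),
        "phi_landmarks": phi,
        "phi_forces": phi_f,
    }
    return FlightRecording(landmarks=landmarks, forces=forces, muscle=muscle,
                           morphology=morph, params=params,
                           n_wingbeats=n_wingbeats, seed=seed, truth=truth)


def _section_frame(vel: np.ndarray, span_hat: np.ndarray):
    """Span-perpendicular flow frame (v_hat, w_hat) with gaps bridged.

    Near stroke reversal the velocity direction is ill-defined; those samples
    inherit smoothly interpolated directions so landmark traces stay smooth.
    """
    speed = np.linalg.norm(vel, axis=1)
    ok = speed > 0.05 * speed.max()
    v_hat = np.empty_like(vel)
    v_hat[ok] = unit(vel[ok])
    idx = np.arange(len(vel))
    for i in range(3):
        v_hat[~ok, i] = np.interp(idx[~ok], idx[ok], v_hat[ok, i], period=len(vel))
    v_hat = unit(v_hat)
    w_hat = unit(np.cross(span_hat, v_hat))
    w_hat *= np.sign(w_hat[:, 2:3] + 1e-300)  # trailing edge above the path
    return v_hat, w_hat


def _emg_envelope(phi: np.ndarray, params: GenerationParams) -> np.ndarray:
    """EMG envelope (mV): onset at shortening onset, offset mid-downstroke."""
    on = params.shortening_onset
    off = 0.5 * params.downstroke_fraction
    span = 1.0 + off - on
    x = np.mod(phi - on, 1.0) / span
    env = np.where(x <= 1.0, np.sin(np.pi * np.clip(x, 0.0, 1.0)) ** 2, 0.0)
    return 1.0 * env


# --------------------------------------------------------------------------
# bird populations for the scaling analysis
# --------------------------------------------------------------------------

DEFAULT_ALLOMETRY = {
    # exponent of each field versus body mass, anchored at the dove
    "wing_radius": 0.39,
    "wingspan_tip_to_tip": 0.39,
    "radius_of_gyration": 0.39,
    "wing_area_single": 0.72,
    "wing_mass_single": 1.10,
    "pect_mass_single": 1.05,
    "supra_mass_single": 1.05,
    "flap_frequency": -0.28,
    "fiber_rest_length": 0.35,
    "pcsa": 0.70,
}


def generate_bird_population(n: int, mass_range: tuple[float, float],
                             allometry: dict | None = None, seed: int = 0,
                             noise_sd: float = 0.05) -> list[BirdMorphology]:
    """Synthesize ``n`` bird morphologies on power-law allometries.

    Body masses are log-spaced and span the range endpoints exactly; every
    other field follows ``value_dove * (m / m_dove) ** exponent`` with
    multiplicative lognormal noise of relative sd ``noise_sd``.
    """
    if n < 2:
        raise ValueError("population size must be >= 2")
    lo, hi = mass_range
    if not lo < hi:
        raise ValueError("degenerate mass range: low >= high")
    if lo <= 0.005 or hi >= 5.0:
        raise ValueError("mass range must lie within (0.005, 5) kg")
    expo = dict(DEFAULT_ALLOMETRY)
    if allometry:
        expo.update(allometry)
    rng = np.random.default_rng(seed)
    masses = np.geomspace(lo, hi, n)
    birds = []
    for i, m in enumerate(masses):
        ratio = m / _DOVE["body_mass"]
        fields = {"body_mass": float(m), "name": f"bird_{i:03d}",
                  "pennation_angle": _DOVE["pennation_angle"]}
        for key, exponent in expo.items():
            noise = float(rng.lognormal(0.0, noise_sd)) if noise_sd > 0 else 1.0
            fields[key] = _DOVE[key] * ratio ** exponent * noise
        # keep the gyration radius inside the wing even under noise
        fields["radius_of_gyration"] = min(
            fields["radius_of_gyration"], 0.95 * fields["wing_radius"])
        birds.append(BirdMorphology(**fields))
    return birds


# --------------------------------------------------------------------------
# disk round trip
# --------------------------------------------------------------------------

def write_recording(rec: FlightRecording, outdir: str | Path) -> Path:
    """Write one flight as the plain-text directory layout used by the CLI."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rec.landmarks.to_csv(outdir / "landmarks.csv", index=False)
    rec.forces.to_csv(outdir / "forces.csv", index=False)
    rec.muscle.to_csv(outdir / "muscle.csv", index=False)
    with open(outdir / "morphology.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(rec.morphology), fh)
    params = dataclasses.asdict(rec.params)
    params.update(n_wingbeats=rec.n_wingbeats, seed=rec.seed)
    with open(outdir / "params.yaml", "w") as fh:
        yaml.safe_dump(_yaml_friendly(params), fh)
    return outdir


def _yaml_friendly(obj):
    if isinstance(obj, dict):
        return {k: _yaml_friendly(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_friendly(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def read_morphology(path: str | Path) -> BirdMorphology:
    with open(path) as fh:
        return BirdMorphology(**yaml.safe_load(fh))
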