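"""Wingbeat kinematics from landmark trajectories.

Derives the stroke plane, stroke/deviation angles, angle of attack, wing
velocity, stroke phases, and the discretized (20-point-mass) wing model from
the 12 tracked landmarks.

Coordinate convention: x = flight direction (back to front), z = up,
y = lateral (right to left), right-handed.  All angles in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.signal import find_peaks
from scipy.sparse.linalg import spsolve

from .synthetic_data import BirdMorphology
from .util import unit

#: samples with |v| below this fraction of peak wing speed have no
#: well-defined flow direction (stroke reversal) and are masked
VELOCITY_MASK_FRACTION = 0.05

#: wrist station along the shoulder->tip line used by the V-path model
WRIST_FRACTION = 0.45


# --------------------------------------------------------------------------
# smoothing and differentiation
# --------------------------------------------------------------------------

def smooth_trajectories(raw: np.ndarray, smoothing_parameter: float) -> np.ndarray:
    """Whittaker difference-penalty smoother applied per column.

    Minimizes ||y - z||^2 + lam * ||D2 z||^2 (penalized least squares with a
    second-order difference penalty); lam -> 0 returns the input.
    """
    if smoothing_parameter < 0:
        raise ValueError("smoothing parameter must be positive")
    y = np.atleast_2d(np.asarray(raw, dtype=float).T).T
    if not np.all(np.isfinite(y)):
        raise ValueError("missing samples must be interpolated before smoothing")
    if smoothing_parameter == 0:
        return np.asarray(raw, dtype=float)
    n = y.shape[0]
    d2 = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    a = sp.eye(n) + smoothing_parameter * (d2.T @ d2)
    z = spsolve(a.tocsc(), y)
    return z.reshape(np.asarray(raw).shape)


def differentiate(pos: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Second-order central differences (one-sided at the ends)."""
    return np.gradient(np.asarray(pos, dtype=float), np.asarray(t, dtype=float), axis=0)


# --------------------------------------------------------------------------
# stroke plane and stroke angles
# --------------------------------------------------------------------------

def fit_stroke_plane(tip_vectors: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares plane through the shoulder for the shoulder->tip path.

    Returns the unit plane normal and the plane's inclination to the world
    horizontal in degrees (90 deg for a vertical plane).
    """
    v = np.asarray(tip_vectors, dtype=float)
    if v.shape[0] < 3:
        raise ValueError("need at least 3 tip vectors to fit a stroke plane")
    _, s, vt = np.linalg.svd(v, full_matrices=False)
    if s[1] < 1e-9 * s[0]:
        raise ValueError("tip vectors are collinear; stroke plane is degenerate")
    normal = vt[2]
    if normal[2] < 0:
        normal = -normal
    inclination = float(np.degrees(np.arccos(np.clip(abs(normal[2]), 0.0, 1.0))))
    return normal, inclination


def compute_stroke_angles(tip_vectors: np.ndarray,
                          plane_normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane stroke angle and out-of-plane deviation angle (deg, unwrapped).

    The in-plane reference axis is the lateral (y) axis projected onto the
    stroke plane, so a fully outstretched wing at mid-stroke reads ~0 deg.
    """
    v = np.asarray(tip_vectors, dtype=float)
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-length tip vector")
    n = unit(np.asarray(plane_normal, dtype=float))
    y_axis = np.array([0.0, 1.0, 0.0])
    e1 = unit(y_axis - np.dot(y_axis, n) * n)
    e2 = np.cross(n, e1)
    r_hat = v / norms[:, None]
    theta = np.degrees(np.unwrap(np.arctan2(r_hat @ e2, r_hat @ e1)))
    deviation = np.degrees(np.arcsin(np.clip(r_hat @ n, -1.0, 1.0)))
    return theta, deviation


def compute_angle_of_attack(chord_vector: np.ndarray,
                            local_velocity: np.ndarray,
                            speed_threshold: float | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Unsigned angle between the wing chord line and the local velocity.

    ``chord_vector`` points leading edge -> trailing edge; the angle is zero
    when the chord streams with the flow (trailing edge downstream).  Samples
    with |v| below ``speed_threshold`` (default: 5% of the peak speed) are
    masked and returned as NaN.

    Returns ``(aoa_deg, valid_mask)``.
    """
    c = np.atleast_2d(np.asarray(chord_vector, dtype=float))
    v = np.atleast_2d(np.asarray(local_velocity, dtype=float))
    speed = np.linalg.norm(v, axis=1)
    if speed_threshold is None:
        speed_threshold = VELOCITY_MASK_FRACTION * speed.max()
    c_norm = np.linalg.norm(c, axis=1)
    valid = (speed > max(speed_threshold, 1e-12)) & (c_norm > 1e-12)
    aoa = np.full(len(c), np.nan)
    cosang = np.sum(-c[valid] * v[valid], axis=1) / (c_norm[valid] * speed[valid])
    aoa[valid] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return aoa, valid


def detect_stroke_phases(stroke_angle: np.ndarray, time: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int, int]]]:
    """Label each sample downstroke/upstroke and locate wingbeat boundaries.

    The downstroke runs from a stroke-angle maximum to the following minimum.
    Returns ``(phase_labels, stroke_fraction, wingbeats)`` where ``wingbeats``
    is a list of index triples (downstroke start, reversal, wingbeat end).
    Stroke fraction is 0 at each downstroke start and NaN outside complete
    wingbeats.
    """
    theta = np.asarray(stroke_angle, dtype=float)
    t = np.asarray(time, dtype=float)
    amp = theta.max() - theta.min()
    if amp < 1e-9:
        raise ValueError("stroke angle is constant; no oscillation to segment")
    prom = 0.25 * amp
    maxima, _ = find_peaks(theta, prominence=prom)
    minima, _ = find_peaks(-theta, prominence=prom)
    if len(maxima) + len(minima) < 2:
        raise ValueError("fewer than two stroke-angle extrema found")
    labels = np.empty(len(theta), dtype=object)
    # between any extremum pair, sign of local trend decides the phase
    extrema = np.sort(np.concatenate([maxima, minima, [0, len(theta) - 1]]))
    for a, b in zip(extrema[:-1], extrema[1:]):
        if b <= a:
            continue
        labels[a:b + 1] = "down" if theta[b] <= theta[a] else "up"
    fraction = np.full(len(theta), np.nan)
    wingbeats = []
    for a, b in zip(maxima[:-1], maxima[1:]):
        inner = minima[(minima > a) & (minima < b)]
        if len(inner) == 0:
            continue
        rev = int(inner[0])
        fraction[a:b + 1] = (t[a:b + 1] - t[a]) / (t[b] - t[a])
        wingbeats.append((int(a), rev, int(b)))
    if not wingbeats:
        raise ValueError("no complete wingbeat (maximum-minimum-maximum) found")
    return labels, fraction, wingbeats


def compute_advance_ratio(forward_speed: float, wingtip_speed: np.ndarray) -> float:
    """Forward flight speed over mean wingtip speed (0 when hovering)."""
    v = np.asarray(wingtip_speed, dtype=float)
    mean_tip = float(np.mean(v))
    if mean_tip <= 0:
        raise ValueError("wingtip speed must be positive")
    return float(forward_speed) / mean_tip


# --------------------------------------------------------------------------
# distributed wing mass
# --------------------------------------------------------------------------

def spanwise_mass_profile(n_points: int = 20, decay: float = 3.0) -> np.ndarray:
    """Normalized spanwise mass weights, monotonically decreasing to the tip.

    An exponential decay approximating published avian wing mass
    distributions; yields a radius of gyration near 0.37 of wing length for
    an outstretched wing.
    """
    x = (np.arange(n_points) + 0.5) / n_points
    w = np.exp(-decay * x)
    return w / w.sum()


@dataclass
class WingPointMassModel:
    """Wing mass discretized as point masses along the shoulder-wrist-tip path."""

    masses: np.ndarray           # (n_points,)
    stations: np.ndarray         # (n_points,) arc-length fractions
    positions: np.ndarray        # (n_t, n_points, 3)
    velocities: np.ndarray
    accelerations: np.ndarray
    time: np.ndarray

    def radius_of_gyration(self, origin: np.ndarray, frame: int | None = None) -> float:
        """sqrt(sum m r^2 / sum m) about ``origin`` at one time frame."""
        i = 0 if frame is None else frame
        r = np.linalg.norm(self.positions[i] - np.asarray(origin), axis=1)
        return float(np.sqrt(np.sum(self.masses * r ** 2) / np.sum(self.masses)))

    def kinetic_energy(self) -> np.ndarray:
        """Total kinetic energy series of the point masses."""
        return 0.5 * np.einsum("p,tpi,tpi->t", self.masses,
                               self.velocities, self.velocities)


def build_point_mass_wing(morph: BirdMorphology, shoulder: np.ndarray,
                          wrist: np.ndarray, tip: np.ndarray, time: np.ndarray,
                          n_points: int = 20,
                          mass_profile: np.ndarray | None = None) -> WingPointMassModel:
    """Place point masses at fixed proportional arc positions on the V-path.

    ``shoulder``, ``wrist`` and ``tip`` are (n_t, 3) trajectories; masses are
    assigned from ``mass_profile`` (default: decreasing exponential)
    normalized to the single-wing mass.
    """
    if morph.wing_mass_single <= 0:
        raise ValueError("wing mass must be positive")
    if mass_profile is None:
        mass_profile = spanwise_mass_profile(n_points)
    mass_profile = np.asarray(mass_profile, dtype=float)
    if len(mass_profile) != n_points or np.any(mass_profile < 0):
        raise ValueError("mass profile must have n_points non-negative weights")
    masses = morph.wing_mass_single * mass_profile / mass_profile.sum()
    stations = (np.arange(n_points) + 0.5) / n_points

    sh = np.asarray(shoulder, dtype=float)
    wr = np.asarray(wrist, dtype=float)
    tp = np.asarray(tip, dtype=float)
    l1 = np.linalg.norm(wr - sh, axis=1)
    l2 = np.linalg.norm(tp - wr, axis=1)
    total = l1 + l2
    arc = stations[None, :] * total[:, None]           # (n_t, n_points)
    on_inner = arc <= l1[:, None]
    frac_inner = arc / np.maximum(l1[:, None], 1e-12)
    frac_outer = (arc - l1[:, None]) / np.maximum(l2[:, None], 1e-12)
    inner_pos = sh[:, None, :] + frac_inner[..., None] * (wr - sh)[:, None, :]
    outer_pos = wr[:, None, :] + frac_outer[..., None] * (tp - wr)[:, None, :]
    positions = np.where(on_inner[..., None], inner_pos, outer_pos)
    velocities = np.gradient(positions, time, axis=0)
    accelerations = np.gradient(velocities, time, axis=0)
    return WingPointMassModel(masses=masses, stations=stations,
                              positions=positions, velocities=velocities,
                              accelerations=accelerations, time=np.asarray(time, float))


@dataclass
class BodyState:
    """Body (minus wings) modeled as a point mass at the trunk landmark."""

    mass: float
    position: np.ndarray
    velocity: np.ndarray
    acceleration: np.ndarray
    time: np.ndarray


def build_body_state(morph: BirdMorphology, back: np.ndarray,
                     time: np.ndarray) -> BodyState:
    pos = np.asarray(back, dtype=float)
    vel = np.gradient(pos, time, axis=0)
    acc = np.gradient(vel, time, axis=0)
    m_b = morph.body_mass - 2.0 * morph.wing_mass_single
    return BodyState(mass=m_b, position=pos, velocity=vel,
                     acceleration=acc, time=np.asarray(time, float))


# --------------------------------------------------------------------------
# full kinematics stage
# --------------------------------------------------------------------------

@dataclass
class WingbeatKinematics:
    """Time-resolved wing kinematics for one (left-wing) recording."""

    time: np.ndarray
    landmarks: dict[str, np.ndarray]
    stroke_plane_normal: np.ndarray
    stroke_plane_angle: float
    stroke_angle: np.ndarray
    deviation_angle: np.ndarray
    angle_of_attack: np.ndarray
    aoa_valid: np.ndarray
    wing_velocity: np.ndarray      # reference-station velocity (cop_fraction * R)
    tip_velocity: np.ndarray
    span_vector: np.ndarray        # unit shoulder->tip
    area_factor: np.ndarray        # instantaneous span extension (|sh->tip| / R)
    phase_labels: np.ndarray
    stroke_fraction: np.ndarray
    wingbeats: list[tuple[int, int, int]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "time": self.time,
            "stroke_angle_deg": self.stroke_angle,
            "deviation_deg": self.deviation_angle,
            "aoa_deg": self.angle_of_attack,
            "aoa_valid": self.aoa_valid.astype(int),
            "phase": self.phase_labels,
            "stroke_fraction": self.stroke_fraction,
            "area_factor": self.area_factor,
        })
        for i, ax in enumerate("xyz"):
            df[f"vwing_{ax}"] = self.wing_velocity[:, i]
            df[f"vtip_{ax}"] = self.tip_velocity[:, i]
            df[f"span_{ax}"] = self.span_vector[:, i]
        return df


def _landmark_array(df: pd.DataFrame, name: str) -> np.ndarray:
    return df[[f"{name}_x", f"{name}_y", f"{name}_z"]].to_numpy(dtype=float)


def analyze_kinematics(landmarks: pd.DataFrame, morph: BirdMorphology,
                       smoothing_parameter: float = 1e-3,
                       reference_station: float = 0.7) -> WingbeatKinematics:
    """Run the full kinematics stage on a landmark table.

    Landmark trajectories are smoothed, the stroke plane fitted, angles and
    velocities derived, and stroke phases segmented.
    """
    t = landmarks["time"].to_numpy(dtype=float)
    lm = {}
    for name in ("XP9", "S7", "shoulder", "wrist", "back", "head"):
        lm[name] = smooth_trajectories(_landmark_array(landmarks, name),
                                       smoothing_parameter)
    tip_rel = lm["XP9"] - lm["shoulder"]
    normal, plane_angle = fit_stroke_plane(tip_rel)
    theta, deviation = compute_stroke_angles(tip_rel, normal)
    labels, fraction, wingbeats = detect_stroke_phases(theta, t)

    span = unit(tip_rel)
    area_factor = np.linalg.norm(tip_rel, axis=1) / morph.wing_radius
    tip_vel = differentiate(lm["XP9"], t)
    # reference aerodynamic station on the shoulder->tip line
    ref_pos = lm["shoulder"] + reference_station * tip_rel
    ref_vel = differentiate(ref_pos, t)

    # chord at the outer wing: S7 relative to its projection on the
    # wrist->tip leading-edge line, pointing leading -> trailing
    le_dir = unit(lm["XP9"] - lm["wrist"])
    rel = lm["S7"] - lm["wrist"]
    foot = lm["wrist"] + np.sum(rel * le_dir, axis=1)[:, None] * le_dir
    chord = lm["S7"] - foot
    sec_station = np.sum((foot - lm["shoulder"]) * span, axis=1)
    sec_vel = differentiate(
        lm["shoulder"] + sec_station[:, None] * span, t)
    aoa, aoa_valid = compute_angle_of_attack(chord, sec_vel)

    return WingbeatKinematics(
        time=t, landmarks=lm, stroke_plane_normal=normal,
        stroke_plane_angle=plane_angle, stroke_angle=theta,
        deviation_angle=deviation, angle_of_attack=aoa, aoa_valid=aoa_valid,
        wing_velocity=ref_vel, tip_velocity=tip_vel, span_vector=span,
        area_factor=area_factor, phase_labels=labels,
        stroke_fraction=fraction, wingbeats=wingbeats)
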