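"""3D aerodynamic force reconstruction, lift/drag decomposition, aero power.

The force platform measures only the horizontal (x) and vertical (z) net
force.  The lateral (y) component is recovered from kinematic direction
constraints: drag points opposite the span-perpendicular wing velocity and
lift is perpendicular to both drag and the span.  Solving the 2x2 system that
matches the measured x and z components then fixes (L, D) and hence the full
3D vector; with bilateral symmetry the lateral components of the two wings
cancel on the body.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .kinematics import WingbeatKinematics
from .synthetic_data import BirdMorphology
from .util import RHO_AIR, resample, unit

FORCE_FILTER_CUTOFF_HZ = 80.0
FORCE_FILTER_ORDER = 8
VELOCITY_MASK_FRACTION = 0.05
DRAG_MASK_FRACTION = 0.01


@dataclass
class ForceTrace:
    """Measured planar forces plus the reconstructed per-wing 3D forces."""

    time: np.ndarray
    measured_xz: np.ndarray      # (n, 2) net (both wings) Fx, Fz
    force_wing: np.ndarray       # (n, 3) single (left) wing
    lift_vec: np.ndarray
    drag_vec: np.ndarray
    lift: np.ndarray             # signed scalar w.r.t. wing surface normal
    drag: np.ndarray             # >= 0
    valid: np.ndarray
    bodyweight: float

    @property
    def force_net(self) -> np.ndarray:
        """Both wings combined; lateral components cancel by symmetry."""
        out = 2.0 * self.force_wing.copy()
        out[:, 1] = 0.0
        return out


def filter_forces(forces: pd.DataFrame, cutoff_hz: float = FORCE_FILTER_CUTOFF_HZ,
                  order: int = FORCE_FILTER_ORDER) -> pd.DataFrame:
    """Zero-phase low-pass Butterworth, matching the plate's 80 Hz cutoff."""
    t = forces["time"].to_numpy(dtype=float)
    fs = 1.0 / np.median(np.diff(t))
    sos = butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    out = forces.copy()
    for col in ("Fx", "Fz"):
        out[col] = sosfiltfilt(sos, forces[col].to_numpy(dtype=float))
    return out


def _direction_triad(wing_velocity: np.ndarray, span_vector: np.ndarray,
                     surface_normal: np.ndarray | None = None):
    """Unit drag/lift directions and the validity mask.

    Drag opposes the span-perpendicular velocity; lift is perpendicular to
    both drag and span, signed along the wing surface normal when given.
    """
    v = np.asarray(wing_velocity, dtype=float)
    s = unit(np.asarray(span_vector, dtype=float))
    v_perp = v - np.sum(v * s, axis=1)[:, None] * s
    speed_perp = np.linalg.norm(v_perp, axis=1)
    valid = speed_perp > VELOCITY_MASK_FRACTION * speed_perp.max()
    d_hat = np.zeros_like(v)
    d_hat[valid] = -v_perp[valid] / speed_perp[valid, None]
    l_hat = unit(np.cross(s, d_hat))
    if surface_normal is not None:
        sign = np.sign(np.sum(l_hat * surface_normal, axis=1))
        sign[sign == 0] = 1.0
        l_hat *= sign[:, None]
    else:
        up = np.sign(l_hat[:, 2])
        up[up == 0] = 1.0
        l_hat *= up[:, None]
    return d_hat, l_hat, valid


def reconstruct_3d_force(measured_xz: np.ndarray, wing_velocity: np.ndarray,
                         span_vector: np.ndarray, bodyweight: float = np.nan,
                         time: np.ndarray | None = None,
                         surface_normal: np.ndarray | None = None) -> ForceTrace:
    """Recover the per-wing 3D force from net x/z forces and kinematics.

    ``measured_xz`` holds the net forces of both wings; each wing carries
    half (bilateral symmetry).  Samples where the 2x2 direction system is
    ill-conditioned (stroke reversal) are masked.
    """
    meas = np.asarray(measured_xz, dtype=float)
    d_hat, l_hat, valid = _direction_triad(wing_velocity, span_vector,
                                           surface_normal)
    n = len(meas)
    lift = np.zeros(n)
    drag = np.zeros(n)
    a = np.stack([np.stack([l_hat[:, 0], d_hat[:, 0]], axis=1),
                  np.stack([l_hat[:, 2], d_hat[:, 2]], axis=1)], axis=1)
    det = a[:, 0, 0] * a[:, 1, 1] - a[:, 0, 1] * a[:, 1, 0]
    valid = valid & (np.abs(det) > 1e-6)
    rhs = 0.5 * meas  # per wing
    lift[valid] = (rhs[valid, 0] * a[valid, 1, 1]
                   - rhs[valid, 1] * a[valid, 0, 1]) / det[valid]
    drag[valid] = (rhs[valid, 1] * a[valid, 0, 0]
                   - rhs[valid, 0] * a[valid, 1, 0]) / det[valid]
    lift_vec = lift[:, None] * l_hat
    drag_vec = drag[:, None] * d_hat
    force = lift_vec + drag_vec
    t = np.arange(n, dtype=float) if time is None else np.asarray(time, float)
    return ForceTrace(time=t, measured_xz=meas, force_wing=force,
                      lift_vec=lift_vec, drag_vec=drag_vec, lift=lift,
                      drag=drag, valid=valid, bodyweight=bodyweight)


def decompose_lift_drag(force_3d: np.ndarray, wing_velocity: np.ndarray,
                        span_vector: np.ndarray,
                        surface_normal: np.ndarray | None = None
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project a known 3D wing force onto the lift/drag directions.

    Drag is the (non-negative by convention) component opposing the
    span-perpendicular velocity; lift is the signed remainder along the
    lift direction.  Returns ``(lift, drag, valid_mask)``.
    """
    f = np.atleast_2d(np.asarray(force_3d, dtype=float))
    d_hat, l_hat, valid = _direction_triad(
        np.atleast_2d(wing_velocity), np.atleast_2d(span_vector), surface_normal)
    drag = np.sum(f * d_hat, axis=1)
    lift = np.sum(f * l_hat, axis=1)
    return lift, drag, valid


def power_factor(lift: np.ndarray, drag: np.ndarray,
                 dynamic_pressure_ref: np.ndarray | float) -> np.ndarray:
    """Non-dimensional CL^(3/2)/CD; NaN where lift or drag is non-positive.

    ``dynamic_pressure_ref`` is the reference q*S used to form coefficients;
    the location of the power-factor maximum does not depend on it.
    """
    lift = np.asarray(lift, dtype=float)
    drag = np.asarray(drag, dtype=float)
    qs = np.broadcast_to(np.asarray(dynamic_pressure_ref, dtype=float), lift.shape)
    out = np.full(lift.shape, np.nan)
    ok = (lift > 0) & (drag > 0) & (qs > 0)
    cl = lift[ok] / qs[ok]
    cd = drag[ok] / qs[ok]
    out[ok] = cl ** 1.5 / cd
    return out


def aerodynamic_power(drag_vec: np.ndarray, wing_velocity: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Aerodynamic power of one wing and its per-axis split.

    Only drag consumes power: P = -(D . v) >= 0 when drag opposes motion;
    lift is perpendicular to velocity and contributes exactly zero.
    """
    d = np.asarray(drag_vec, dtype=float)
    v = np.asarray(wing_velocity, dtype=float)
    if d.shape != v.shape:
        raise ValueError("drag and velocity traces are not on a common grid")
    per_axis = -d * v
    return per_axis.sum(axis=1), per_axis


@dataclass
class AeroPowerTrace:
    """Aero power (both wings), power factor and lift/drag ratio series."""

    time: np.ndarray
    p_aero_total: np.ndarray
    p_aero_xyz: np.ndarray
    power_factor: np.ndarray
    lift_to_drag: np.ndarray
    valid: np.ndarray


def analyze_aero(forces: pd.DataFrame, kin: WingbeatKinematics,
                 morph: BirdMorphology,
                 prefiltered: bool = False) -> tuple[ForceTrace, AeroPowerTrace]:
    """Full aero stage: filter, resample to the kinematics grid, reconstruct.

    Returns the reconstructed per-wing force trace and the aero power trace
    (both wings).
    """
    if not prefiltered:
        forces = filter_forces(forces)
    t = kin.time
    meas = resample(forces["time"].to_numpy(float),
                    forces[["Fx", "Fz"]].to_numpy(float), t)
    # wing surface normal from span and chord (S7 relative to leading edge)
    chord = kin.landmarks["S7"] - (
        kin.landmarks["wrist"]
        + np.sum((kin.landmarks["S7"] - kin.landmarks["wrist"])
                 * unit(kin.landmarks["XP9"] - kin.landmarks["wrist"]), axis=1)[:, None]
        * unit(kin.landmarks["XP9"] - kin.landmarks["wrist"]))
    normal = unit(np.cross(kin.span_vector, chord))
    flip = np.sign(normal[:, 2])
    flip[flip == 0] = 1.0
    normal *= flip[:, None]  # dorsal side by convention

    trace = reconstruct_3d_force(meas, kin.wing_velocity, kin.span_vector,
                                 bodyweight=np.nan, time=t,
                                 surface_normal=normal)
    p_wing, p_axis = aerodynamic_power(trace.drag_vec, kin.wing_velocity)
    p_total = 2.0 * p_wing
    p_axis = 2.0 * p_axis

    # reference dynamic pressure x area at the radius-of-gyration station
    x_gyr = morph.radius_of_gyration / morph.wing_radius
    sh_v = np.gradient(kin.landmarks["shoulder"], t, axis=0)
    v_gyr = sh_v + x_gyr * (kin.tip_velocity - sh_v)
    qs = (0.5 * RHO_AIR * np.sum(v_gyr ** 2, axis=1)
          * morph.wing_area_single * kin.area_factor)
    pf = power_factor(trace.lift, trace.drag, qs)
    drag_floor = DRAG_MASK_FRACTION * np.nanmax(trace.drag)
    pf[trace.drag < drag_floor] = np.nan
    ld = np.where(trace.valid & (trace.drag > drag_floor),
                  trace.lift / np.where(trace.drag > 0, trace.drag, np.nan), np.nan)
    power = AeroPowerTrace(time=t, p_aero_total=p_total, p_aero_xyz=p_axis,
                           power_factor=pf, lift_to_drag=ld, valid=trace.valid)
    return trace, power


def aero_frame(trace: ForceTrace, power: AeroPowerTrace) -> pd.DataFrame:
    """Tabular aero.csv layout for the pipeline."""
    net = trace.force_net
    df = pd.DataFrame({
        "time": trace.time,
        "Fx": net[:, 0], "Fy": net[:, 1], "Fz": net[:, 2],
        "Fx_wing": trace.force_wing[:, 0],
        "Fy_wing": trace.force_wing[:, 1],
        "Fz_wing": trace.force_wing[:, 2],
        "lift": trace.lift, "drag": trace.drag,
        "power_factor": power.power_factor,
        "p_aero": power.p_aero_total,
        "p_aero_x": power.p_aero_xyz[:, 0],
        "p_aero_y": power.p_aero_xyz[:, 1],
        "p_aero_z": power.p_aero_xyz[:, 2],
        "valid": trace.valid.astype(int),
    })
    for i, ax in enumerate("xyz"):
        df[f"drag_{ax}"] = trace.drag_vec[:, i]
        df[f"lift_{ax}"] = trace.lift_vec[:, i]
    return df
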