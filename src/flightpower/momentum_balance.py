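"""3D angular-momentum balance about the shoulder and the pectoralis pull.

The net torque the flight muscles must exert on the wing is the residual of
the angular-momentum rate of the wing point masses about the shoulder after
subtracting the aerodynamic and gravitational moments.  The shoulder reaction
force produces no moment about the shoulder and the reaction moment is
assumed negligible.

Combining the muscle moment (this balance) with the pectoralis force
magnitude (power balance) yields the pull angle on the humerus; the
perpendicular-to-humerus moment component alone fixes the pull direction and
muscle stress under the assumption that the pectoralis is the only muscle
loading the wing during the downstroke.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import WingPointMassModel
from .util import G, unit

#: default spanwise station of the aerodynamic center of pressure
COP_FRACTION = 0.5
#: default deltopectoral-crest moment arm (m), order-of-magnitude anatomical
DPC_ARM = 0.012
#: fraction of the shoulder->wrist segment taken as the humerus axis length
HUMERUS_FRACTION = 1.0


@dataclass
class MuscleMomentState:
    """Torque balance terms about the (left) shoulder, world frame, N·m."""

    time: np.ndarray
    muscle_moment: np.ndarray         # required flight-muscle torque
    aero_moment: np.ndarray
    inertial_moment_rate: np.ndarray  # dH/dt of the wing point masses
    gravity_moment: np.ndarray


def required_muscle_moment(wing: WingPointMassModel, force_wing: np.ndarray,
                           shoulder: np.ndarray, tip: np.ndarray,
                           cop_fraction: float = COP_FRACTION,
                           g: float = G) -> MuscleMomentState:
    """Balance dH/dt against aerodynamic and gravity moments about the shoulder.

    The aerodynamic force acts along the shoulder->tip line at
    ``cop_fraction`` of the span.  The residual is the muscle moment.
    """
    t = wing.time
    f = np.asarray(force_wing, dtype=float)
    sh = np.asarray(shoulder, dtype=float)
    if f.shape != sh.shape:
        raise ValueError("force and shoulder traces are not on a common grid")
    r = wing.positions - sh[:, None, :]
    dh_dt = np.einsum("p,tpi->ti", wing.masses,
                      np.cross(r, wing.accelerations))
    r_cop = cop_fraction * (np.asarray(tip, float) - sh)
    m_aero = np.cross(r_cop, f)
    g_vec = np.array([0.0, 0.0, -g])
    m_grav = np.einsum("p,tpi->ti", wing.masses, np.cross(r, g_vec[None, None, :]))
    m_musc = dh_dt - m_aero - m_grav
    return MuscleMomentState(time=t, muscle_moment=m_musc, aero_moment=m_aero,
                             inertial_moment_rate=dh_dt, gravity_moment=m_grav)


def humerus_axis(shoulder: np.ndarray, wrist: np.ndarray) -> np.ndarray:
    """Unit humerus direction modeled along the shoulder->wrist landmark line."""
    return unit(np.asarray(wrist, float) - np.asarray(shoulder, float))


def pull_angle(muscle_moment: np.ndarray, humerus: np.ndarray,
               force_magnitude: np.ndarray, moment_arm: float = DPC_ARM,
               moment_threshold_fraction: float = 0.01) -> np.ndarray:
    """Pectoralis pull angle on the humerus (deg).

    From |M_perp| = |F| d sin(theta_p): the moment component perpendicular to
    the humerus axis, the muscle force magnitude (power balance) and the
    deltopectoral-crest moment arm ``d`` fix the pull angle.  Samples with a
    negligible moment or undefined force are masked (NaN).
    """
    m = np.atleast_2d(np.asarray(muscle_moment, dtype=float))
    h = unit(np.atleast_2d(np.asarray(humerus, dtype=float)))
    f = np.broadcast_to(np.asarray(force_magnitude, dtype=float), m.shape[:1]).copy()
    m_par = np.sum(m * h, axis=1)[:, None] * h
    m_perp = np.linalg.norm(m - m_par, axis=1)
    mag = np.linalg.norm(m, axis=1)
    ok = (mag > moment_threshold_fraction * mag.max()) & np.isfinite(f) & (f > 0)
    theta = np.full(len(m), np.nan)
    theta[ok] = np.degrees(np.arcsin(np.clip(
        m_perp[ok] / (np.abs(f[ok]) * moment_arm), 0.0, 1.0)))
    return theta


@dataclass
class PectoralisPull:
    """Pull direction (body frame) and stress of the pectoralis."""

    time: np.ndarray
    pull_angle_deg: np.ndarray
    direction_body: np.ndarray    # unit vectors; +x_b cranial, +z_b dorsal
    stress: np.ndarray            # Pa
    force_vec_world: np.ndarray
    valid: np.ndarray


def body_frame(back: np.ndarray, head: np.ndarray) -> np.ndarray:
    """Per-sample body axes as rows (x_b cranial, y_b lateral-left, z_b dorsal).

    x_b is the back->head direction projected onto the horizontal, z_b is
    vertical-dorsal, y_b completes the right-handed triad (for the left
    shoulder +y_b points lateral; medial components are negative y_b).
    """
    d = np.asarray(head, float) - np.asarray(back, float)
    d[:, 2] = 0.0
    x_b = unit(d)
    z_b = np.tile(np.array([0.0, 0.0, 1.0]), (len(x_b), 1))
    y_b = np.cross(z_b, x_b)
    return np.stack([x_b, y_b, z_b], axis=1)


def pull_direction_and_stress(muscle_moment: np.ndarray, humerus: np.ndarray,
                              pcsa: float, dpc_arm: float = DPC_ARM,
                              frame: np.ndarray | None = None,
                              downstroke: np.ndarray | None = None,
                              time: np.ndarray | None = None) -> PectoralisPull:
    """Unique force at the DPC reproducing the perpendicular-humerus moment.

    F_perp = (M_perp x h) / d is the minimal force at the deltopectoral crest
    whose moment about the shoulder matches the muscle moment's component
    perpendicular to the humerus.  Stress is |F|/PCSA.  Undefined outside the
    downstroke, where the single-muscle assumption breaks.
    """
    m = np.atleast_2d(np.asarray(muscle_moment, dtype=float))
    h = unit(np.atleast_2d(np.asarray(humerus, dtype=float)))
    if pcsa <= 0 or dpc_arm <= 0:
        raise ValueError("PCSA and moment arm must be positive")
    m_perp = m - np.sum(m * h, axis=1)[:, None] * h
    force = np.cross(m_perp, h) / dpc_arm
    mag = np.linalg.norm(force, axis=1)
    valid = mag > 0
    if downstroke is not None:
        valid = valid & np.asarray(downstroke, dtype=bool)
    direction = np.full_like(force, np.nan)
    if frame is not None:
        fb = np.einsum("tij,tj->ti", frame, force)   # components in body axes
        direction[valid] = unit(fb[valid])
    else:
        direction[valid] = unit(force[valid])
    stress = np.where(valid, mag / pcsa, np.nan)
    t = np.arange(len(m), dtype=float) if time is None else np.asarray(time, float)
    theta = np.full(len(m), np.nan)
    return PectoralisPull(time=t, pull_angle_deg=theta, direction_body=direction,
                          stress=stress, force_vec_world=force, valid=valid)
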