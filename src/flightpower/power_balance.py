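"""Whole-bird 1D power balance.

Time-resolved total muscle power is the sum of aerodynamic power, the rate of
change of wing kinetic energy (inertial power), and the body term (kinetic
plus potential rate of the trunk point mass).  Combined with the measured
pectoralis strain rate this yields the pectoralis force magnitude during the
downstroke.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import BodyState, WingPointMassModel
from .synthetic_data import BirdMorphology
from .util import G, check_common_grid, resample

#: shortening-velocity fraction below which force-from-power is ill-posed
SHORTENING_MASK_FRACTION = 0.05


@dataclass
class MuscleState:
    """Pectoralis fiber length, strain and activation on the analysis grid."""

    time: np.ndarray
    fiber_length: np.ndarray
    rest_length: float
    strain: np.ndarray
    strain_rate: np.ndarray
    shortening_velocity: np.ndarray   # -dL/dt; positive while shortening
    emg_envelope: np.ndarray

    @property
    def activation_window(self) -> tuple[float, float]:
        """(onset, offset) times of the EMG envelope above 5% of its peak."""
        active = self.emg_envelope > 0.05 * self.emg_envelope.max()
        idx = np.flatnonzero(active)
        return float(self.time[idx[0]]), float(self.time[idx[-1]])


def strain_from_length(fiber_length: np.ndarray, rest_length: float) -> np.ndarray:
    """Fiber strain: length over rest length minus one."""
    fiber_length = np.asarray(fiber_length, dtype=float)
    if rest_length <= 0 or np.any(fiber_length <= 0):
        raise ValueError("fiber lengths must be strictly positive")
    return fiber_length / rest_length - 1.0


def build_muscle_state(muscle: pd.DataFrame, morph: BirdMorphology,
                       t_grid: np.ndarray) -> MuscleState:
    """Resample the sonomicrometry/EMG channels onto the analysis grid."""
    t_src = muscle["time"].to_numpy(dtype=float)
    length = resample(t_src, muscle["fiber_length_m"].to_numpy(float), t_grid)
    emg = resample(t_src, muscle["emg_mV"].to_numpy(float), t_grid)
    strain = strain_from_length(length, morph.fiber_rest_length)
    dldt = np.gradient(length, t_grid)
    return MuscleState(time=np.asarray(t_grid, float), fiber_length=length,
                       rest_length=morph.fiber_rest_length, strain=strain,
                       strain_rate=np.gradient(strain, t_grid),
                       shortening_velocity=-dldt, emg_envelope=emg)


def inertial_power(wing_models: WingPointMassModel | list[WingPointMassModel]
                   ) -> np.ndarray:
    """P_iner = sum_i m_i (a_i . v_i) over all wing point masses.

    Equals the time derivative of the total wing kinetic energy.
    """
    if isinstance(wing_models, WingPointMassModel):
        wing_models = [wing_models]
    t0 = wing_models[0].time
    total = np.zeros(len(t0))
    for wm in wing_models:
        check_common_grid(t0, wm.time)
        total += np.einsum("p,tpi,tpi->t", wm.masses,
                           wm.accelerations, wm.velocities)
    return total


def body_power(body: BodyState, g: float = G) -> np.ndarray:
    """Kinetic plus potential rate of the trunk point mass: m(a.v) + m g v_z."""
    kinetic = body.mass * np.sum(body.acceleration * body.velocity, axis=1)
    potential = body.mass * g * body.velocity[:, 2]
    return kinetic + potential


@dataclass
class PowerDecomposition:
    """Aerodynamic / inertial / body split of the required muscle power."""

    time: np.ndarray
    p_aero: np.ndarray
    p_iner: np.ndarray
    p_body: np.ndarray
    p_musc_total: np.ndarray
    mass_specific: np.ndarray     # W per kg of total (left+right) pectoralis
    pect_mass_total: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.time, "p_aero": self.p_aero, "p_iner": self.p_iner,
            "p_body": self.p_body, "p_musc_total": self.p_musc_total,
            "p_mass_specific": self.mass_specific,
        })


def total_muscle_power(p_aero: np.ndarray, p_iner: np.ndarray,
                       p_body: np.ndarray, time: np.ndarray,
                       morph: BirdMorphology) -> PowerDecomposition:
    """Sum the three power terms; also report the pectoralis-mass-specific series.

    Mass-specific power divides by the combined mass of both pectorales, the
    convention used for muscle power throughout.
    """
    p_aero, p_iner, p_body = (np.asarray(p, dtype=float)
                              for p in (p_aero, p_iner, p_body))
    if not p_aero.shape == p_iner.shape == p_body.shape == np.shape(time):
        raise ValueError("power terms are not on a common grid")
    total = p_aero + p_iner + p_body
    m_pect = 2.0 * morph.pect_mass_single
    return PowerDecomposition(time=np.asarray(time, float), p_aero=p_aero,
                              p_iner=p_iner, p_body=p_body,
                              p_musc_total=total,
                              mass_specific=total / m_pect,
                              pect_mass_total=m_pect)


def pectoralis_force_from_power(p_pect: np.ndarray,
                                shortening_velocity: np.ndarray,
                                mask_fraction: float = SHORTENING_MASK_FRACTION
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Pectoralis force magnitude from per-muscle power and strain rate.

    ``p_pect`` is the power of one muscle (callers split the whole-bird
    power equally between the left and right pectoralis before calling).
    Samples where |shortening velocity| is below ``mask_fraction`` of its
    peak are masked (NaN) — the quotient is ill-posed near stroke reversal.

    Returns ``(force, valid_mask)``.
    """
    p = np.asarray(p_pect, dtype=float)
    v = np.asarray(shortening_velocity, dtype=float)
    if p.shape != v.shape:
        raise ValueError("power and shortening velocity are not on a common grid")
    valid = np.abs(v) > mask_fraction * np.max(np.abs(v))
    force = np.full(p.shape, np.nan)
    force[valid] = p[valid] / v[valid]
    return force, valid
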