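"""Allometric scaling of pectoralis power and its timing across extant birds.

Two scaling parameters govern slow-flight muscle performance: the
aerodynamic parameter x_aero = f*R (wingtip-speed scale, m/s) and the
inertial parameter x_iner = (m_wing/m_body) * (r_gyr/R)^2 * (f*R) * f (wing
mass distribution times wingbeat rate).  Average pectoralis power per unit
body mass rises linearly with x_aero, while larger x_iner shifts the
midpoint of power (and force) exertion earlier in the stroke.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic_data import BirdMorphology

# fitted linear scaling coefficients (intercept, slope)
MEAN_POWER_COEFFS = (-0.59, 18.74)      # W/kg body mass vs x_aero (m/s)
POWER_TIMING_COEFFS = (35.01, -61.75)   # % of stroke vs x_iner
FORCE_TIMING_COEFFS = (31.90, -59.06)   # % of stroke vs x_iner


@dataclass
class ScalingPrediction:
    """Scaling parameters and predicted power/timing for one morphology."""

    name: str
    x_p_aero: float                 # m/s
    x_p_iner: float                 # dimensionless composite
    mean_power_per_bodymass: float  # W/kg body mass
    t_power_mid: float              # % of stroke
    t_force_mid: float              # % of stroke


def scaling_parameters(morph: BirdMorphology) -> tuple[float, float]:
    """(x_aero, x_iner) for a morphology; wing mass counts both wings."""
    f = morph.flap_frequency
    r = morph.wing_radius
    m_wing = 2.0 * morph.wing_mass_single
    x_aero = f * r
    x_iner = (m_wing / morph.body_mass) * (morph.radius_of_gyration / r) ** 2 \
        * (f * r) * f
    return x_aero, x_iner


def predict_mean_power(morph: BirdMorphology) -> float:
    """Stroke-averaged pectoralis power per kg body mass (W/kg)."""
    x_aero, _ = scaling_parameters(morph)
    a, b = MEAN_POWER_COEFFS
    return a + b * x_aero


def predict_power_timing(morph: BirdMorphology) -> float:
    """Midway point of pectoralis power exertion (% of stroke)."""
    _, x_iner = scaling_parameters(morph)
    a, b = POWER_TIMING_COEFFS
    return a + b * x_iner


def predict_force_timing(morph: BirdMorphology) -> float:
    """Midway point of pectoralis force exertion (% of stroke)."""
    _, x_iner = scaling_parameters(morph)
    a, b = FORCE_TIMING_COEFFS
    return a + b * x_iner


def predict(morph: BirdMorphology) -> ScalingPrediction:
    x_aero, x_iner = scaling_parameters(morph)
    return ScalingPrediction(
        name=morph.name, x_p_aero=x_aero, x_p_iner=x_iner,
        mean_power_per_bodymass=MEAN_POWER_COEFFS[0] + MEAN_POWER_COEFFS[1] * x_aero,
        t_power_mid=POWER_TIMING_COEFFS[0] + POWER_TIMING_COEFFS[1] * x_iner,
        t_force_mid=FORCE_TIMING_COEFFS[0] + FORCE_TIMING_COEFFS[1] * x_iner)


def predictions_frame(birds: list[BirdMorphology]) -> pd.DataFrame:
    rows = [predict(b) for b in birds]
    return pd.DataFrame([r.__dict__ for r in rows])


def midway_timing_from_trace(series: np.ndarray, stroke_fraction: np.ndarray
                             ) -> float:
    """Stroke fraction (%) where the cumulative positive part reaches half.

    The positive part of the power (or force) series is integrated over the
    wingbeat; the reported timing is the stroke percentage at which the
    cumulative integral crosses 50% of its total, linearly interpolated.
    """
    y = np.maximum(np.asarray(series, dtype=float), 0.0)
    x = np.asarray(stroke_fraction, dtype=float)
    if y.shape != x.shape:
        raise ValueError("series and stroke fraction are not on a common grid")
    dx = np.diff(x)
    inc = 0.5 * (y[1:] + y[:-1]) * dx
    cum = np.concatenate([[0.0], np.cumsum(inc)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("series has no positive part")
    return float(np.interp(0.5 * total, cum, x)) * 100.0


def fit_scaling_coefficients(x: np.ndarray, y: np.ndarray):
    """OLS line through (x, y) pairs; returns ((intercept, slope), results).

    Used for parameter recovery on synthetic bird populations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two points to fit a line")
    design = sm.add_constant(x)
    if np.linalg.matrix_rank(design) < 2:
        raise ValueError("rank-deficient design: x values are all equal")
    res = sm.OLS(y, design).fit()
    return (float(res.params[0]), float(res.params[1])), res
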