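"""Small numerical helpers shared across the pipeline stages."""

from __future__ import annotations

import numpy as np

G = 9.81  # gravitational acceleration, m/s^2
RHO_AIR = 1.225  # air density at sea level, kg/m^3


def unit(v: np.ndarray, axis: int = -1, eps: float = 1e-30) -> np.ndarray:
    """Normalize vectors along ``axis``; zero vectors stay zero."""
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    return v / np.maximum(n, eps)


def span_average(t: np.ndarray, y: np.ndarray, t_end: float | None = None) -> float:
    """Trapezoidal time average of ``y`` over ``[t[0], t_end]``.

    If ``t_end`` falls between samples the final partial interval is included
    via linear interpolation, so an average over an exact integer number of
    wingbeats is well defined on any sampling grid.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t_end is None:
        t_end = t[-1]
    if t_end > t[-1] + 1e-12:
        raise ValueError("t_end beyond trace")
    i = int(np.searchsorted(t, t_end, side="right"))
    tt = t[:i]
    yy = y[:i]
    if tt[-1] < t_end - 1e-12:
        y_end = np.interp(t_end, t, y)
        tt = np.append(tt, t_end)
        yy = np.append(yy, y_end)
    return float(np.trapezoid(yy, tt) / (tt[-1] - tt[0]))


def resample(t_src: np.ndarray, y: np.ndarray, t_dst: np.ndarray) -> np.ndarray:
    """Cubic-spline resampling of one or more channels onto a new grid."""
    from scipy.interpolate import CubicSpline

    y = np.asarray(y, dtype=float)
    cs = CubicSpline(np.asarray(t_src, dtype=float), y, axis=0)
    return cs(np.clip(t_dst, t_src[0], t_src[-1]))


def check_common_grid(*times: np.ndarray) -> np.ndarray:
    """Verify all time vectors coincide; return the shared grid."""
    t0 = np.asarray(times[0], dtype=float)
    for t in times[1:]:
        t = np.asarray(t, dtype=float)
        if t.shape != t0.shape or not np.allclose(t, t0, atol=1e-12):
            raise ValueError("traces are not on a common time grid")
    return t0
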