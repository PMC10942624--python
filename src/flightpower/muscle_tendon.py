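"""Pectoralis / supracoracoideus power partition under tendon elastic storage.

The total required muscle power over one wingbeat is split into five modes:
pectoralis generation (downstroke shortening), pectoralis absorption
(negative power), supracoracoideus generation (upstroke), tendon storage
(extra pectoralis power spent tensioning the supracoracoideus tendon during
the late downstroke, plotted negative) and tendon release (upstroke).  A
storage scenario sets the fraction of upstroke positive work that is
pre-stored and the window (duration, as % of stroke, ending at the end of
the downstroke) over which it is stored.  The sum of the five modes equals
the total muscle power at every sample, to rounding error.

Work loops (muscle force versus fiber length over one wingbeat) and their
shape factor — loop area over the bounding peak-force x peak-excursion
rectangle, 1 for the ideal rectangular loop — quantify how storage timing
re-shapes pectoralis output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .power_balance import MuscleState, SHORTENING_MASK_FRACTION

STORAGE_PROFILES = ("flat_force", "flat_power", "raised_cosine")


@dataclass
class StorageScenario:
    """Amount, timing and shape of elastic storage in the supracoracoideus tendon.

    ``storage_fraction``: fraction of upstroke positive work pre-stored.
    ``storage_duration``: window length as a fraction of the full stroke; the
    window always ends at the end of the downstroke (the tendon must be
    tensioned at stroke reversal).
    ``profile``: how the storage power is distributed inside the window.
    ``flat_force`` (default) tops up pectoralis output to a constant *force*
    level (extra power proportional to shortening velocity — peaks
    mid-window, tapers to zero at stroke reversal); ``flat_power`` tops up to
    a constant power level; ``raised_cosine`` is a fixed smooth bump.
    """

    storage_fraction: float
    storage_duration: float
    profile: str = "flat_force"

    def __post_init__(self) -> None:
        if not 0.0 <= self.storage_fraction <= 1.0:
            raise ValueError("storage fraction must lie in [0, 1]")
        if self.storage_duration < 0.0:
            raise ValueError("storage duration must be non-negative")
        if self.profile not in STORAGE_PROFILES:
            raise ValueError(f"unknown storage profile {self.profile!r}")


@dataclass
class MusclePowerPartition:
    """Time-resolved five-mode power split over one wingbeat."""

    time: np.ndarray
    p_pect_generate: np.ndarray   # >= 0
    p_pect_absorb: np.ndarray     # <= 0
    p_supra_generate: np.ndarray  # >= 0
    p_tendon_store: np.ndarray    # <= 0, downstroke window
    p_tendon_release: np.ndarray  # >= 0, upstroke
    e_stored: float               # J
    scenario: StorageScenario
    downstroke: np.ndarray | None = None

    @property
    def p_total(self) -> np.ndarray:
        return (self.p_pect_generate + self.p_pect_absorb
                + self.p_supra_generate + self.p_tendon_store
                + self.p_tendon_release)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.time,
            "p_pect_generate": self.p_pect_generate,
            "p_pect_absorb": self.p_pect_absorb,
            "p_supra_generate": self.p_supra_generate,
            "p_tendon_store": self.p_tendon_store,
            "p_tendon_release": self.p_tendon_release,
        })


def _trapezoid_weights(t: np.ndarray) -> np.ndarray:
    w = np.zeros_like(t)
    dt = np.diff(t)
    w[:-1] += 0.5 * dt
    w[1:] += 0.5 * dt
    return w


def partition_power(time: np.ndarray, p_total: np.ndarray,
                    downstroke: np.ndarray, muscle: MuscleState | None,
                    scenario: StorageScenario) -> MusclePowerPartition:
    """Split total muscle power into the five power modes for one wingbeat.

    ``time``/``p_total``/``downstroke`` must cover exactly one wingbeat,
    downstroke first.  ``muscle`` supplies the shortening-velocity trace used
    by the ``flat_force`` profile (may be None for the other profiles).
    """
    t = np.asarray(time, dtype=float)
    p = np.asarray(p_total, dtype=float)
    down = np.asarray(downstroke, dtype=bool)
    if not (t.shape == p.shape == down.shape):
        raise ValueError("inputs are not on a common grid")
    if not down[0] or down[-1]:
        raise ValueError("wingbeat must start with the downstroke and end in the upstroke")
    switches = np.flatnonzero(np.diff(down.astype(int)))
    if len(switches) != 1:
        raise ValueError("expected exactly one downstroke->upstroke transition")
    t_rev = t[switches[0] + 1]
    period = t[-1] - t[0]
    # The tensioning window ends where pectoralis shortening arrests (just
    # before the wing's stroke reversal): the muscle cannot load the tendon
    # once it stops shortening, and the tendon is then held tensioned
    # through the reversal.
    t_end = t_rev
    if muscle is not None:
        v = muscle.shortening_velocity
        live = down & (v > 0.05 * np.max(np.abs(v)))
        if live.any():
            t_end = t[np.flatnonzero(live)[-1]]
    window_len = scenario.storage_duration * period
    if window_len > (t_rev - t[0]) + 1e-12:
        raise ValueError("storage window extends outside the downstroke")
    # a window longer than the pre-arrest downstroke clamps to its start
    t_start = max(t_end - window_len, t[0])

    p_pos = np.maximum(p, 0.0)
    p_neg = np.minimum(p, 0.0)
    wts = _trapezoid_weights(t)
    up = ~down
    e_up = float(np.sum(wts[up] * p_pos[up]))
    e_stored = scenario.storage_fraction * e_up

    extra = np.zeros_like(p)
    if e_stored > 0:
        in_window = down & (t >= t_start - 1e-12) & (t <= t_end + 1e-12)
        extra = _storage_profile(t, p_pos, wts, in_window, e_stored,
                                 scenario, muscle)

    phi = scenario.storage_fraction
    return MusclePowerPartition(
        time=t,
        p_pect_generate=p_pos * down + extra,
        p_pect_absorb=p_neg,
        p_supra_generate=(1.0 - phi) * p_pos * up,
        p_tendon_store=-extra,
        p_tendon_release=phi * p_pos * up,
        e_stored=e_stored,
        scenario=scenario,
        downstroke=down,
    )


def _storage_profile(t, p_pos, wts, in_window, e_stored, scenario, muscle):
    """Extra (tendon-tensioning) pectoralis power inside the storage window.

    The flat-top profiles allocate storage power to the headroom between a
    constant flat-top pectoralis output level and the aero+inertial
    requirement; the level is solved (bisection) so the window integral
    equals the energy to store.  ``flat_force`` holds muscle *force* flat
    (extra power proportional to shortening velocity, tapering at stroke
    reversal); ``flat_power`` holds power flat.  Small stored amounts fill
    the deepest part of the mid-downstroke dip first; storing more than the
    window can absorb below its natural maximum raises the top above the
    flanking peaks, degrading the work loop — energy storage must be tuned.
    """
    extra = np.zeros_like(t)
    idx = np.flatnonzero(in_window)
    if len(idx) < 2:
        # degenerate zero-width window: impulse storage at the last
        # downstroke sample, energy-consistent under the trapezoid rule
        i = idx[-1] if len(idx) else np.flatnonzero(t < t[-1])[-1]
        extra[i] = e_stored / wts[i]
        return extra
    if scenario.profile == "raised_cosine":
        extra[idx] = e_stored * _smooth_bump(t, wts, idx)
        return extra
    if scenario.profile == "flat_force":
        if muscle is None:
            raise ValueError("flat_force profile needs the muscle shortening velocity")
        shape = np.maximum(muscle.shortening_velocity[idx], 0.0)
        if shape.max() <= 0:
            # no shortening inside the window (fiber already arrested):
            # fall back to a smooth bump; the stored power then appears at
            # near-zero fiber velocity, the degenerate late-storage case
            extra[idx] = e_stored * _smooth_bump(t, wts, idx)
            return extra
    else:  # flat_power
        shape = np.ones(len(idx))

    def stored(level):
        return np.sum(wts[idx] * np.maximum(level * shape - p_pos[idx], 0.0))

    hi = 1.0
    while stored(hi) < e_stored:
        hi *= 2.0
        if hi > 1e15:
            raise ValueError("storage profile cannot absorb the requested energy")
    lo = 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if stored(mid) < e_stored:
            lo = mid
        else:
            hi = mid
    level = 0.5 * (lo + hi)
    extra[idx] = np.maximum(level * shape - p_pos[idx], 0.0)
    total = np.sum(wts[idx] * extra[idx])
    if total > 0:
        extra[idx] *= e_stored / total   # exact energy bookkeeping
    else:  # level below every sample (tiny e_stored): smooth fallback
        extra[idx] = e_stored * _smooth_bump(t, wts, idx)
    return extra


def _smooth_bump(t, wts, idx):
    """Unit-integral raised-cosine bump over the window samples."""
    span = t[idx[-1]] - t[idx[0]]
    if span <= 0:
        return 1.0 / np.sum(wts[idx]) * np.ones(len(idx))
    xi = (t[idx] - t[idx[0]]) / span
    bump = 1.0 - np.cos(2.0 * np.pi * xi)
    norm = np.sum(wts[idx] * bump)
    if norm <= 0:
        bump = np.ones(len(idx))
        norm = np.sum(wts[idx])
    return bump / norm


# --------------------------------------------------------------------------
# work loops
# --------------------------------------------------------------------------

@dataclass
class WorkLoop:
    """Closed force-length loop over one contraction cycle."""

    force: np.ndarray
    length: np.ndarray
    loop_area: float = field(init=False)

    def __post_init__(self) -> None:
        f = np.asarray(self.force, dtype=float)
        x = np.asarray(self.length, dtype=float)
        if f.shape != x.shape or f.ndim != 1 or len(f) < 3:
            raise ValueError("work loop needs matching 1D force and length series")
        self.force, self.length = f, x
        self.loop_area = _shoelace(x, f)


def _shoelace(x: np.ndarray, y: np.ndarray) -> float:
    """Signed polygon area, counterclockwise positive (net positive work)."""
    x2 = np.append(x, x[0])
    y2 = np.append(y, y[0])
    return float(0.5 * np.sum(x2[:-1] * y2[1:] - x2[1:] * y2[:-1]))


def build_work_loop(force: np.ndarray, length: np.ndarray,
                    closure_tolerance: float = 0.05) -> WorkLoop:
    """Build a work loop, requiring the length trajectory to close on itself.

    After one full wingbeat the fiber length must return to its starting
    value within ``closure_tolerance`` of the peak excursion; the polygon is
    closed by the implicit wrap edge (the force may step across the wrap,
    since consecutive cyclic samples are adjacent, not coincident, in time).
    """
    f = np.asarray(force, dtype=float)
    x = np.asarray(length, dtype=float)
    rng = x.max() - x.min()
    gap = abs(x[-1] - x[0])
    if rng > 0 and gap > closure_tolerance * rng:
        raise ValueError(f"open loop: length endpoints differ by {gap:.3g} "
                         f"(> {closure_tolerance:.0%} of excursion)")
    return WorkLoop(force=f, length=x)


def shape_factor(loop: WorkLoop) -> float:
    """Loop area over the peak-force x peak-length-excursion rectangle.

    1.0 for the theoretically ideal rectangular work loop; 0.5 for a
    triangle spanning the same extrema.
    """
    df = loop.force.max() - loop.force.min()
    dx = loop.length.max() - loop.length.min()
    if df <= 0 or dx <= 0:
        raise ValueError("work loop has zero force or length excursion")
    return loop.loop_area / (df * dx)


def pectoralis_work_loop(partition: MusclePowerPartition, muscle: MuscleState,
                         mask_fraction: float = SHORTENING_MASK_FRACTION
                         ) -> WorkLoop:
    """Per-muscle pectoralis force-length loop implied by a power partition.

    Force is pectoralis power over the shortening velocity, halved for one
    muscle, with sign rules reflecting that a muscle can only pull:

    * downstroke generation (power and shortening velocity positive) maps to
      positive force; where total power turns negative at the end of the
      downstroke the force is zero — the antagonist takes over at reversal;
    * late-upstroke negative power with the pectoralis active is the
      pectoralis braking the wing: it carries positive (tensile) force of
      magnitude |P|/v;
    * samples where the quotient is ill-posed (|v| below the mask threshold)
      carry zero force.
    """
    p_pect = partition.p_pect_generate + partition.p_pect_absorb
    v = muscle.shortening_velocity
    if p_pect.shape != v.shape:
        raise ValueError("partition and muscle state are not on a common grid")
    valid = np.abs(v) > mask_fraction * np.max(np.abs(v))
    force = np.zeros_like(p_pect)
    # While shortening, the pectoralis can only pull: its tensile output is
    # the generation term; any simultaneous negative wing power is taken up
    # by the tendon and skeleton, not by the (shortening) muscle fiber.
    force[valid] = np.maximum(0.5 * partition.p_pect_generate[valid] / v[valid],
                              0.0)
    if partition.downstroke is not None:
        # Late-upstroke braking: the muscle is active and absorbing while the
        # fiber barely moves (series compliance takes up the wing's motion),
        # so the fiber-rate quotient overestimates force; floor the
        # denominator at the stroke-scale shortening rate.
        brake = (~partition.downstroke) & valid & (v > 0) & (p_pect < 0)
        v_stroke = np.mean(v[partition.downstroke & (v > 0)])
        force[brake] = 0.5 * np.abs(p_pect[brake]) / np.maximum(v[brake], v_stroke)
    # Quasi-isometric bridge: while the muscle is electrically active the
    # force-from-power quotient is indeterminate around the top stroke
    # reversal (total power crosses zero at near-zero shortening velocity),
    # yet an activated muscle holds tension there.  Interpolate the force
    # across active low-power runs bounded by loaded samples on both sides.
    active = muscle.emg_envelope > 0.05 * muscle.emg_envelope.max()
    low_power = np.abs(p_pect) < 0.05 * np.max(np.abs(p_pect))
    force = _bridge_cyclic(force, active & (low_power | ~valid))
    return build_work_loop(force, muscle.fiber_length)


def _bridge_cyclic(force: np.ndarray, flagged: np.ndarray) -> np.ndarray:
    """Linearly interpolate force across flagged runs (cyclically).

    Only runs whose two (cyclic) neighbours both carry positive force are
    bridged; isolated zero-force stretches away from the loaded loop remain
    zero.
    """
    n = len(force)
    out = force.copy()
    if flagged.all() or not flagged.any():
        return out
    idx = np.arange(n)
    runs = []
    # walk cyclic runs of flagged samples
    start = None
    for i in np.concatenate([idx, idx]):
        if flagged[i % n] and start is None:
            start = i
        elif not flagged[i % n] and start is not None:
            if i - start < n:
                runs.append((start % n, (i - 1) % n))
            start = None
        if i >= n and start is None:
            break
    seen = set()
    for a, b in runs:
        if (a, b) in seen:
            continue
        seen.add((a, b))
        left = (a - 1) % n
        right = (b + 1) % n
        if force[left] <= 0 or force[right] <= 0:
            continue
        length = (b - a) % n + 1
        for k in range(length):
            w = (k + 1) / (length + 1)
            out[(a + k) % n] = (1 - w) * force[left] + w * force[right]
    return out


# --------------------------------------------------------------------------
# storage parameter sweep
# --------------------------------------------------------------------------

def sweep_storage(time: np.ndarray, p_total: np.ndarray, downstroke: np.ndarray,
                  muscle: MuscleState, fractions: np.ndarray,
                  timings: np.ndarray, profile: str = "flat_force",
                  pect_mass_total: float | None = None) -> pd.DataFrame:
    """Shape factor and pectoralis power over a (fraction, timing) grid.

    For every storage fraction and storage-window duration the partition is
    run, the pectoralis work loop built, and the shape factor and
    stroke-averaged positive pectoralis power recorded.  Power is reported
    mass-specifically (W/kg pectoralis) when ``pect_mass_total`` is given.
    Fully deterministic.
    """
    fractions = np.atleast_1d(np.asarray(fractions, dtype=float))
    timings = np.atleast_1d(np.asarray(timings, dtype=float))
    if fractions.size == 0 or timings.size == 0:
        raise ValueError("fraction and timing grids must be non-empty")
    t = np.asarray(time, dtype=float)
    wts = _trapezoid_weights(t)
    period = t[-1] - t[0]
    rows = []
    for frac in fractions:
        for timing in timings:
            part = partition_power(t, p_total, downstroke, muscle,
                                   StorageScenario(frac, timing, profile))
            loop = pectoralis_work_loop(part, muscle)
            mean_pos = float(np.sum(wts * part.p_pect_generate)) / period
            if pect_mass_total:
                mean_pos /= pect_mass_total
            rows.append((frac, timing, shape_factor(loop), mean_pos))
    return pd.DataFrame(rows, columns=["fraction", "timing", "shape_factor",
                                       "mean_positive_pect_power"])


def optimal_timing(sweep: pd.DataFrame, min_fraction: float = 0.35
                   ) -> pd.DataFrame:
    """Per-fraction argmax timing and shape factor, for fractions >= min."""
    sel = sweep[sweep["fraction"] >= min_fraction - 1e-12]
    idx = sel.groupby("fraction")["shape_factor"].idxmax()
    return sel.loc[idx, ["fraction", "timing", "shape_factor"]].reset_index(drop=True)
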