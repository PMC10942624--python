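"""Power partitioning under tendon elastic storage; work loops; sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flightpower.muscle_tendon import (StorageScenario, build_work_loop,
                                       partition_power, pectoralis_work_loop,
                                       shape_factor, sweep_storage)
from flightpower.power_balance import MuscleState


def _toy_wingbeat(n=200, fd=0.6):
    """Synthetic one-wingbeat power and muscle traces for partition tests."""
    t = np.linspace(0.0, 0.1, n, endpoint=False)
    phi = t / 0.1
    down = phi < fd
    p = np.where(down, 8.0 * np.sin(np.pi * phi / fd) ** 2,
                 2.0 * np.sin(np.pi * (phi - fd) / (1 - fd)) ** 2)
    p = p - 0.5  # some negative power near the reversals
    v = np.where(down, 0.06 * np.sin(np.pi * np.minimum(phi / fd, 1.0)), -0.04)
    length = 0.017 * (1 + 0.2 - 0.2 * phi)  # monotone stand-in
    muscle = MuscleState(time=t, fiber_length=length, rest_length=0.017,
                         strain=length / 0.017 - 1,
                         strain_rate=np.gradient(length / 0.017 - 1, t),
                         shortening_velocity=v,
                         emg_envelope=np.ones_like(t))
    return t, p, down, muscle


class TestPartition:
    def test_zero_storage_degenerate(self):
        t, p, down, muscle = _toy_wingbeat()
        part = partition_power(t, p, down, muscle, StorageScenario(0.0, 0.2))
        np.testing.assert_allclose(part.p_tendon_store, 0.0)
        np.testing.assert_allclose(part.p_tendon_release, 0.0)
        up_pos = np.where(~down, np.maximum(p, 0.0), 0.0)
        np.testing.assert_allclose(part.p_supra_generate, up_pos)

    def test_full_storage_conservation(self):
        t, p, down, muscle = _toy_wingbeat()
        part = partition_power(t, p, down, muscle, StorageScenario(1.0, 0.3))
        np.testing.assert_allclose(part.p_supra_generate, 0.0)
        release = np.trapezoid(part.p_tendon_release, t)
        up_work = np.trapezoid(np.where(~down, np.maximum(p, 0), 0), t)
        assert release == pytest.approx(up_work, rel=1e-6)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 0.55),
           st.sampled_from(["flat_force", "flat_power", "raised_cosine"]))
    def test_conservation_across_random_scenarios(self, fraction, duration,
                                                  profile):
        """Sum of the five power modes equals total power at every sample."""
        t, p, down, muscle = _toy_wingbeat()
        part = partition_power(t, p, down, muscle,
                               StorageScenario(fraction, duration, profile))
        np.testing.assert_allclose(part.p_total, p, rtol=1e-9, atol=1e-9)
        assert np.all(part.p_pect_generate >= 0)
        assert np.all(part.p_pect_absorb <= 0)
        assert np.all(part.p_supra_generate >= 0)
        assert np.all(part.p_tendon_store <= 0)
        assert np.all(part.p_tendon_release >= 0)

    def test_storage_equals_release(self):
        t, p, down, muscle = _toy_wingbeat()
        part = partition_power(t, p, down, muscle, StorageScenario(0.7, 0.25))
        from flightpower.muscle_tendon import _trapezoid_weights

        w = _trapezoid_weights(t)
        stored = np.sum(w * part.p_tendon_store)
        released = np.sum(w * part.p_tendon_release)
        assert stored == pytest.approx(-released, rel=1e-9)
        assert -stored == pytest.approx(part.e_stored, rel=1e-9)

    def test_monotone_energy_accounting(self):
        t, p, down, muscle = _toy_wingbeat()
        from flightpower.muscle_tendon import _trapezoid_weights

        w = _trapezoid_weights(t)
        pect, supra = [], []
        for f in (0.0, 0.3, 0.6, 0.9):
            part = partition_power(t, p, down, muscle, StorageScenario(f, 0.3))
            pect.append(np.sum(w * part.p_pect_generate))
            supra.append(np.sum(w * part.p_supra_generate))
        assert np.all(np.diff(pect) > 0)
        assert np.all(np.diff(supra) < 0)

    def test_zero_width_window_impulse(self):
        t, p, down, muscle = _toy_wingbeat()
        part = partition_power(t, p, down, muscle, StorageScenario(0.5, 0.0))
        from flightpower.muscle_tendon import _trapezoid_weights

        w = _trapezoid_weights(t)
        assert np.sum(w * -part.p_tendon_store) == pytest.approx(part.e_stored,
                                                                 rel=1e-9)
        assert np.count_nonzero(part.p_tendon_store) == 1

    def test_window_outside_downstroke_rejected(self):
        t, p, down, muscle = _toy_wingbeat()
        with pytest.raises(ValueError, match="window"):
            partition_power(t, p, down, muscle, StorageScenario(0.5, 0.9))

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ValueError):
            StorageScenario(1.5, 0.2)
        with pytest.raises(ValueError):
            StorageScenario(0.5, -0.1)
        with pytest.raises(ValueError):
            StorageScenario(0.5, 0.2, profile="banana")


class TestWorkLoop:
    def test_rectangle_area_and_shape(self):
        length = np.array([1.0, 0.0, 0.0, 1.0])
        force = np.array([2.0, 2.0, 0.0, 0.0])
        loop = build_work_loop(force, length)
        assert loop.loop_area == pytest.approx(2.0)
        assert shape_factor(loop) == pytest.approx(1.0)

    def test_triangle_is_half(self):
        length = np.array([1.0, 0.0, 1.0])
        force = np.array([2.0, 0.0, 0.0])
        loop = build_work_loop(force, length)
        assert shape_factor(loop) == pytest.approx(0.5)

    def test_degenerate_line_zero_area(self):
        length = np.array([0.0, 1.0, 0.0])
        force = np.array([0.0, 1.0, 0.0])
        assert build_work_loop(force, length).loop_area == pytest.approx(0.0)

    def test_random_polygon_matches_shoelace_oracle(self, rng):
        ang = np.sort(rng.uniform(0, 2 * np.pi, 12))
        ang[-1] = ang[0] + 2 * np.pi  # traversal returns to its start
        r = rng.uniform(0.5, 1.5, 12)
        r[-1] = r[0]
        x, y = r * np.cos(ang), r * np.sin(ang)
        loop = build_work_loop(y - y.min(), x)
        area = 0.0  # independent triangle-fan oracle
        for i in range(1, 11):
            ax, ay = x[i] - x[0], y[i] - y[0]
            bx, by = x[i + 1] - x[0], y[i + 1] - y[0]
            area += 0.5 * (ax * by - ay * bx)
        assert loop.loop_area == pytest.approx(float(area), rel=1e-12)

    def test_open_loop_rejected(self):
        with pytest.raises(ValueError, match="open loop"):
            build_work_loop(np.array([0.0, 1.0, 1.0]), np.array([0.0, 1.0, 2.0]))

    def test_zero_excursion_rejected(self):
        loop = build_work_loop(np.zeros(4), np.array([0.0, 1.0, 1.0, 0.0]))
        with pytest.raises(ValueError):
            shape_factor(loop)

    def test_shape_factor_never_exceeds_one(self, dove, rng):
        sl, down, _ = dove.wingbeat()
        muscle = dove._muscle_slice(sl)
        for _ in range(10):
            scen = StorageScenario(rng.uniform(0, 1), rng.uniform(0, 0.5))
            part = partition_power(dove.kin.time[sl],
                                   dove.power.p_musc_total[sl], down, muscle,
                                   scen)
            assert shape_factor(pectoralis_work_loop(part, muscle)) <= 1.0

    def test_force_stress_affine_invariance(self, dove):
        """Shape factor is identical for force (N) and stress (Pa) loops."""
        sl, down, _ = dove.wingbeat()
        muscle = dove._muscle_slice(sl)
        part = partition_power(dove.kin.time[sl], dove.power.p_musc_total[sl],
                               down, muscle, StorageScenario(0.5, 0.3))
        loop_f = pectoralis_work_loop(part, muscle)
        loop_s = build_work_loop(loop_f.force / dove.morphology.pcsa,
                                 loop_f.length)
        assert shape_factor(loop_s) == pytest.approx(shape_factor(loop_f),
                                                     rel=1e-12)


class TestSweep:
    def test_zero_fraction_column_equals_baseline(self, dove):
        sw = dove.sweep(np.array([0.0]), np.array([0.0, 0.2, 0.4]))
        assert sw["shape_factor"].nunique() == 1
        part = dove.partition(StorageScenario(0.0, 0.0))
        sl, _, _ = dove.wingbeat()
        base = shape_factor(pectoralis_work_loop(part, dove._muscle_slice(sl)))
        np.testing.assert_allclose(sw["shape_factor"], base)

    def test_deterministic(self, dove):
        fr, tm = np.array([0.3, 0.9]), np.array([0.1, 0.3])
        a = dove.sweep(fr, tm)
        b = dove.sweep(fr, tm)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_short_timing_degrades_shape(self, dove):
        """Concentrated late storage spikes pectoralis output: lower shape."""
        sw = dove.sweep(np.array([0.9]), np.array([0.05, 0.31]))
        short = sw[sw.timing == 0.05]["shape_factor"].iloc[0]
        tuned = sw[sw.timing == 0.31]["shape_factor"].iloc[0]
        assert short < tuned

    def test_empty_grid_rejected(self, dove):
        with pytest.raises(ValueError):
            dove.sweep(np.array([]), np.array([0.1]))
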