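"""Frame schedule, input-function calculus and forward compartment models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petkin.core import (
    FrameSchedule,
    InputFunction,
    IRREVERSIBLE_2TC,
    KineticParameters,
    KineticsError,
    ONE_TISSUE,
    REVERSIBLE_2TC,
    TimeActivityCurve,
    convolve_exp,
    model_conc,
    model_tac,
    net_influx,
)


class TestFrameSchedule:
    def test_abdominal_framing_covers_45_minutes(self):
        s = FrameSchedule.abdominal_45min()
        assert s.n_frames == 22
        assert s.total_span == pytest.approx(45.0, abs=1e-12)
        # 6x10, 3x20, 3x60, 5x180, 5x300 seconds
        expected = np.array([10] * 6 + [20] * 3 + [60] * 3 + [180] * 5 + [300] * 5) / 60
        np.testing.assert_allclose(s.durations, expected)
        assert np.all(np.diff(s.start_times) > 0)

    def test_rejects_overlapping_and_nonpositive_frames(self):
        with pytest.raises(KineticsError):
            FrameSchedule([0.0, 0.5], [1.0, 1.0])  # overlap
        with pytest.raises(KineticsError):
            FrameSchedule([0.0, 1.0], [1.0, 0.0])  # zero duration


class TestInputFunction:
    def test_zero_origin_enforced(self):
        f = InputFunction([1.0, 2.0], [3.0, 4.0])  # zero sample prepended
        assert f(0.0) == 0.0
        with pytest.raises(KineticsError):
            InputFunction([0.0, 1.0], [1.0, 2.0])  # C(0) != 0
        with pytest.raises(KineticsError):
            InputFunction([0.0, 1.0], [0.0, -1.0])

    def test_integral_is_nondecreasing_and_exact(self, cp):
        t = np.linspace(0, cp.t_max, 400)
        integ = cp.integral(t)
        assert np.all(np.diff(integ) >= 0)
        # exact trapezoid on the curve's own nodes
        ref = np.concatenate(
            [[0.0], np.cumsum(np.diff(cp.sample_times)
                              * (cp.concentrations[:-1] + cp.concentrations[1:]) / 2)]
        )
        np.testing.assert_allclose(cp.integral(cp.sample_times), ref, rtol=1e-12)


class TestConvolveExp:
    def test_theta_zero_degenerates_to_running_integral(self, cp):
        t = np.array([1.0, 5.0, 20.0, 45.0])
        np.testing.assert_allclose(convolve_exp(0.0, cp, t), cp.integral(t), rtol=1e-12)

    def test_zero_input_gives_zeros(self, schedule):
        f = InputFunction([0.0, 45.0], [0.0, 0.0])
        assert np.all(convolve_exp(0.7, f, schedule.mid_times) == 0.0)

    def test_unit_step_matches_closed_form(self):
        # near-instantaneous rise to 1 at t=0: kernel response (1 - e^-t)
        f = InputFunction([0.0, 1e-9, 20.0], [0.0, 1.0, 1.0])
        t = np.array([0.5, 1.0, 2.0, 5.0, 10.0])
        np.testing.assert_allclose(convolve_exp(1.0, f, t), 1 - np.exp(-t), rtol=1e-7)

    def test_matches_dense_numerical_convolution(self, cp):
        # trapezoidal oracle on a 10 ms grid over the dynamic scan
        theta = 0.3
        grid = np.arange(0.0, 45.0 + 1e-9, 1.0 / 6000.0)
        cg = np.interp(grid, cp.sample_times, cp.concentrations)
        kernel_int = np.exp(theta * grid) * cg
        cum = np.concatenate(
            [[0.0], np.cumsum((kernel_int[1:] + kernel_int[:-1]) / 2 * np.diff(grid))]
        )
        y_num = np.exp(-theta * grid) * cum
        pick = slice(60000, None, 60000)  # every 10 min
        np.testing.assert_allclose(
            convolve_exp(theta, cp, grid[pick]), y_num[pick], rtol=1e-3
        )

    def test_negative_theta_rejected(self, cp):
        with pytest.raises(KineticsError):
            convolve_exp(-0.1, cp, [1.0])


class TestNetInflux:
    def test_arithmetic_and_limits(self):
        assert net_influx(KineticParameters(K1=0.2, k2=0.2, k3=0.2)) == pytest.approx(0.1)
        assert net_influx(KineticParameters(K1=0.3, k2=0.5, k3=0.0)) == 0.0
        # full trapping: k2 = 0 traps everything delivered
        assert net_influx(KineticParameters(K1=0.3, k2=0.0, k3=0.1)) == pytest.approx(0.3)
        with pytest.raises(KineticsError):
            net_influx(KineticParameters(K1=0.3))

    @given(
        K1=st.floats(0.01, 2.0),
        k2=st.floats(0.001, 2.0),
        k3=st.floats(0.0, 2.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_ki_bounded_by_k1_and_monotone_in_k3(self, K1, k2, k3):
        p = KineticParameters(K1=K1, k2=k2, k3=k3)
        assert p.ki <= K1 * (1 + 1e-12)
        p_hi = KineticParameters(K1=K1, k2=k2, k3=k3 + 0.1)
        assert p_hi.ki > p.ki or k2 == 0


class TestForwardModels:
    def test_nesting_identities(self, cp, schedule):
        rng = np.random.default_rng(7)
        for _ in range(100):
            K1, k2, k3 = rng.uniform(0.02, 1.0, 3)
            vb = rng.uniform(0.0, 0.3)
            p3 = KineticParameters(K1=K1, k2=k2, k3=k3, vb=vb)
            t3 = model_tac(p3, IRREVERSIBLE_2TC, cp, schedule).values
            t4 = model_tac(p3, REVERSIBLE_2TC, cp, schedule).values
            np.testing.assert_allclose(t4, t3, rtol=1e-10)
            p1 = KineticParameters(K1=K1, k2=k2, vb=vb)
            t1 = model_tac(p1, ONE_TISSUE, cp, schedule).values
            t3z = model_tac(p1, IRREVERSIBLE_2TC, cp, schedule).values
            np.testing.assert_allclose(t3z, t1, rtol=1e-10)

    def test_small_k4_is_continuous_with_irreversible_model(self, cp, schedule):
        p3 = KineticParameters(K1=0.3, k2=0.3, k3=0.02, vb=0.05)
        p4 = KineticParameters(K1=0.3, k2=0.3, k3=0.02, k4=1e-10, vb=0.05)
        t3 = model_tac(p3, IRREVERSIBLE_2TC, cp, schedule).values
        t4 = model_tac(p4, REVERSIBLE_2TC, cp, schedule).values
        np.testing.assert_allclose(t4, t3, rtol=1e-7)

    def test_pure_blood_signal(self, cp, schedule):
        p = KineticParameters(K1=0.0, k2=0.0, vb=0.05)
        tac = model_tac(p, ONE_TISSUE, cp, schedule)
        np.testing.assert_allclose(tac.values, 0.05 * cp.frame_averages(schedule), rtol=1e-12)

    def test_frame_average_lies_within_instantaneous_range(self, cp, schedule, lesion_params):
        for spec, p in [
            (REVERSIBLE_2TC, lesion_params.with_(k4=0.02)),
            (IRREVERSIBLE_2TC, lesion_params),
            (ONE_TISSUE, KineticParameters(K1=0.3, k2=0.4, vb=0.1)),
        ]:
            tac = model_tac(p, spec, cp, schedule)
            for i in range(schedule.n_frames):
                fine = np.linspace(schedule.start_times[i], schedule.end_times[i], 60)
                inst = model_conc(p, spec, cp, fine)
                assert inst.min() - 1e-9 <= tac.values[i] <= inst.max() + 1e-9

    def test_late_patlak_slope_of_irreversible_tac_equals_ki(self, cp, schedule, lesion_params):
        # the integral-normalised late TAC slope is the net influx rate
        p = lesion_params.with_(vb=0.0)
        t = np.linspace(30.0, 45.0, 50)
        y = model_conc(p, IRREVERSIBLE_2TC, cp, t) / cp(t)
        x = cp.integral(t) / cp(t)
        slope = np.polyfit(x, y, 1)[0]
        assert slope == pytest.approx(p.ki, rel=0.02)

    def test_model_spec_validation(self, cp, schedule):
        with pytest.raises(KineticsError):
            model_tac(
                KineticParameters(K1=0.1, k2=0.1, k3=0.1), ONE_TISSUE, cp, schedule
            )
        with pytest.raises(KineticsError):
            model_tac(
                KineticParameters(K1=0.1, k2=0.1, k3=0.1, k4=0.1),
                IRREVERSIBLE_2TC, cp, schedule,
            )


class TestTimeActivityCurve:
    def test_weights_default_to_frame_durations(self, schedule):
        tac = TimeActivityCurve(schedule, np.ones(schedule.n_frames))
        np.testing.assert_allclose(
            tac.weights, schedule.durations / schedule.durations.max()
        )
        with pytest.raises(KineticsError):
            TimeActivityCurve(schedule, np.ones(schedule.n_frames - 1))
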