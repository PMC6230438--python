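"""Closed-form phase and cycle durations of the half-center pair."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from limbcpg import (
    CycleSolution,
    HalfCenterParams,
    LimbCPGParams,
    NonPositiveRateError,
    SaturationError,
    ThresholdCrossingError,
    cycle_duration,
    phase_duration_exact,
    phase_duration_taylor,
    rational_coefficients,
)

# drive corresponding to 1 m/s through the printed regression
U_UNIT_SPEED = (1.0 + 0.1272) / 0.2357


class TestRationalCoefficients:
    @pytest.mark.parametrize(
        "hc1, hc2, expected",
        [
            # optimised cat parameters: sums/products of offsets and gains
            (
                (-0.0007, 0.6203),
                (2.4256, 0.4882),
                (2.4249, 1.1085, -0.00169792, 1.50425794, 0.30283046),
            ),
            # symmetric zero-gain pair
            ((1.0, 0.0), (1.0, 0.0), (2.0, 0.0, 1.0, 0.0, 0.0)),
            # pure-gain pair
            ((0.0, 1.0), (0.0, 1.0), (0.0, 2.0, 0.0, 0.0, 1.0)),
        ],
    )
    def test_coefficient_formulas(self, hc1, hc2, expected):
        params = LimbCPGParams(
            hc1=HalfCenterParams(*hc1), hc2=HalfCenterParams(*hc2), r_leak=0.0
        )
        c = rational_coefficients(params)
        assert (c.a, c.b, c.a_t, c.b_t, c.c_t) == pytest.approx(expected, rel=1e-12)

    @given(
        x01=st.floats(-1, 3), x02=st.floats(-1, 3),
        g1=st.floats(0, 3), g2=st.floats(0, 3),
    )
    @settings(max_examples=100, deadline=None)
    def test_pure_function_of_params(self, x01, x02, g1, g2):
        """Coefficients depend on the half-centers only, not the leak."""
        for r in (0.0, -0.01):
            c = rational_coefficients(
                LimbCPGParams(
                    hc1=HalfCenterParams(x01, g1),
                    hc2=HalfCenterParams(x02, g2),
                    r_leak=r,
                )
            )
            assert c.a == x01 + x02
            assert c.c_t == g1 * g2


class TestPhaseDurationTaylor:
    def test_unit_speed_extensor_phase(self):
        hc = HalfCenterParams(x0=2.4256, g=0.4882)
        assert phase_duration_taylor(hc, U_UNIT_SPEED) == pytest.approx(
            0.21006887478376363, rel=1e-12
        )

    def test_unit_rate(self):
        assert phase_duration_taylor(HalfCenterParams(1.0, 0.0), 42.0) == 1.0

    def test_negative_offset_rejects_zero_drive(self):
        hc = HalfCenterParams(x0=-0.0007, g=0.6203)
        with pytest.raises(NonPositiveRateError) as exc:
            phase_duration_taylor(hc, 0.0)
        assert exc.value.u_min == pytest.approx(0.0007 / 0.6203, rel=1e-9)

    def test_u_min_none_without_gain(self):
        with pytest.raises(NonPositiveRateError) as exc:
            phase_duration_taylor(HalfCenterParams(-1.0, 0.0), 5.0)
        assert exc.value.u_min is None


class TestPhaseDurationExact:
    def test_unit_speed_extensor_phase(self):
        """Frozen value from an adaptive-step integration to threshold."""
        hc = HalfCenterParams(x0=2.4256, g=0.4882)
        t = phase_duration_exact(hc, -0.0094, U_UNIT_SPEED)
        assert t == pytest.approx(0.2102765542056751, rel=1e-10)

    def test_matches_independent_ode_integrator(self):
        """Cross-check against scipy's event-detecting ODE solver."""
        solve_ivp = pytest.importorskip("scipy.integrate").solve_ivp
        hc = HalfCenterParams(x0=-0.0007, g=0.6203)
        r = -0.0094
        rate = hc.rate(U_UNIT_SPEED)
        event = lambda t, y: y[0] - 1.0
        event.terminal = True
        event.direction = 1
        sol = solve_ivp(
            lambda t, y: [rate + r * y[0]], [0, 10], [0.0],
            events=event, rtol=1e-12, atol=1e-14,
        )
        assert phase_duration_exact(hc, r, U_UNIT_SPEED) == pytest.approx(
            sol.t_events[0][0], rel=1e-8
        )

    def test_zero_leak_equals_taylor(self):
        hc = HalfCenterParams(x0=0.7, g=0.3)
        assert phase_duration_exact(hc, 0.0, 2.0) == phase_duration_taylor(hc, 2.0)

    def test_saturation_below_threshold(self):
        """Rate below |r_leak|: the state saturates below 1."""
        with pytest.raises(SaturationError):
            phase_duration_exact(HalfCenterParams(0.001, 0.0), -0.0094, 0.0)

    def test_saturation_distinct_from_nonpositive_rate(self):
        with pytest.raises(NonPositiveRateError):
            phase_duration_exact(HalfCenterParams(-0.5, 0.0), -0.0094, 0.0)

    @given(
        x0=st.floats(0.2, 3.0), g=st.floats(0.0, 2.0), u=st.floats(0.0, 10.0),
        r=st.floats(-0.05, -1e-6),
    )
    @settings(max_examples=200, deadline=None)
    def test_leak_lengthens_the_phase(self, x0, g, u, r):
        """Negative leak always slows the climb to threshold."""
        hc = HalfCenterParams(x0, g)
        assert phase_duration_exact(hc, r, u) >= phase_duration_taylor(hc, u)

    def test_taylor_is_small_leak_limit(self):
        """Exact-vs-Taylor discrepancy shrinks ~linearly in |r_leak|."""
        hc = HalfCenterParams(x0=2.4256, g=0.4882)
        errs = []
        for r in (-1e-2, -1e-4, -1e-6):
            errs.append(
                abs(phase_duration_exact(hc, r, U_UNIT_SPEED)
                    - phase_duration_taylor(hc, U_UNIT_SPEED))
            )
        ratios = [errs[i] / errs[i + 1] for i in range(2)]
        for ratio in ratios:  # each |r| drop by 100x shrinks the error ~100x
            assert 50 < ratio < 200


class TestCycleDuration:
    def test_unit_speed_taylor(self, params):
        sol = cycle_duration(params, U_UNIT_SPEED, method="taylor")
        assert sol.tau1 == pytest.approx(0.337178064508358, rel=1e-12)
        assert sol.tau2 == pytest.approx(0.21006887478376363, rel=1e-12)
        assert sol.Tc == pytest.approx(0.5472469392921216, rel=1e-12)

    def test_symmetric_unit_cycle(self):
        params = LimbCPGParams(
            hc1=HalfCenterParams(0.0, 1.0), hc2=HalfCenterParams(0.0, 1.0), r_leak=0.0
        )
        sol = cycle_duration(params, 2.0, method="taylor")
        assert sol == CycleSolution(tau1=0.5, tau2=0.5, Tc=1.0)

    def test_exact_close_to_taylor_for_small_leak(self, params):
        a = cycle_duration(params, U_UNIT_SPEED, method="exact").Tc
        t = cycle_duration(params, U_UNIT_SPEED, method="taylor").Tc
        assert abs(a - t) / t < 0.01

    def test_taylor_sum_equals_rational_form(self, params):
        coeffs = rational_coefficients(params)
        for u in np.linspace(0.5, 12.0, 40):
            Tc = cycle_duration(params, float(u), method="taylor").Tc
            assert Tc == pytest.approx(coeffs(float(u)), rel=1e-12)

    def test_strictly_decreasing_in_drive(self, params):
        us = np.linspace(1.0, 10.0, 200)
        Tcs = [cycle_duration(params, float(u), method="exact").Tc for u in us]
        assert all(a > b for a, b in zip(Tcs, Tcs[1:]))

    def test_error_labelled_by_phase(self, params):
        with pytest.raises(ThresholdCrossingError, match="phase 1"):
            cycle_duration(params, 0.0, method="taylor")

    def test_invalid_method(self, params):
        with pytest.raises(ValueError, match="method"):
            cycle_duration(params, 1.0, method="euler")


class TestTypeInvariants:
    def test_positive_leak_rejected(self):
        with pytest.raises(ValueError, match="r_leak"):
            LimbCPGParams(
                hc1=HalfCenterParams(1, 1), hc2=HalfCenterParams(1, 1), r_leak=0.01
            )

    def test_threshold_fixed_at_one(self):
        with pytest.raises(ValueError, match="threshold"):
            LimbCPGParams(
                hc1=HalfCenterParams(1, 1), hc2=HalfCenterParams(1, 1),
                r_leak=0.0, threshold=2.0,
            )

    def test_non_finite_offset_rejected(self):
        with pytest.raises(ValueError):
            HalfCenterParams(x0=float("nan"), g=1.0)

    def test_cycle_solution_requires_positive_phases(self):
        with pytest.raises(ValueError):
            CycleSolution.from_phases(-0.1, 0.2)
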