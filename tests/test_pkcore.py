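"""Two-compartment kinetics: reparameterization, closed form vs ODE oracle, limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad, solve_ivp

from remipk import (
    DoseEvent,
    PKParameters,
    Regimen,
    concentration,
    micro_constants,
    time_to_css_fraction,
)
from remipk.pkcore import accumulation_fraction, steady_state_concentration


def _ode_concentration(params, regimen, times, rtol=1e-10):
    """Independent oracle: adaptive integration of the compartmental ODEs."""
    k10 = params.cl / params.v1
    k12 = params.q / params.v1
    k21 = params.q / params.v2

    def rate_in(t):
        return sum(e.rate for e in regimen.events if e.start <= t < e.end)

    def rhs(t, a):
        return [rate_in(t) - (k10 + k12) * a[0] + k21 * a[1],
                k12 * a[0] - k21 * a[1]]

    t_end = max(np.max(times), regimen.end_time) + 1e-9
    switches = sorted({e.start for e in regimen.events}
                      | {e.end for e in regimen.events} | {0.0, t_end})
    sol = solve_ivp(rhs, (0.0, t_end), [0.0, 0.0], t_eval=np.sort(times),
                    rtol=rtol, atol=1e-12, max_step=0.05,
                    method="LSODA")
    order = np.argsort(times)
    out = np.empty_like(np.asarray(times, float))
    out[order] = sol.y[0] / params.v1 * 1000.0
    return out


class TestMicroConstants:
    def test_table_values(self, typical_params):
        h = micro_constants(typical_params)
        assert h.k10 == pytest.approx(58.2 / 25.5, rel=1e-12)
        assert h.k12 == pytest.approx(20.0 / 25.5, rel=1e-12)
        assert h.k21 == pytest.approx(20.0 / 34.5, rel=1e-12)
        # quadratic-root oracle for the hybrid exponents
        roots = np.roots([1.0, -(h.k10 + h.k12 + h.k21), h.k10 * h.k21])
        assert h.lambda_fast == pytest.approx(max(roots), rel=1e-10)
        assert h.lambda_slow == pytest.approx(min(roots), rel=1e-10)
        assert h.lambda_slow == pytest.approx(0.409, abs=5e-4)
        assert h.t_half_slow == pytest.approx(1.70, abs=0.01)

    def test_invariants_random_params(self, rng):
        for _ in range(50):
            cl, v1, q, v2 = np.exp(rng.normal(np.log([50, 25, 20, 35]), 0.8))
            h = micro_constants(PKParameters(cl, v1, q, v2))
            assert h.lambda_fast > h.lambda_slow > 0
            assert h.lambda_fast * h.lambda_slow == pytest.approx(
                h.k10 * h.k21, rel=1e-9
            )
            assert h.lambda_fast + h.lambda_slow == pytest.approx(
                h.k10 + h.k12 + h.k21, rel=1e-9
            )
            assert h.t_half_slow == pytest.approx(np.log(2) / h.lambda_slow)

    def test_small_q_limit_degenerates_to_one_compartment(self):
        p = PKParameters(58.2, 25.5, 1e-6, 34.5)
        h = micro_constants(p)
        # small-Q expansion: slow root -> k10*k21/(k10+k12+k21), fast -> k10
        assert h.lambda_slow == pytest.approx(
            h.k10 * h.k21 / (h.k10 + h.k12 + h.k21), rel=1e-4
        )
        assert h.lambda_fast == pytest.approx(h.k10, rel=1e-4)

    @pytest.mark.parametrize("bad", [
        dict(cl=0.0, v1=25.5, q=20.0, v2=34.5),
        dict(cl=58.2, v1=-1.0, q=20.0, v2=34.5),
        dict(cl=58.2, v1=25.5, q=float("nan"), v2=34.5),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            PKParameters(**bad)


class TestConcentration:
    def test_steady_state_is_rate_over_cl(self, typical_params):
        reg = Regimen.constant_infusion(12.0, 1e6)
        c = concentration(typical_params, reg, [1e5])
        assert c[0] == pytest.approx(12.0 / 58.2 * 1000.0, rel=1e-9)
        assert steady_state_concentration(typical_params, 12.0) == pytest.approx(
            206.2, abs=0.05
        )

    def test_matches_ode_integration_short_infusion(self, typical_params):
        reg = Regimen.constant_infusion(12.0, 0.5)
        times = [0.1, 0.25, 0.5, 0.75, 1.0, 2.0, 4.0]
        closed = concentration(typical_params, reg, times)
        oracle = _ode_concentration(typical_params, reg, times)
        np.testing.assert_allclose(closed, oracle, rtol=1e-6)
        assert closed[2] == pytest.approx(122.0, rel=0.01)  # end of 0.5-h infusion

    def test_matches_ode_on_random_draws(self, rng):
        for _ in range(8):
            cl, v1, q, v2 = np.exp(rng.normal(np.log([50, 25, 20, 35]), 0.6))
            p = PKParameters(cl, v1, q, v2)
            events = tuple(
                DoseEvent(start=float(rng.uniform(0, 3)),
                          rate=float(rng.uniform(2, 18)),
                          duration=float(rng.uniform(0.5, 6)))
                for _ in range(rng.integers(1, 4))
            )
            reg = Regimen(events)
            times = np.sort(rng.uniform(0.0, reg.end_time + 4.0, size=12))
            np.testing.assert_allclose(
                concentration(p, reg, times),
                _ode_concentration(p, reg, times),
                rtol=1e-6, atol=1e-9,
            )

    def test_superposition_linearity(self, typical_params, rng):
        r1 = Regimen.constant_infusion(6.0, 2.0)
        r2 = Regimen((DoseEvent(start=1.0, rate=4.0, duration=3.0),))
        both = Regimen(r1.events + r2.events)
        t = np.linspace(0.0, 8.0, 40)
        np.testing.assert_allclose(
            concentration(typical_params, both, t),
            concentration(typical_params, r1, t) + concentration(typical_params, r2, t),
            rtol=1e-9, atol=1e-12,
        )

    def test_dose_proportionality(self, typical_params):
        t = np.linspace(0.0, 10.0, 25)
        c1 = concentration(typical_params, Regimen.constant_infusion(6.0, 4.0), t)
        c2 = concentration(typical_params, Regimen.constant_infusion(12.0, 4.0), t)
        np.testing.assert_allclose(c2, 2.0 * c1, rtol=1e-12)

    def test_post_infusion_strictly_decreasing(self, typical_params):
        reg = Regimen.constant_infusion(12.0, 8.0)
        t = np.linspace(8.0, 20.0, 200)
        c = concentration(typical_params, reg, t)
        assert np.all(np.diff(c) < 0)

    def test_mass_balance_total_elimination(self, typical_params):
        # all infused drug is eventually cleared: CL * AUC(0, inf) = dose
        reg = Regimen.constant_infusion(12.0, 3.0)
        auc, _ = quad(
            lambda t: concentration(typical_params, reg, [t])[0] / 1000.0,
            0.0, 200.0, limit=400,
        )
        assert typical_params.cl * auc == pytest.approx(reg.total_dose, rel=1e-4)

    def test_empty_and_zero_rate_regimens(self, typical_params):
        t = [0.0, 1.0, 5.0]
        assert np.all(concentration(typical_params, Regimen(()), t) == 0.0)
        zero = Regimen.constant_infusion(0.0, 4.0)
        assert np.all(concentration(typical_params, zero, t) == 0.0)

    def test_negative_time_rejected(self, typical_params, infusion_12mgh):
        with pytest.raises(ValueError, match="times"):
            concentration(typical_params, infusion_12mgh, [-0.5])

    def test_loading_dose_is_one_minute_infusion(self, typical_params):
        reg = Regimen.loading_plus_maintenance(6.0, 12.0, 8.0)
        assert reg.events[0].duration == pytest.approx(1.0 / 60.0)
        assert reg.events[0].amount == pytest.approx(6.0)
        assert reg.total_dose == pytest.approx(6.0 + 96.0)


_positive = st.floats(min_value=1.0, max_value=200.0)


class TestKineticsProperties:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(cl=_positive, v1=_positive, q=_positive, v2=_positive,
           rate=st.floats(2.0, 18.0), duration=st.floats(0.5, 24.0))
    def test_physical_invariants_hold_for_any_parameters(
        self, cl, v1, q, v2, rate, duration
    ):
        p = PKParameters(cl, v1, q, v2)
        h = micro_constants(p)
        assert h.lambda_fast >= h.lambda_slow > 0
        reg = Regimen.constant_infusion(rate, duration)
        t = np.linspace(0.0, duration + 6.0, 60)
        c = concentration(p, reg, t)
        assert np.all(c >= 0.0)
        assert np.all(np.isfinite(c))
        # never exceeds the steady-state plateau under a single infusion
        assert c.max() <= rate / cl * 1000.0 * (1 + 1e-9)
        # doubling the rate doubles the profile
        c2 = concentration(p, Regimen.constant_infusion(2 * rate, duration), t)
        np.testing.assert_allclose(c2, 2.0 * c, rtol=1e-9)


class TestTimeToSteadyState:
    def test_definition_and_monotonicity(self, typical_params):
        t90 = time_to_css_fraction(typical_params, 12.0, 0.9)
        assert accumulation_fraction(typical_params, t90) == pytest.approx(0.9, abs=1e-9)
        assert float(accumulation_fraction(typical_params, 0.99 * t90)) < 0.9
        t50 = time_to_css_fraction(typical_params, 12.0, 0.5)
        t99 = time_to_css_fraction(typical_params, 12.0, 0.99)
        assert t50 < t90 < t99

    def test_rate_independence(self, typical_params):
        t_a = time_to_css_fraction(typical_params, 6.0, 0.9)
        t_b = time_to_css_fraction(typical_params, 12.0, 0.9)
        assert t_a == pytest.approx(t_b, rel=1e-12)

    def test_small_fraction_small_time(self, typical_params):
        assert time_to_css_fraction(typical_params, 12.0, 1e-6) < 1e-3

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.1, 1.5])
    def test_fraction_domain(self, typical_params, frac):
        with pytest.raises(ValueError):
            time_to_css_fraction(typical_params, 12.0, frac)
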