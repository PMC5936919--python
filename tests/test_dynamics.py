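"""Recirculating extraction dynamics: factors, efficiency, time course."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from pertraction import (
    ExtractionFactors,
    extraction_factor_E,
    kw_from_phi,
    mass_balance_metrics,
    module_efficiency_phi,
    reservoir_factor_R,
    simulate_timecourse,
)

ML = 1e-6
ML_MIN = 1e-6 / 60.0


class TestExtractionFactors:
    def test_unit_factor(self):
        assert extraction_factor_E(1.0, 2.0, 2.0) == 1.0

    def test_reference_flows(self):
        assert extraction_factor_E(600.0, 40 * ML_MIN, 3 * ML_MIN) == pytest.approx(8000.0)

    def test_linear_in_partition(self):
        assert extraction_factor_E(20.0, 1.0, 2.0) == 2 * extraction_factor_E(10.0, 1.0, 2.0)

    def test_reservoir_factor(self):
        assert reservoir_factor_R(2.0, 1.0, 2.0) == 1.0
        assert reservoir_factor_R(600.0, 50 * ML, 100 * ML) == pytest.approx(300.0)
        assert reservoir_factor_R(5.0, 3.0, 7.0) == reservoir_factor_R(5.0, 6.0, 14.0)

    def test_zero_denominators_rejected(self):
        with pytest.raises(ValueError):
            extraction_factor_E(1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            reservoir_factor_R(1.0, 1.0, 0.0)


class TestModuleEfficiency:
    def test_zero_transfer_means_zero_efficiency(self):
        assert module_efficiency_phi(0.0, 56e-4, 3 * ML_MIN, 100.0) == 0.0

    def test_infinite_extraction_factor_limit(self):
        x = 0.5
        K_w, A, Q_w = 1.0, x, 1.0
        phi = module_efficiency_phi(K_w, A, Q_w, 1e12)
        assert phi == pytest.approx(1 - np.exp(-x), rel=1e-9)

    def test_saturates_to_one_at_large_transfer(self):
        phi = module_efficiency_phi(1.0, 1000.0, 1.0, 1e12)
        assert phi == pytest.approx(1.0, abs=1e-9)

    def test_unity_extraction_factor_uses_analytic_limit(self):
        x = 0.7
        phi = module_efficiency_phi(x, 1.0, 1.0, 1.0)
        assert phi == pytest.approx(x / (1 + x), rel=1e-12)
        # continuity across the switch
        near = module_efficiency_phi(x, 1.0, 1.0, 1.0 + 1e-7)
        assert near == pytest.approx(phi, rel=1e-6)

    @given(
        x1=st.floats(0.01, 5.0),
        bump=st.floats(1.01, 5.0),
        E=st.floats(1.5, 1e4),
    )
    @settings(derandomize=True, max_examples=60)
    def test_strictly_increasing_in_transfer_and_bounded(self, x1, bump, E):
        p1 = module_efficiency_phi(x1, 1.0, 1.0, E)
        p2 = module_efficiency_phi(x1 * bump, 1.0, 1.0, E)
        assert 0 < p1 < p2 < 1

    @given(x=st.floats(0.01, 5.0), E1=st.floats(1.5, 100.0), bump=st.floats(1.1, 10.0))
    @settings(derandomize=True, max_examples=60)
    def test_increasing_in_extraction_factor(self, x, E1, bump):
        assert module_efficiency_phi(x, 1.0, 1.0, E1 * bump) >= module_efficiency_phi(
            x, 1.0, 1.0, E1
        )


class TestKwFromPhi:
    @pytest.mark.parametrize("K_w", [1e-7, 2.2e-6, 1e-5])
    @pytest.mark.parametrize("E", [1.5, 50.0, 1e6])
    def test_round_trip_identity(self, K_w, E):
        A, Q_w = 56e-4, 3 * ML_MIN
        phi = module_efficiency_phi(K_w, A, Q_w, E)
        assert kw_from_phi(phi, A, Q_w, E) == pytest.approx(K_w, rel=1e-9)

    def test_matches_closed_form_at_infinite_extraction_factor(self):
        A, Q_w, phi = 56e-4, 40 * ML_MIN, 0.05
        closed = -Q_w * np.log(1 - phi) / A
        assert kw_from_phi(phi, A, Q_w, 1e12) == pytest.approx(closed, rel=1e-9)

    def test_infeasible_efficiency_explained(self):
        with pytest.raises(ValueError, match="not attainable"):
            kw_from_phi(0.6, 1.0, 1.0, 0.5)  # sup = E = 0.5


class TestSimulateTimecourse:
    @staticmethod
    def factors(phi=0.222, P=600.0, Q_s=40 * ML_MIN, Q_w=3 * ML_MIN,
                V_s=50 * ML, V_w=100 * ML):
        return ExtractionFactors(
            E=extraction_factor_E(P, Q_s, Q_w),
            R=reservoir_factor_R(P, V_s, V_w),
            phi=phi,
        )

    def test_initial_condition(self):
        course = simulate_timecourse(self.factors(), 3 * ML_MIN, 100 * ML, 0.15,
                                     50 * ML, [0.0, 60.0])
        assert course.c_w[0] == pytest.approx(0.15)
        assert course.c_s[0] == pytest.approx(0.0, abs=1e-15)

    def test_equilibrium_limit_and_phase_ratio(self):
        P = 600.0
        f = self.factors(P=P)
        course = simulate_timecourse(f, 3 * ML_MIN, 100 * ML, 0.15, 50 * ML,
                                     [0.0, 1e9])
        assert course.c_w[-1] == pytest.approx(0.15 / (1 + f.R), rel=1e-9)
        assert course.c_s[-1] / course.c_w[-1] == pytest.approx(P, rel=1e-9)

    def test_mass_conserved_everywhere(self):
        V_w, V_s, c0 = 100 * ML, 50 * ML, 0.15
        course = simulate_timecourse(self.factors(), 3 * ML_MIN, V_w, c0, V_s,
                                     np.linspace(0, 8 * 3600, 200))
        total = V_w * course.c_w + V_s * course.c_s
        assert np.allclose(total, V_w * c0, rtol=1e-12, atol=0)

    def test_monotone_traces(self):
        course = simulate_timecourse(self.factors(), 3 * ML_MIN, 100 * ML, 0.15,
                                     50 * ML, np.linspace(0, 8 * 3600, 50))
        assert np.all(np.diff(course.c_w) < 0)
        assert np.all(np.diff(course.c_s) > 0)

    @pytest.mark.parametrize(
        "phi,P,Q_w,V_w,V_s",
        [
            (0.222, 600.0, 3 * ML_MIN, 100 * ML, 50 * ML),
            (0.05, 600.0, 40 * ML_MIN, 100 * ML, 50 * ML),
            (0.5, 10.0, 10 * ML_MIN, 200 * ML, 200 * ML),
            (0.9, 2.0, 1 * ML_MIN, 50 * ML, 100 * ML),
        ],
    )
    def test_closed_form_matches_ode_integration(self, phi, P, Q_w, V_w, V_s):
        """Independent oracle: numerically integrate the reservoir balance."""
        f = self.factors(phi=phi, P=P, Q_w=Q_w, V_s=V_s, V_w=V_w)
        c0 = 0.15
        times = np.linspace(0, 8 * 3600, 9)
        course = simulate_timecourse(f, Q_w, V_w, c0, V_s, times)

        def rhs(t, c):
            return [-(Q_w * phi / V_w) * (c[0] * (1 + 1 / f.R) - c0 / f.R)]

        sol = solve_ivp(rhs, (0, times[-1]), [c0], t_eval=times,
                        rtol=1e-11, atol=1e-14, method="LSODA")
        assert np.allclose(course.c_w, sol.y[0], rtol=1e-8)

    def test_linearization_is_exactly_linear(self):
        f = self.factors()
        Q_w, V_w = 3 * ML_MIN, 100 * ML
        times = np.linspace(0, 8 * 3600, 9)
        course = simulate_timecourse(f, Q_w, V_w, 0.15, 50 * ML, times)
        y = np.log((1 + 1 / f.R) * course.c_w / 0.15 - 1 / f.R)
        slope_expected = -(Q_w * f.phi / V_w) * (1 + 1 / f.R)
        slopes = y[1:] / times[1:]
        assert np.allclose(slopes, slope_expected, rtol=1e-10)

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError):
            simulate_timecourse(self.factors(), 3 * ML_MIN, 100 * ML, 0.15,
                                50 * ML, [0.0, 60.0, 30.0])


class TestMassBalanceMetrics:
    def test_lossless_simulation_has_unit_recovery(self):
        f = TestSimulateTimecourse.factors()
        course = simulate_timecourse(f, 3 * ML_MIN, 100 * ML, 0.15, 50 * ML,
                                     np.linspace(0, 8 * 3600, 20))
        metrics = mass_balance_metrics(course, 100 * ML, 50 * ML)
        assert np.allclose(metrics["recovery"], 1.0, rtol=1e-12)

    def test_start_of_run_is_unenriched(self):
        f = TestSimulateTimecourse.factors()
        course = simulate_timecourse(f, 3 * ML_MIN, 100 * ML, 0.15, 50 * ML, [0.0, 60.0])
        metrics = mass_balance_metrics(course, 100 * ML, 50 * ML)
        assert metrics["concentration_factor"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert metrics["enrichment"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_to_one_phase_ratio_concentrates_twofold(self):
        """At R >> 1 the 2:1 aqueous:organic ratio doubles the concentration."""
        f = TestSimulateTimecourse.factors(P=600.0)
        course = simulate_timecourse(f, 3 * ML_MIN, 100 * ML, 0.15, 50 * ML, [0.0, 1e9])
        metrics = mass_balance_metrics(course, 100 * ML, 50 * ML)
        expected = 2.0 * f.R / (f.R + 1)
        assert metrics["concentration_factor"].iloc[-1] == pytest.approx(expected, rel=1e-9)
        assert metrics["concentration_factor"].iloc[-1] == pytest.approx(2.0, rel=0.01)

    def test_zero_initial_concentration_rejected(self):
        f = TestSimulateTimecourse.factors()
        course = simulate_timecourse(f, 3 * ML_MIN, 100 * ML, 0.15, 50 * ML, [0.0, 60.0])
        with pytest.raises(ValueError):
            mass_balance_metrics(course, 100 * ML, 50 * ML, c_w0=0.0)
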