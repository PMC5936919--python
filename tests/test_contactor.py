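"""Module geometry and film/overall mass-transfer coefficients."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pertraction import (
    Diffusivity,
    MembraneModule,
    Mode,
    k_fibre_leveque,
    k_membrane,
    k_shell_parallel_flow,
    log_mean_diameter,
    overall_kw,
)
from pertraction.contactor import LowGraetzWarning, graetz_number

ML_MIN = 1e-6 / 60.0


class TestLogMeanDiameter:
    def test_equal_diameter_limit(self):
        assert log_mean_diameter(3e-3, 3e-3) == pytest.approx(3e-3)

    def test_hand_value(self):
        assert log_mean_diameter(3e-3, 4e-3) == pytest.approx(1e-3 / math.log(4 / 3))

    @given(
        d_i=st.floats(1e-4, 1e-2),
        ratio=st.floats(1.0001, 3.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_strictly_between_bounds(self, d_i, ratio):
        d_o = d_i * ratio
        d_lm = log_mean_diameter(d_i, d_o)
        assert d_i < d_lm < d_o

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log_mean_diameter(0.0, 1e-3)


class TestModuleGeometry:
    def test_reference_inner_area_matches_56_cm2(self, module):
        assert module.inner_area * 1e4 == pytest.approx(56.0, rel=0.015)

    def test_derived_quantities_consistent(self, module):
        n, d_o, d_s = module.n_fibres, module.d_o, module.shell_inner_diameter
        assert module.packing_fraction == pytest.approx(n * d_o**2 / d_s**2)
        assert module.hydraulic_diameter == pytest.approx((d_s**2 - n * d_o**2) / (n * d_o))
        assert module.d_i < module.log_mean_diameter < module.d_o

    def test_overfull_shell_rejected(self):
        with pytest.raises(ValueError, match="packing"):
            MembraneModule(n_fibres=3, d_i=3e-3, d_o=6e-3, length=0.2,
                           shell_inner_diameter=10e-3)

    def test_inverted_wall_rejected(self):
        with pytest.raises(ValueError):
            MembraneModule(n_fibres=3, d_i=3e-3, d_o=2e-3, length=0.2)


class TestFibreLeveque:
    def test_reference_value(self, d_water):
        k = k_fibre_leveque(d_water, 3e-3, 1 * ML_MIN, 0.2)
        assert k == pytest.approx(2.0e-6, rel=0.02)

    def test_cube_root_flow_scaling(self, d_water):
        k1 = k_fibre_leveque(d_water, 3e-3, 1 * ML_MIN, 0.2)
        k8 = k_fibre_leveque(d_water, 3e-3, 8 * ML_MIN, 0.2)
        assert k8 == pytest.approx(2 * k1, rel=1e-9)

    def test_sherwood_restatement_consistent(self, d_water):
        # Sh = k·d_i/D must equal 1.62·Gz^(1/3)
        d_i, L, q = 3e-3, 0.2, 1 * ML_MIN
        k = k_fibre_leveque(d_water, d_i, q, L)
        gz = graetz_number(q, d_i, L, d_water)
        assert k * d_i / d_water.value == pytest.approx(1.62 * gz ** (1 / 3), rel=1e-12)

    def test_low_graetz_warns(self):
        slow_diffusing = Diffusivity(1e-9, "x", "w", 298.15)
        tiny_flow = 1e-11  # m³/s: Gz far below 4
        with pytest.warns(LowGraetzWarning):
            k_fibre_leveque(slow_diffusing, 3e-3, tiny_flow, 0.2)

    def test_zero_flow_rejected(self, d_water):
        with pytest.raises(ValueError):
            k_fibre_leveque(d_water, 3e-3, 0.0, 0.2)


class TestShellParallelFlow:
    def test_reynolds_exponent_scaling(self, d_heptane, module, heptane):
        k1 = k_shell_parallel_flow(d_heptane, module, 40 * ML_MIN, heptane)
        k2 = k_shell_parallel_flow(d_heptane, module, 80 * ML_MIN, heptane)
        assert k2 / k1 == pytest.approx(2**0.6, rel=1e-9)

    def test_frozen_reference_evaluation(self, d_heptane, module, heptane):
        # independent spreadsheet-style evaluation of the correlation for the
        # reference geometry (heptane shell flow at 40 ml/min), frozen value
        k = k_shell_parallel_flow(d_heptane, module, 40 * ML_MIN, heptane)
        assert k == pytest.approx(3.86729e-06, rel=1e-5)

    def test_full_packing_kills_transfer(self, d_heptane, heptane):
        almost_full = MembraneModule(
            n_fibres=3, d_i=3e-3, d_o=4e-3, length=0.2,
            shell_inner_diameter=math.sqrt(3 * 16e-6 / 0.999),
        )
        loose = MembraneModule(
            n_fibres=3, d_i=3e-3, d_o=4e-3, length=0.2, shell_inner_diameter=20e-3,
        )
        k_tight = k_shell_parallel_flow(d_heptane, almost_full, 40 * ML_MIN, heptane)
        k_loose = k_shell_parallel_flow(d_heptane, loose, 40 * ML_MIN, heptane)
        assert k_tight < 0.02 * k_loose

    def test_missing_shell_geometry_rejected(self, d_heptane, heptane):
        bare = MembraneModule(n_fibres=3, d_i=3e-3, d_o=4e-3, length=0.2)
        with pytest.raises(ValueError, match="shell"):
            k_shell_parallel_flow(d_heptane, bare, 40 * ML_MIN, heptane)


class TestMembraneCoefficient:
    def test_ideal_membrane(self):
        d = Diffusivity(2.3e-9, "x", "org", 298.15)
        mod = MembraneModule(n_fibres=1, d_i=3e-3, d_o=3.4e-3, length=0.2,
                             porosity=0.999999, tortuosity=1.0)
        assert k_membrane(d, mod) == pytest.approx(2 * 2.3e-9 / 0.4e-3, rel=1e-4)

    def test_hand_value(self):
        d = Diffusivity(2.3e-9, "x", "org", 298.15)
        mod = MembraneModule(n_fibres=1, d_i=3e-3, d_o=3.4e-3, length=0.2,
                             porosity=0.5, tortuosity=2.0)
        assert k_membrane(d, mod) == pytest.approx(2 * 0.5 * 2.3e-9 / (2.0 * 0.4e-3))

    def test_proportional_to_porosity_over_tortuosity(self):
        d = Diffusivity(2.3e-9, "x", "org", 298.15)
        a = MembraneModule(n_fibres=1, d_i=3e-3, d_o=3.4e-3, length=0.2,
                           porosity=0.3, tortuosity=1.5)
        b = MembraneModule(n_fibres=1, d_i=3e-3, d_o=3.4e-3, length=0.2,
                           porosity=0.6, tortuosity=3.0)
        assert k_membrane(d, a) == pytest.approx(k_membrane(d, b))


class TestOverallKw:
    def test_aqueous_film_controls_at_large_partition(self, module):
        bk = overall_kw(1e12, k_w=2e-6, k_o=4e-6, k_m=1e-6, module=module, mode="in-out")
        assert bk.K_w == pytest.approx(2e-6, rel=1e-4)
        assert bk.resistance_fractions[0] == pytest.approx(1.0, abs=1e-4)

    def test_matches_brute_force_resistance_sum(self, module):
        P, k_w, k_o, k_m = 630.0, 2e-6, 3.9e-6, 1.04e-6
        bk = overall_kw(P, k_w, k_o, k_m, module, "in-out")
        d_i, d_o, d_lm = module.d_i, module.d_o, module.log_mean_diameter
        expected = 1.0 / (
            d_i * (1 / (P * k_o * d_o) + 1 / (P * k_m * d_lm) + 1 / (k_w * d_i))
        )
        assert bk.K_w == pytest.approx(expected, rel=1e-12)

    def test_out_in_mode_swaps_diameter_basis(self, module):
        P, k_w, k_o, k_m = 630.0, 1.5e-6, 4.5e-6, 1.04e-6
        bk = overall_kw(P, k_w, k_o, k_m, module, "out-in")
        d_i, d_o, d_lm = module.d_i, module.d_o, module.log_mean_diameter
        expected = 1.0 / (
            d_o * (1 / (P * k_o * d_i) + 1 / (P * k_m * d_lm) + 1 / (k_w * d_o))
        )
        assert bk.K_w == pytest.approx(expected, rel=1e-12)
        assert bk.basis_diameter == d_o
        assert bk.k_shell == bk.k_aqueous

    def test_resistance_fractions_sum_to_one(self, module):
        bk = overall_kw(10.0, 2e-6, 4e-6, 1e-6, module, "in-out")
        assert sum(bk.resistance_fractions) == pytest.approx(1.0, abs=1e-12)
        assert all(f >= 0 for f in bk.resistance_fractions)

    @given(
        P=st.floats(0.1, 1e4),
        k_w=st.floats(1e-8, 1e-4),
        k_o=st.floats(1e-8, 1e-4),
        k_m=st.floats(1e-8, 1e-4),
        bump=st.floats(1.01, 10.0),
        which=st.sampled_from(["P", "k_w", "k_o", "k_m"]),
    )
    @settings(derandomize=True, max_examples=80)
    def test_monotone_in_every_coefficient(self, module, P, k_w, k_o, k_m, bump, which):
        args = {"P": P, "k_w": k_w, "k_o": k_o, "k_m": k_m}
        base = overall_kw(module=module, mode="in-out", **args).K_w
        args[which] *= bump
        assert overall_kw(module=module, mode="in-out", **args).K_w >= base

    def test_never_exceeds_aqueous_film(self, module):
        bk = overall_kw(5.0, 2e-6, 4e-6, 1e-6, module, "in-out")
        assert bk.K_w <= 2e-6

    def test_unknown_mode_rejected(self, module):
        with pytest.raises(ValueError, match="mode"):
            overall_kw(10.0, 2e-6, 4e-6, 1e-6, module, "sideways")
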