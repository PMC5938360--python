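"""Closed-form channel transport models against limits, scalings and the FD oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmgrowth.transport import (
    AbsorbingColonyParams,
    ChannelGeometry,
    GrowthKinetics,
    KineticUptakeParams,
    PermeationParams,
    accumulation_length,
    accumulation_profile,
    concentration_units,
    dead_end_fold_increase,
    doubling_time_profile,
    kinetic_depletion,
    mother_cell_doubling_time,
    nutrient_profile,
    screening_length,
    solve_transport_numerically,
)

GEOM = ChannelGeometry(width=0.9, height=1.15, length=50.0)
ABSORB = AbsorbingColonyParams(cell_radius=0.4, diffusion=700.0, k_abs=1.0)
PERM = PermeationParams(water_flux=7e-6, diffusion=70.0, water_density=1000.0)


class TestScreeningLength:
    def test_reference_arithmetic(self):
        # λ = sqrt((WH − πR²) D / (2π R k)) with the study channel and glucose D
        lam = screening_length(GEOM, ABSORB)
        free = 0.9 * 1.15 - math.pi * 0.4**2
        assert lam == pytest.approx(math.sqrt(free * 700.0 / (2 * math.pi * 0.4 * 1.0)), rel=1e-12)
        assert lam == pytest.approx(12.18, abs=0.01)

    def test_doubling_absorption_shrinks_by_sqrt2(self):
        doubled = AbsorbingColonyParams(0.4, 700.0, 2.0)
        assert screening_length(GEOM, doubled) == pytest.approx(
            screening_length(GEOM, ABSORB) / math.sqrt(2), rel=1e-12
        )

    def test_no_absorption_gives_infinite_length(self):
        lam = screening_length(GEOM, AbsorbingColonyParams(0.4, 700.0, 0.0))
        assert math.isinf(lam)

    def test_cells_filling_cross_section_refused(self):
        with pytest.raises(ValueError, match="fit"):
            screening_length(GEOM, AbsorbingColonyParams(0.6, 700.0, 1.0))

    def test_vanishing_free_cross_section_limit(self):
        # π R² → (W·H)⁻ : free cross-section ≈ 2.5e-4 μm², λ → 0
        tight = AbsorbingColonyParams(cell_radius=0.57387, diffusion=700.0, k_abs=1.0)
        assert screening_length(GEOM, tight) < 0.3
        assert screening_length(GEOM, tight) < screening_length(GEOM, ABSORB)


class TestNutrientProfile:
    def test_entrance_value_exact(self):
        res = nutrient_profile(GEOM, ABSORB, np.array([0.0, 25.0, 50.0]))
        assert res.values[0] == ABSORB.c0

    def test_no_absorption_flat_profile(self):
        res = nutrient_profile(GEOM, AbsorbingColonyParams(0.4, 700.0, 0.0), np.linspace(0, 50, 11))
        np.testing.assert_array_equal(res.values, ABSORB.c0)

    def test_deep_screening_asymptote(self):
        lam = screening_length(GEOM, ABSORB)
        geom = ChannelGeometry(0.9, 1.15, 20 * lam)
        res = nutrient_profile(geom, ABSORB, np.array([geom.length]))
        assert res.values[0] == pytest.approx(2 * math.exp(-20.0), rel=0.01)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        k=st.floats(0.01, 100.0),
        d=st.floats(50.0, 2000.0),
        length=st.floats(5.0, 200.0),
    )
    def test_monotone_nonincreasing(self, k, d, length):
        geom = ChannelGeometry(0.9, 1.15, length)
        params = AbsorbingColonyParams(0.4, d, k)
        res = nutrient_profile(geom, params, np.linspace(0, length, 101))
        assert np.all(np.diff(res.values) <= 1e-12)
        assert np.all(res.values > 0)

    def test_positions_outside_channel_refused(self):
        with pytest.raises(ValueError):
            nutrient_profile(GEOM, ABSORB, np.array([-1.0]))


class TestDoublingTimeProfile:
    KIN = GrowthKinetics(td_min=23.0, td_liquid=26.0)

    def test_entrance_returns_liquid_value(self):
        res = doubling_time_profile(GEOM, ABSORB, self.KIN, np.array([0.0]))
        assert res.values[0] == pytest.approx(26.0, rel=1e-12)

    def test_no_limitation_constant(self):
        kin = GrowthKinetics(td_min=25.0, td_liquid=25.0)
        res = doubling_time_profile(GEOM, ABSORB, kin, np.linspace(0, 50, 7))
        np.testing.assert_allclose(res.values, 25.0, rtol=1e-12)

    def test_liquid_below_minimum_refused(self):
        with pytest.raises(ValueError):
            GrowthKinetics(td_min=25.0, td_liquid=20.0)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        k=st.floats(0.05, 20.0),
        td_min=st.floats(15.0, 40.0),
        excess=st.floats(0.1, 40.0),
        length=st.floats(5.0, 100.0),
    )
    def test_equals_saturation_kinetics_applied_to_concentration(
        self, k, td_min, excess, length
    ):
        """The doubling-time profile must equal Michaelis–Menten growth kinetics
        composed with the screening concentration profile (independent route)."""
        geom = ChannelGeometry(0.9, 1.15, length)
        params = AbsorbingColonyParams(0.4, 700.0, k, c0=2.5)
        kin = GrowthKinetics(td_min=td_min, td_liquid=td_min + excess)
        x = np.linspace(0, length, 31)
        direct = doubling_time_profile(geom, params, kin, x).values
        # independent route: Td(x) = td_min (1 + K / c(x)) with K from the
        # liquid-culture identity td_liquid = td_min (1 + K/c0)
        K = kin.saturation_constant(params.c0)
        c = nutrient_profile(geom, params, x).values
        composed = td_min * (1.0 + K / c)
        np.testing.assert_allclose(direct, composed, rtol=1e-9)


class TestMotherCellDoublingTime:
    KIN = GrowthKinetics(td_min=23.0, td_liquid=26.0)

    def test_short_channel_limit_is_liquid_value(self):
        lam = screening_length(GEOM, ABSORB)
        geom = ChannelGeometry(0.9, 1.15, 1e-3 * lam)
        td = mother_cell_doubling_time(geom, ABSORB, self.KIN)
        assert td == pytest.approx(26.0, rel=1e-6)

    def test_length_equal_to_screening_length(self):
        lam = screening_length(GEOM, ABSORB)
        geom = ChannelGeometry(0.9, 1.15, lam)
        td = mother_cell_doubling_time(geom, ABSORB, self.KIN)
        assert td == pytest.approx(23.0 + 3.0 * math.cosh(1.0), rel=1e-12)

    def test_exponential_growth_in_long_channels(self):
        lam = screening_length(GEOM, ABSORB)
        t1 = mother_cell_doubling_time(ChannelGeometry(0.9, 1.15, 15 * lam), ABSORB, self.KIN)
        t2 = mother_cell_doubling_time(ChannelGeometry(0.9, 1.15, 30 * lam), ABSORB, self.KIN)
        assert (t2 - 23.0) / (t1 - 23.0) == pytest.approx(math.exp(15.0), rel=1e-4)

    def test_excess_log_slope_is_inverse_screening_length(self):
        lam = screening_length(GEOM, ABSORB)
        lengths = np.linspace(10 * lam, 20 * lam, 20)
        excess = [
            mother_cell_doubling_time(ChannelGeometry(0.9, 1.15, L), ABSORB, self.KIN) - 23.0
            for L in lengths
        ]
        slope = np.polyfit(lengths, np.log(excess), 1)[0]
        assert slope == pytest.approx(1.0 / lam, rel=0.01)


class TestKineticDepletion:
    UPTAKE = KineticUptakeParams(imax=2e5, mean_cell_length=2.12, diffusion=700.0, c0_mM=22.0)

    def test_reference_arithmetic(self):
        res = kinetic_depletion(GEOM, self.UPTAKE, cell_radius=0.4)
        free = 0.9 * 1.15 - math.pi * 0.4**2
        expected_molec = 50.0**2 * 2e5 / (2 * free * 2.12 * 700.0)
        assert res.delta_c_mM == pytest.approx(expected_molec / 6.02214076e5, rel=1e-9)
        assert res.delta_c_mM == pytest.approx(0.53, abs=0.01)
        assert res.valid

    def test_quadratic_in_length(self):
        d1 = kinetic_depletion(GEOM, self.UPTAKE, 0.4).delta_c_mM
        d2 = kinetic_depletion(ChannelGeometry(0.9, 1.15, 100.0), self.UPTAKE, 0.4).delta_c_mM
        assert d2 == pytest.approx(4 * d1, rel=1e-12)

    def test_short_channel_limit(self):
        tiny = kinetic_depletion(ChannelGeometry(0.9, 1.15, 1e-6), self.UPTAKE, 0.4)
        assert tiny.delta_c_mM == pytest.approx(0.0, abs=1e-12)

    def test_overdrawn_depletion_flagged(self):
        strong = KineticUptakeParams(imax=2e7, mean_cell_length=2.12, diffusion=700.0, c0_mM=22.0)
        res = kinetic_depletion(ChannelGeometry(0.9, 1.15, 200.0), strong, 0.4)
        assert not res.valid


class TestAccumulation:
    def test_sigma_for_bsa_in_study_channel(self):
        sigma = accumulation_length(GEOM, PERM)
        # exact: sqrt((ρD/J) · WH/(2H+W)) with unit conversion m → μm
        assert sigma == pytest.approx(math.sqrt(1e4 * (0.9 * 1.15) / (2 * 1.15 + 0.9)), rel=1e-12)
        assert round(sigma) == 57

    def test_quadrupled_flux_halves_sigma(self):
        fast = PermeationParams(water_flux=4 * 7e-6, diffusion=70.0)
        assert accumulation_length(GEOM, fast) == pytest.approx(
            accumulation_length(GEOM, PERM) / 2.0, rel=1e-12
        )

    def test_glucose_sigma_scales_with_sqrt_diffusion(self):
        glucose = PermeationParams(water_flux=7e-6, diffusion=700.0)
        assert accumulation_length(GEOM, glucose) == pytest.approx(
            accumulation_length(GEOM, PERM) * math.sqrt(10.0), rel=1e-12
        )

    def test_profile_entrance_and_fold(self):
        sigma = accumulation_length(GEOM, PERM)
        geom = ChannelGeometry(0.9, 1.15, sigma)
        res = accumulation_profile(geom, PERM, np.array([0.0, sigma]))
        assert res.values[0] == PERM.c0
        assert res.values[1] / res.values[0] == pytest.approx(math.exp(0.5), rel=1e-12)
        assert dead_end_fold_increase(geom, PERM) == pytest.approx(math.exp(0.5), rel=1e-12)

    def test_profile_nondecreasing(self):
        res = accumulation_profile(GEOM, PERM, np.linspace(0, 50, 101))
        assert np.all(np.diff(res.values) >= 0)


class TestUnits:
    def test_one_millimolar(self):
        assert concentration_units(1.0, "mM", "molecules/um3") == pytest.approx(6.02214076e5)

    def test_round_trip_identity(self):
        v = concentration_units(concentration_units(3.7, "mM", "molecules/um3"),
                                "molecules/um3", "mM")
        assert v == pytest.approx(3.7, rel=1e-12)

    def test_zero_maps_to_zero(self):
        assert concentration_units(0.0, "mM", "molecules/um3") == 0.0

    def test_unknown_unit_refused(self):
        with pytest.raises(ValueError, match="unknown"):
            concentration_units(1.0, "mol/L", "mM")


class TestNumericalOracle:
    def test_screening_closed_form_matches_fd(self):
        fd = solve_transport_numerically("screening", GEOM, ABSORB, 10_000)
        closed = nutrient_profile(GEOM, ABSORB, fd.x)
        np.testing.assert_allclose(fd.values, closed.values, rtol=1e-3)
        assert np.max(np.abs(fd.values / closed.values - 1)) < 1e-3

    def test_screening_zero_absorption_constant_solution(self):
        fd = solve_transport_numerically(
            "screening", GEOM, AbsorbingColonyParams(0.4, 700.0, 0.0), 500
        )
        np.testing.assert_allclose(fd.values, 1.0, rtol=1e-10)

    def test_accumulation_end_ratio_matches_closed_form(self):
        geom = ChannelGeometry(0.9, 1.15, 100.0)
        fd = solve_transport_numerically("accumulation", geom, PERM, 10_000)
        sigma = accumulation_length(geom, PERM)
        assert fd.values[-1] / fd.values[0] == pytest.approx(
            math.exp(100.0**2 / (2 * sigma**2)), rel=1e-3
        )

    @pytest.mark.parametrize("model,params,geom", [
        ("screening", ABSORB, ChannelGeometry(0.9, 1.15, 30.0)),
        ("accumulation", PERM, ChannelGeometry(0.9, 1.15, 100.0)),
    ])
    def test_second_order_convergence(self, model, params, geom):
        def max_err(n):
            fd = solve_transport_numerically(model, geom, params, n)
            if model == "screening":
                exact = nutrient_profile(geom, params, fd.x).values
            else:
                exact = accumulation_profile(geom, params, fd.x).values
            return np.max(np.abs(fd.values - exact))

        ratio = max_err(201) / max_err(401)
        assert 3.0 < ratio < 5.0  # halving h shrinks the error ≈ 4×

    def test_unknown_model_refused(self):
        with pytest.raises(ValueError, match="unknown"):
            solve_transport_numerically("advection", GEOM, ABSORB, 100)
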