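"""Buoyancy frequency, heat-budget diffusivity, thermocline flux."""

import numpy as np
import pandas as pd
import pytest

import oxilake as ox
from oxilake.core import ValidationError
from oxilake.gas_exchange import InsufficientDataError
from oxilake.mixing import DiffusivityProfile, water_density


class TestBuoyancyFrequency:
    depths = np.arange(0.0, 21.0)

    def test_isothermal_profile_is_neutral(self):
        n2 = ox.buoyancy_frequency(self.depths, np.full(21, 15.0))
        assert np.allclose(n2, 0.0)

    def test_warm_over_cold_is_stable_everywhere(self):
        temp = 22.0 - 0.5 * self.depths  # warming upward, above 4 degC
        n2 = ox.buoyancy_frequency(self.depths, temp)
        assert np.all(n2 > 0)

    def test_two_layer_profile_peaks_at_interface(self):
        temp = 6.0 + 14.0 * 0.5 * (1 - np.tanh((self.depths - 8.0) / 1.0))
        n2 = ox.buoyancy_frequency(self.depths, temp)
        peak_depth = self.depths[np.argmax(n2)]
        assert peak_depth == pytest.approx(8.0, abs=1.0)
        # oracle: N^2 at the interface from the analytic density gradient
        rho = water_density(temp)
        drho = np.gradient(rho, self.depths)
        i = int(np.argmax(n2))
        assert n2[i] == pytest.approx(9.80665 / rho[i] * drho[i], rel=1e-12)

    def test_single_depth_rejected(self):
        with pytest.raises(InsufficientDataError):
            ox.buoyancy_frequency(np.array([5.0]), np.array([10.0]))


def two_layer_series(geometry, kz, n_weeks=3, heating=0.0, mix_above=None,
                     interface=8.0, width=1.5):
    """Forward-diffusion oracle: snapshots of a diffusing two-layer profile."""
    depths = np.arange(0.0, 20.0 + 1.0)
    areas = np.interp(depths, geometry.hypsometry["depth_m"],
                      geometry.hypsometry["area_m2"])
    t0 = 6.0 + 14.0 * 0.5 * (1 - np.tanh((depths - interface) / width))
    grids = [t0]
    for _ in range(n_weeks - 1):
        grids.append(ox.simulate_diffusion(
            depths, areas, grids[-1], kz, dt_s=3600.0, total_s=7 * 86400.0,
            heating_c_per_day=heating, mix_above_m=mix_above))
    dates = pd.date_range("2016-06-20", periods=n_weeks, freq="7D")
    return ox.ProfileSeries(dates=dates, depths=depths,
                            values=np.column_stack(grids))


class TestHeatBudgetDiffusivity:
    def test_recovers_uniform_diffusivity_within_10pct(self, linear_hypsometry):
        """Oracle equivalence: forward-simulated uniform K_z = 2e-6 m2 s-1."""
        geometry = ox.derive_geometry(linear_hypsometry, 6.0)
        series = two_layer_series(geometry, 2e-6)
        profiles = ox.heat_budget_diffusivity(series, geometry)
        for prof in profiles:
            core = (prof.depths >= 6) & (prof.depths <= 12)
            recovered = prof.K_z[core]
            recovered = recovered[np.isfinite(recovered)]
            assert recovered.size >= 4
            assert np.median(recovered) == pytest.approx(2e-6, rel=0.10)

    def test_time_constant_field_gives_zero_where_defined(self, linear_hypsometry):
        geometry = ox.derive_geometry(linear_hypsometry, 6.0)
        depths = np.arange(0.0, 21.0)
        temp = 6.0 + 14.0 * 0.5 * (1 - np.tanh((depths - 8.0) / 1.5))
        series = ox.ProfileSeries(
            dates=pd.date_range("2016-06-20", periods=2, freq="7D"),
            depths=depths, values=np.column_stack([temp, temp]))
        prof = ox.heat_budget_diffusivity(series, geometry)[0]
        defined = np.isfinite(prof.K_z)
        assert defined.any()
        assert np.allclose(prof.K_z[defined], 0.0, atol=1e-15)

    def test_stratified_lake_gives_thermocline_order_1e6(self, south_geometry):
        """Order-of-magnitude check at the SML base of a summer campaign."""
        spec = ox.preset("stechlin_s", seed=0, noise_temp_c=0.0)
        bundle = ox.generate_campaign(spec)
        series = ox.ProfileSeries.from_long(bundle.temperature, "temperature")
        prof = ox.heat_budget_diffusivity(series, bundle.geometry)[0]
        window = (prof.depths >= 5) & (prof.depths <= 7)
        kz = prof.K_z[window]
        kz = kz[np.isfinite(kz)]
        assert kz.size > 0
        assert 1e-7 < np.median(kz) < 1e-5

    def test_weak_gradient_cells_flagged_undefined(self, linear_hypsometry):
        geometry = ox.derive_geometry(linear_hypsometry, 6.0)
        series = two_layer_series(geometry, 2e-6)
        prof = ox.heat_budget_diffusivity(series, geometry)[0]
        # surface mixed cells are isothermal: no heat-budget estimate there
        assert np.isnan(prof.K_z[0])

    def test_single_date_rejected(self, linear_hypsometry):
        geometry = ox.derive_geometry(linear_hypsometry, 6.0)
        depths = np.arange(0.0, 21.0)
        series = ox.ProfileSeries(
            dates=pd.DatetimeIndex(["2016-06-20"]), depths=depths,
            values=np.full((21, 1), 10.0))
        with pytest.raises(InsufficientDataError):
            ox.heat_budget_diffusivity(series, geometry)


class TestThermoclineFlux:
    depths = np.arange(0.0, 12.0)

    def kz(self, value=1e-6):
        k = np.full(self.depths.size, np.nan)
        k[3:8] = value
        return DiffusivityProfile(depths=self.depths, K_z=k)

    def test_zero_gradient_gives_zero_flux(self):
        res = ox.thermocline_flux(self.kz(), self.depths,
                                  np.full(12, 500.0), 6.0)
        assert res.flux_mmol_m2_d == 0.0

    def test_hand_converted_example(self):
        """K_z = 1e-6 m2 s-1 against +370 nmol l-1 m-1 -> 0.032 mmol m-2 d-1."""
        ch4 = 500.0 + 370.0 * np.clip(self.depths - 5.0, 0, None)
        res = ox.thermocline_flux(self.kz(1e-6), self.depths, ch4, 6.0)
        assert res.gradient_nmol_l_m == pytest.approx(370.0)
        assert res.flux_mmol_m2_d == pytest.approx(
            1e-6 * 370e-6 * 86400 * 1e3, rel=1e-12)
        assert res.flux_mmol_m2_d == pytest.approx(0.032, abs=0.0005)

    def test_concentration_decreasing_downward_gives_negative_flux(self):
        ch4 = 900.0 - 50.0 * self.depths
        res = ox.thermocline_flux(self.kz(), self.depths, ch4, 6.0)
        assert res.flux_mmol_m2_d < 0

    def test_linear_in_kz_and_gradient(self):
        ch4 = 500.0 + 100.0 * np.clip(self.depths - 5.0, 0, None)
        base = ox.thermocline_flux(self.kz(1e-6), self.depths, ch4, 6.0)
        double_k = ox.thermocline_flux(self.kz(2e-6), self.depths, ch4, 6.0)
        ch4_steep = 500.0 + 300.0 * np.clip(self.depths - 5.0, 0, None)
        triple_g = ox.thermocline_flux(self.kz(1e-6), self.depths, ch4_steep, 6.0)
        assert double_k.flux_mmol_m2_d == pytest.approx(
            2 * base.flux_mmol_m2_d, rel=1e-12)
        assert triple_g.flux_mmol_m2_d == pytest.approx(
            3 * base.flux_mmol_m2_d, rel=1e-12)

    def test_maximum_kz_in_bottom_3m_window_is_used(self):
        k = np.full(self.depths.size, np.nan)
        k[3], k[4], k[5], k[6] = 1e-6, 5e-6, 2e-6, 8e-6  # 8e-6 at 6 m
        kz = DiffusivityProfile(depths=self.depths, K_z=k)
        ch4 = 500.0 + 100.0 * np.clip(self.depths - 5.0, 0, None)
        res = ox.thermocline_flux(kz, self.depths, ch4, 6.0)
        assert res.K_z_used == pytest.approx(8e-6)

    def test_undefined_window_flags_flux(self):
        k = np.full(self.depths.size, np.nan)
        k[8:] = 1e-6  # defined only below the window
        kz = DiffusivityProfile(depths=self.depths, K_z=k)
        res = ox.thermocline_flux(kz, self.depths, np.full(12, 500.0), 6.0)
        assert not res.defined
        assert np.isnan(res.flux_mmol_m2_d)

    def test_profile_must_cover_the_gradient_stencil(self):
        with pytest.raises(ValidationError):
            ox.thermocline_flux(self.kz(), np.arange(0.0, 6.0),
                                np.full(6, 500.0), 6.0)
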