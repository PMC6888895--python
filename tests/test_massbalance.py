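"""Steady-state closure, Monte Carlo propagation, seasonal switching."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import oxilake as ox
from oxilake.core import ValidationError
from oxilake.massbalance import (BalanceConfig, SingularClosureError,
                                 residual)
from conftest import components


class TestSolvePnet:
    def test_per_volume_closure(self, stratified_cfg):
        """(90 - 36 - 5)/0.7 = 70 nmol l-1 d-1."""
        comp = components((90, 52), (36, 6), (5, 5))
        p = ox.solve_pnet(comp, None, stratified_cfg)
        assert p.value == pytest.approx(70.0, rel=1e-12)

    def test_all_zero_fluxes_give_zero_production(self, stratified_cfg):
        comp = components((0, 0), (0, 0), (0, 0))
        assert ox.solve_pnet(comp, None, stratified_cfg).value == 0.0

    def test_enclosure_areal_closure(self, enclosure_geometry, stratified_cfg):
        """Littoral-free enclosure: P = (F_S - F_z)/(0.7 * 6 m) = 101."""
        comp = components((0.43, 0.07), (0.0, 0.0), (0.007, 0.009),
                          unit="mmol m-2 d-1")
        p = ox.solve_pnet(comp, enclosure_geometry, stratified_cfg)
        assert p.value == pytest.approx(101, abs=1)

    def test_alpha_one_is_singular(self):
        with pytest.raises(SingularClosureError):
            BalanceConfig(alpha=1.0)

    def test_ignoring_oxidation_shifts_pnet_toward_zero(self, stratified_cfg):
        """With positive net emission, alpha = 0 lowers the inferred rate."""
        comp = components((90, 0), (36, 0), (5, 0))
        with_ox = ox.solve_pnet(comp, None, stratified_cfg)
        without = ox.solve_pnet(comp, None, BalanceConfig(alpha=0.0))
        assert without.value < with_ox.value
        assert np.sign(with_ox.value - without.value) == np.sign(90 - 36 - 5)

    @settings(max_examples=200, deadline=None)
    @given(f_s=st.floats(-200, 400), f_l=st.floats(0, 200),
           f_z=st.floats(-50, 100), alpha=st.floats(0, 0.9),
           scope=st.sampled_from(["internal_only", "internal_plus_lateral"]))
    def test_back_substitution_residual_vanishes(self, f_s, f_l, f_z, alpha,
                                                 scope):
        cfg = BalanceConfig(alpha=alpha, mox_scope=scope)
        comp = components((f_s, 0), (f_l, 0), (f_z, 0))
        p = ox.solve_pnet(comp, None, cfg).value
        scale = max(abs(f_s), abs(f_l), abs(f_z), abs(p), 1.0)
        assert abs(residual(p, f_s, f_l, f_z, cfg)) <= 1e-10 * scale


class TestSolveLateral:
    def test_enclosure_comparison_volumetric(self, south_geometry):
        """Open water (0.77, 0.024) minus enclosure production 101 -> ~76."""
        cfg = BalanceConfig(mox_scope="internal_plus_lateral")
        res = ox.solve_lateral(0.77, 0.024, 100.714, south_geometry, cfg)
        assert res.volumetric_nmol_l_d == pytest.approx(76, abs=2)

    def test_volumetric_to_areal_littoral_flux(self, south_geometry):
        """76 nmol l-1 d-1 over V = 5.7e6 m^3, A_sed = 0.31 km^2 -> 1.4."""
        cfg = BalanceConfig(mox_scope="internal_plus_lateral")
        res = ox.solve_lateral(0.77, 0.024, 100.714, south_geometry, cfg)
        assert res.areal_mmol_m2_d == pytest.approx(1.4, abs=0.05)

    def test_identical_systems_have_zero_lateral_input(self, south_geometry):
        cfg = BalanceConfig(mox_scope="internal_plus_lateral")
        p_enc = (0.43 - 0.007) / (0.7 * 6.0) * 1e3
        res = ox.solve_lateral(0.43, 0.007, p_enc, south_geometry, cfg)
        assert res.volumetric_nmol_l_d == pytest.approx(0.0, abs=1e-9)
        assert not res.negative_flag

    def test_negative_lateral_is_flagged_not_raised(self, south_geometry):
        cfg = BalanceConfig(mox_scope="internal_plus_lateral")
        with pytest.warns(UserWarning, match="negative"):
            res = ox.solve_lateral(0.1, 0.05, 200.0, south_geometry, cfg)
        assert res.negative_flag
        assert res.volumetric_nmol_l_d < 0


class TestMonteCarlo:
    ne = ((90, 52), (36, 6), (5, 5))

    def test_zero_sd_collapses_to_deterministic(self, stratified_cfg):
        comp = components((90, 0), (36, 0), (5, 0))
        mc = ox.monte_carlo_pnet(comp, None, stratified_cfg, n=999, seed=3)
        assert mc.sd == 0.0
        assert mc.mean == pytest.approx(70.0, rel=1e-12)

    def test_mean_and_sd_match_gaussian_closed_form(self, stratified_cfg):
        """Linear combination of normals: analytic mean and SD, 3% at n=9999."""
        comp = components(*self.ne)
        mc = ox.monte_carlo_pnet(comp, None, stratified_cfg, seed=11)
        analytic_mean = (90 - 36 - 5) / 0.7
        analytic_sd = np.sqrt(52**2 + 6**2 + 5**2) / 0.7
        assert mc.mean == pytest.approx(analytic_mean,
                                        abs=3 * analytic_sd / np.sqrt(9999))
        assert mc.sd == pytest.approx(analytic_sd, rel=0.03)

    def test_law_of_large_numbers_at_large_n(self, stratified_cfg):
        comp = components(*self.ne)
        analytic_mean = (90 - 36 - 5) / 0.7
        analytic_sd = np.sqrt(52**2 + 6**2 + 5**2) / 0.7
        for n in (9999, 10**6):
            mc = ox.monte_carlo_pnet(comp, None, stratified_cfg, n=n, seed=5)
            assert abs(mc.mean - analytic_mean) <= 3 * analytic_sd / np.sqrt(n)

    def test_p_positive_matches_gaussian_cdf(self, stratified_cfg):
        comp = components(*self.ne)
        mc = ox.monte_carlo_pnet(comp, None, stratified_cfg, seed=17)
        analytic_mean = (90 - 36 - 5) / 0.7
        analytic_sd = np.sqrt(52**2 + 6**2 + 5**2) / 0.7
        expected = norm.cdf(analytic_mean / analytic_sd)
        assert mc.p_positive == pytest.approx(expected, abs=0.015)

    def test_fixed_seed_is_bit_reproducible(self, stratified_cfg):
        comp = components(*self.ne)
        a = ox.monte_carlo_pnet(comp, None, stratified_cfg, seed=23)
        b = ox.monte_carlo_pnet(comp, None, stratified_cfg, seed=23)
        assert a.mean == b.mean and a.sd == b.sd
        assert a.quantiles == b.quantiles

    def test_negative_draws_are_retained(self, stratified_cfg):
        comp = components(*self.ne)
        mc = ox.monte_carlo_pnet(comp, None, stratified_cfg, seed=29,
                                 keep_draws=True)
        assert (mc.draws < 0).any()
        assert 0.0 < mc.p_positive < 1.0

    def test_whole_system_track(self, stratified_cfg):
        comp = components((2503, 1160), (1198, 185), (139, 170),
                          unit="mol d-1")
        mc = ox.monte_carlo_whole_system(comp, stratified_cfg, seed=31)
        assert mc.unit == "mol d-1"
        assert mc.mean == pytest.approx((2503 - 1198 - 139) / 0.7, rel=0.03)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValidationError):
            components((90, -1), (36, 6), (5, 5))


class TestSeasonalConfig:
    onset = dt.date(2016, 5, 1)
    full = dt.date(2016, 6, 1)

    def test_winter_date_is_non_stratified(self):
        cfg = ox.seasonal_config(dt.date(2016, 3, 15), self.onset, self.full)
        assert cfg.season == "non_stratified"
        assert cfg.alpha == 0.0

    def test_summer_date_is_stratified(self):
        cfg = ox.seasonal_config(dt.date(2016, 6, 20), self.onset, self.full)
        assert cfg.season == "stratified"
        assert cfg.alpha == pytest.approx(0.3)

    @pytest.mark.parametrize("day,season", [(10, "non_stratified"),
                                            (20, "stratified")])
    def test_transition_month_splits_at_mid_month(self, day, season):
        cfg = ox.seasonal_config(dt.date(2016, 5, day), self.onset, self.full)
        assert cfg.season == season

    def test_non_stratified_forces_zero_lateral_in_monte_carlo(self):
        comp = components((50, 10), (30, 5), (2, 1))
        cfg = BalanceConfig(season="non_stratified", alpha=0.0)
        mc = ox.monte_carlo_pnet(comp, None, cfg, n=4999, seed=37)
        # lateral input forced to zero: mean approaches (50 - 2)/1
        assert mc.mean == pytest.approx(48.0, abs=0.6)
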