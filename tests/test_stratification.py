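"""Water density, buoyancy frequency, oxygen saturation, hysteresis loop."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from oxanox.stratification import (
    GRAVITY,
    N2_FLOOR,
    DepthProfile,
    ProfileSeries,
    buoyancy_frequency_squared,
    hysteresis_loop,
    mixing_proxy,
    oxygen_saturation,
    oxygen_saturation_concentration,
    stratification_records,
    water_density,
)


def _profile(depths, temps, oxygen=None, ts="2013-06-15"):
    depths = np.asarray(depths, dtype=float)
    return DepthProfile(
        timestamp=pd.Timestamp(ts),
        depths=depths,
        temperature=np.asarray(temps, dtype=float),
        oxygen=np.full_like(depths, 300.0) if oxygen is None else np.asarray(oxygen, float),
    )


class TestWaterDensity:
    def test_density_maximum_near_3_98(self):
        res = minimize_scalar(lambda t: -water_density(t), bounds=(0.0, 10.0),
                              method="bounded")
        assert abs(res.x - 3.98) < 0.01

    def test_warm_water_is_lighter(self):
        assert water_density(4.0) > water_density(25.0)

    def test_monotone_decreasing_10_to_30(self):
        t = np.linspace(10.0, 30.0, 200)
        assert np.all(np.diff(water_density(t)) < 0)

    def test_out_of_window_warns_but_returns(self):
        with pytest.warns(UserWarning, match="validity"):
            v = water_density(45.0)
        assert np.isfinite(v)


class TestBuoyancyFrequency:
    def test_isothermal_profile_is_unstratified(self):
        p = _profile(range(11), [12.0] * 11)
        n2, _ = buoyancy_frequency_squared(p)
        assert n2 == pytest.approx(0.0, abs=1e-12)

    def test_linear_density_profile_matches_closed_form(self):
        """Temperatures chosen so that rho(z) is linear: N^2 must equal
        (g/rho) * slope at the thermocline depth."""
        z = np.linspace(0.0, 10.0, 21)
        slope = 0.1  # kg/m^3 per m
        rho_target = 997.0 + slope * z  # within the warm branch of rho(T)
        # invert the density polynomial on the warm branch for each depth:
        # density increases downward, so temperature decreases downward
        temps = []
        for r in rho_target:
            res = minimize_scalar(
                lambda t: (water_density(t) - r) ** 2, bounds=(4.0, 35.0),
                method="bounded",
            )
            temps.append(res.x)
        temps = np.array(temps)
        rho = water_density(temps)
        p = _profile(z, temps)
        n2, z_t = buoyancy_frequency_squared(p)
        i = int(np.argmin(np.abs(z - z_t)))
        expected = GRAVITY / rho[i] * slope
        assert n2 == pytest.approx(expected, rel=0.05)

    def test_two_layer_thermocline_at_interface(self):
        z = np.arange(11.0)
        temps = np.where(z < 5.0, 20.0, 8.0)
        # sharpen: interface between 4 and 5 m
        p = _profile(z, temps)
        n2, z_t = buoyancy_frequency_squared(p)
        assert n2 > 0
        assert 4.0 <= z_t <= 5.0

    def test_density_inversion_reported_negative(self):
        p = _profile([0.0, 5.0, 10.0], [8.0, 12.0, 20.0])  # cold over warm
        n2, _ = buoyancy_frequency_squared(p)
        assert n2 < 0

    def test_single_depth_rejected(self):
        with pytest.raises(ValueError):
            buoyancy_frequency_squared(_profile([5.0], [12.0]))

    def test_matches_one_sided_difference_implementation(self):
        """Independent check: N^2 from forward/backward one-sided
        differences brackets the centered-difference value within the
        discretization error of the profile."""
        z = np.arange(11.0)
        temps = 7.0 + 13.0 / (1.0 + np.exp((z - 5.0) / 0.8))
        p = _profile(z, temps)
        n2, z_t = buoyancy_frequency_squared(p)
        rho = water_density(temps)
        i = int(np.where(z == z_t)[0][0])
        fwd = GRAVITY / rho[i] * (rho[i + 1] - rho[i]) / (z[i + 1] - z[i])
        bwd = GRAVITY / rho[i] * (rho[i] - rho[i - 1]) / (z[i] - z[i - 1])
        assert min(fwd, bwd) <= n2 <= max(fwd, bwd)


class TestMixingProxy:
    def test_reciprocal(self):
        v, capped = mixing_proxy(1e-4)
        assert v == pytest.approx(1e4) and not capped

    def test_floor_applies_and_flags(self):
        v, capped = mixing_proxy(0.0)
        assert v == pytest.approx(1.0 / N2_FLOOR) and capped

    def test_monotone_decreasing_above_floor(self):
        n2 = np.logspace(-5.9, -2, 50)
        vals = [mixing_proxy(v)[0] for v in n2]
        assert np.all(np.diff(vals) < 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mixing_proxy(-1e-5)


class TestOxygenSaturation:
    def test_zero_oxygen(self):
        assert oxygen_saturation(12.0, 0.0) == 0.0

    def test_equilibrium_is_100(self):
        for t in (2.0, 12.0, 25.0):
            assert oxygen_saturation(t, oxygen_saturation_concentration(t)) == (
                pytest.approx(100.0)
            )

    def test_solubility_decreases_with_temperature(self):
        t = np.linspace(0.0, 30.0, 100)
        assert np.all(np.diff(oxygen_saturation_concentration(t)) < 0)

    def test_plausible_magnitude(self):
        # air-saturated water near 10 C holds roughly 350 uM oxygen
        assert 300.0 < oxygen_saturation_concentration(10.0) < 400.0


class TestHysteresisLoop:
    @staticmethod
    def _series_from_path(temps_by_date):
        profiles = []
        for i, t_epi in enumerate(temps_by_date):
            z = np.arange(11.0)
            temps = 7.0 + max(t_epi - 7.0, 0.0) / (1.0 + np.exp((z - 5.0) / 0.6))
            o2 = 0.9 * oxygen_saturation_concentration(temps)
            profiles.append(
                DepthProfile(
                    timestamp=pd.Timestamp("2013-01-01") + pd.Timedelta(days=14 * i),
                    depths=z,
                    temperature=temps,
                    oxygen=o2,
                )
            )
        return ProfileSeries(profiles)

    def test_exact_retrace_has_zero_area(self):
        """A path that walks out along a curve and back through the very
        same points encloses exactly zero area."""
        temps = [8.0, 12.0, 16.0, 20.0, 16.0, 12.0, 8.0]
        loop = hysteresis_loop(self._series_from_path(temps), depth=7.0)
        assert loop.area == pytest.approx(0.0, abs=1e-9)

    def test_requires_four_points(self):
        with pytest.raises(ValueError):
            hysteresis_loop(self._series_from_path([8.0, 12.0, 16.0]), depth=7.0)

    def test_missing_depth_uses_nearest_with_warning(self):
        series = self._series_from_path([8.0, 12.0, 16.0, 12.0, 8.0])
        with pytest.warns(UserWarning, match="nearest"):
            loop = hysteresis_loop(series, depth=13.0)
        assert len(loop.inv_N2) == 5

    def test_planted_loop_recovered(self):
        """The synthetic anoxic-turnover series encloses a loop of the
        planted orientation (breakdown limb oxygen-poor => positive area);
        the oxic-turnover series retraces (area near zero)."""
        from oxanox.synthetic import SyntheticLakeConfig, generate_profile_series

        anox = generate_profile_series(
            SyntheticLakeConfig(turnover="anoxic", temp_noise=0.0, o2_noise_frac=0.0)
        )
        oxic = generate_profile_series(
            SyntheticLakeConfig(turnover="oxic", temp_noise=0.0, o2_noise_frac=0.0)
        )
        a_loop = hysteresis_loop(anox, depth=7.0)
        o_loop = hysteresis_loop(oxic, depth=7.0)
        assert a_loop.area > 0.0
        assert abs(o_loop.area) < 0.05 * a_loop.area
        assert a_loop.phase_separation > 10.0

    def test_loop_robust_to_hypolimnion_depth(self):
        """The planted loop signature survives moving the sampling depth
        within the hypolimnion."""
        from oxanox.synthetic import SyntheticLakeConfig, generate_profile_series

        series = generate_profile_series(
            SyntheticLakeConfig(turnover="anoxic", temp_noise=0.0, o2_noise_frac=0.0)
        )
        areas = [hysteresis_loop(series, depth=d).area for d in (7.0, 8.0, 9.0)]
        assert all(a > 0.0 for a in areas)
        assert max(areas) / min(areas) < 2.0


class TestRecordsAndIO:
    def test_records_one_per_profile(self):
        from oxanox.synthetic import SyntheticLakeConfig, generate_profile_series

        series = generate_profile_series(SyntheticLakeConfig())
        recs = stratification_records(series, o2_depth=7.0)
        assert len(recs) == len(series)
        mixed = [r for r in recs if r.proxy_capped or r.unstable_gradient]
        stratified = [r for r in recs if not (r.proxy_capped or r.unstable_gradient)]
        assert mixed and stratified
        assert max(r.N2 for r in stratified) > 1e-4

    def test_series_csv_round_trip(self, tmp_path):
        from oxanox.synthetic import SyntheticLakeConfig, generate_profile_series

        series = generate_profile_series(SyntheticLakeConfig(n_dates=6))
        path = tmp_path / "profiles.csv"
        series.to_csv(path)
        back = ProfileSeries.from_csv(path)
        assert len(back) == len(series)
        for a, b in zip(series, back):
            assert a.timestamp == b.timestamp
            np.testing.assert_allclose(a.temperature, b.temperature, rtol=1e-12)
            np.testing.assert_allclose(a.oxygen, b.oxygen, rtol=1e-12)

    def test_timestamps_must_increase(self):
        p = _profile(range(3), [10, 10, 10])
        with pytest.raises(ValueError):
            ProfileSeries([p, p])
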