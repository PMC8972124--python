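import numpy as np
import pandas as pd
import pytest

from vineflux import rowgeom
from vineflux.core import CanopyGeometry
from vineflux.exceptions import ConfigurationError
from vineflux.radiation import (
    canopy_net_radiation,
    diffuse_fraction,
    direct_interception,
    diffuse_interception,
    longwave_net,
    soil_reflected_interception,
    solar_position,
    stefan_boltzmann_flux,
)

from ._oracles import mc_ground_to_canopy, mc_sky_interception, mc_wall_view_factors


class TestSolarPosition:
    def test_equinox_noon_elevation(self):
        # elevation ~ 90 - |lat| with declination ~ 0 at the equinox
        pos = solar_position(pd.Timestamp("2020-03-20 12:00"), 44.78, 0.0, 0.0)
        assert pos.elevation == pytest.approx(90.0 - 44.78, abs=0.6)
        assert pos.azimuth == pytest.approx(180.0, abs=5.0)

    def test_june_solstice_declination_near_obliquity(self):
        pos = solar_position(pd.Timestamp("2020-06-21 12:00"), 44.78, 0.0, 0.0)
        assert pos.declination == pytest.approx(23.44, abs=0.1)

    def test_midnight_sun_below_horizon(self):
        pos = solar_position(pd.Timestamp("2020-07-15 00:00"), 44.78, 0.0, 0.0)
        assert pos.elevation < 0
        assert pos.extraterrestrial_horizontal == 0.0

    def test_vectorized_matches_scalar(self):
        times = pd.date_range("2020-07-01", periods=8, freq="3h")
        vec = solar_position(times, 44.78, -0.58, 0.0)
        one = solar_position(times[3], 44.78, -0.58, 0.0)
        assert vec.elevation[3] == pytest.approx(one.elevation, rel=1e-12)


class TestDiffuseFraction:
    def _pos(self, extra=1000.0, elev=45.0):
        from vineflux.radiation import SolarPosition

        return SolarPosition(elev, 180.0, 20.0, 0.0, extra)

    def test_overcast_limit_fully_diffuse(self):
        pos = self._pos()
        assert diffuse_fraction(0.22 * 1000.0, pos) == 1.0

    def test_no_flux_fully_diffuse_by_convention(self):
        assert diffuse_fraction(0.0, self._pos()) == 1.0

    def test_intermediate_clearness(self):
        # 1 - 6.4 (0.30 - 0.22)^2
        assert diffuse_fraction(300.0, self._pos()) == pytest.approx(0.95904, rel=1e-6)

    def test_clear_sky_floor_applies(self):
        pos = self._pos(elev=60.0)
        sin_b = np.sin(np.deg2rad(60.0))
        floor = 0.847 - 1.61 * sin_b + 1.04 * sin_b**2
        assert diffuse_fraction(800.0, pos) == pytest.approx(floor, rel=1e-9)

    def test_sun_down_with_flux_treated_diffuse(self):
        pos = self._pos(extra=0.0, elev=-5.0)
        assert diffuse_fraction(30.0, pos) == 1.0


class TestDirectInterception:
    def test_sun_below_horizon_intercepts_nothing(self, geometry):
        from vineflux.radiation import SolarPosition

        pos = SolarPosition(-3.0, 90.0, 20.0, 0.0, 0.0)
        assert direct_interception(0.0, pos, geometry, 0.3) == 0.0

    def test_fully_porous_canopy_intercepts_nothing(self, geometry):
        from vineflux.radiation import SolarPosition

        pos = SolarPosition(45.0, 90.0, 20.0, 0.0, 1000.0)
        assert direct_interception(500.0, pos, geometry, 1.0) == 0.0

    def test_worked_shadow_example(self, geometry):
        # beta 45 deg, sun perpendicular to N-S rows, shadow (0.4 + 1.0)/1.8
        from vineflux.radiation import SolarPosition

        pos = SolarPosition(45.0, 90.0, 20.0, 0.0, 1000.0)
        absorbed = direct_interception(500.0, pos, geometry, 0.2, leaf_albedo=0.2)
        assert absorbed == pytest.approx(500.0 * (1.4 / 1.8) * 0.8 * 0.8, rel=1e-9)

    def test_mutual_shading_caps_fraction(self, geometry):
        frac = rowgeom.beam_shadow_fraction(
            2.0, 90.0, row_spacing=geometry.row_spacing,
            canopy_width=geometry.canopy_width,
            wall_height=geometry.wall_height, row_azimuth=0.0,
        )
        assert frac == 1.0


class TestGeometricFractionsAgainstMonteCarlo:
    """Deterministic quadrature fractions vs seeded ray-tracing oracle."""

    def test_sky_interception_fraction(self, geometry):
        impl = rowgeom.sky_interception_fraction(geometry)
        mc = mc_sky_interception(geometry, n_rays=200_000, seed=42)
        assert impl == pytest.approx(mc, rel=0.02)

    def test_ground_to_canopy_fraction(self, geometry):
        impl = rowgeom.ground_to_canopy_fraction(geometry)
        mc = mc_ground_to_canopy(geometry, n_rays=200_000, seed=43)
        assert impl == pytest.approx(mc, rel=0.02)

    def test_wall_view_factors(self, geometry):
        impl = rowgeom.face_view_factors(geometry)["wall"]
        mc = mc_wall_view_factors(geometry, n_rays=200_000, seed=44)
        for key in ("sky", "ground", "adjacent"):
            assert impl[key] == pytest.approx(mc[key], abs=0.02)

    def test_tall_narrow_gap_limit(self):
        # nearly touching, very tall solid walls intercept almost all sky flux
        g = CanopyGeometry(row_spacing=1.0, canopy_width=0.98,
                           canopy_top_h=50.0, canopy_bottom_h=0.0)
        assert rowgeom.sky_interception_fraction(g) > 0.97


class TestViewFactorClosure:
    def test_each_face_closes_to_one(self, geometry):
        vf = rowgeom.face_view_factors(geometry)
        for face in ("wall", "top"):
            total = sum(vf[face].values())
            assert total == pytest.approx(1.0, abs=1e-9)


class TestInterceptionProperties:
    def test_linear_in_incident_flux(self, geometry):
        from vineflux.radiation import SolarPosition

        pos = SolarPosition(35.0, 120.0, 20.0, 0.0, 1000.0)
        a1 = direct_interception(100.0, pos, geometry, 0.3)
        a2 = direct_interception(250.0, pos, geometry, 0.3)
        assert a2 == pytest.approx(2.5 * a1, rel=1e-12)
        d1 = diffuse_interception(100.0, geometry, 0.3)
        d2 = diffuse_interception(400.0, geometry, 0.3)
        assert d2 == pytest.approx(4.0 * d1, rel=1e-12)

    def test_decreasing_in_porosity(self, geometry):
        porosities = np.linspace(0.0, 1.0, 11)
        vals = [diffuse_interception(300.0, geometry, p) for p in porosities]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] == 0.0

    def test_zero_soil_albedo_or_full_leaf_albedo(self, geometry):
        assert soil_reflected_interception(400.0, 0.0, geometry, 0.3) == 0.0
        assert soil_reflected_interception(400.0, 0.18, geometry, 0.3, leaf_albedo=1.0) == 0.0


class TestStefanBoltzmann:
    def test_blackbody_at_20C(self):
        assert stefan_boltzmann_flux(20.0, 1.0) == pytest.approx(418.7, rel=1e-3)

    def test_grass_emissivity(self):
        assert stefan_boltzmann_flux(20.0, 0.98) == pytest.approx(0.98 * 418.73, rel=1e-3)

    def test_zero_emissivity(self):
        assert stefan_boltzmann_flux(20.0, 0.0) == 0.0


class TestLongwaveNet:
    def test_isothermal_blackbody_enclosure_is_in_equilibrium(self, geometry, constants):
        t = 20.0
        lw_sky = stefan_boltzmann_flux(t, 1.0)
        net = longwave_net(lw_sky, t, t, geometry, porosity=0.0,
                           emissivity_canopy=1.0, emissivity_ground=1.0)
        assert net == pytest.approx(0.0, abs=1e-9)

    def test_warm_canopy_is_net_emitter(self, geometry):
        lw_sky = stefan_boltzmann_flux(5.0, 1.0)
        net = longwave_net(lw_sky, 10.0, 35.0, geometry, porosity=0.2)
        assert net < 0

    def test_missing_inputs_raise_configuration_error(self, geometry):
        with pytest.raises(ConfigurationError):
            longwave_net(None, 10.0, 20.0, geometry, porosity=0.2)


class TestCanopyNetRadiation:
    def _met(self, sw, t=25.0, rh=50.0):
        times = pd.date_range("2020-07-15 00:15", periods=len(sw), freq="15min")
        return pd.DataFrame(
            {"t_canopy_C": t, "rh_pct": rh, "sw_global_Wm2": sw}, index=times
        )

    def test_night_record_is_zero_without_longwave(self, geometry):
        rad = canopy_net_radiation(self._met([0.0, 0.0]), geometry, 0.3)
        assert (rad["r_c"] == 0.0).all()

    def test_absorbed_shortwave_never_exceeds_incident(self, geometry):
        times = pd.date_range("2020-07-15 00:15", periods=96, freq="15min")
        pos_sw = 900.0 * np.maximum(
            0.0, np.sin(np.pi * (np.arange(96) - 24) / 48.0)
        )
        met = pd.DataFrame(
            {"t_canopy_C": 25.0, "rh_pct": 50.0, "sw_global_Wm2": pos_sw},
            index=times,
        )
        rad = canopy_net_radiation(met, geometry, 0.25)
        sw_abs = rad["sw_direct_abs"] + rad["sw_diffuse_abs"]
        assert (sw_abs <= met["sw_global_Wm2"] + 1e-9).all()
        assert (rad[["sw_direct_abs", "sw_diffuse_abs", "sw_soil_reflected_abs"]] >= 0).all().all()

    def test_components_sum_to_r_c(self, geometry):
        met = self._met([400.0, 600.0])
        rad = canopy_net_radiation(met, geometry, 0.3)
        total = (
            rad["sw_direct_abs"] + rad["sw_diffuse_abs"]
            + rad["sw_soil_reflected_abs"] + rad["lw_net_abs"]
        )
        assert np.allclose(total, rad["r_c"], rtol=1e-12)

    def test_longwave_requires_columns(self, geometry):
        with pytest.raises(ConfigurationError):
            canopy_net_radiation(self._met([100.0]), geometry, 0.3, include_longwave=True)
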