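"""Net radiation absorbed by the vine canopy per unit ground area (R_c).

The shortwave budget sums three absorbed components: direct beam, diffuse
sky, and soil-reflected radiation, each intercepted geometrically by the
open hedgerow and reduced by canopy porosity (gap fraction) and leaf
albedo.  An optional long-wave view-factor budget can be added, but the
default R_c is shortwave-only: under the radiation filter used downstream
the long-wave term is small and requires two extra instruments (sky
pyrgeometer, ground infrared thermometer), so final conductance
calculations disregard it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import rowgeom
from .core import CanopyGeometry, PhysicalConstants
from .exceptions import ConfigurationError, InvalidInputError

SOLAR_CONSTANT = 1367.0  # W m^-2
DEFAULT_LEAF_ALBEDO = 0.20
DEFAULT_SOIL_ALBEDO = 0.18
DEFAULT_EMISSIVITY = 0.98


@dataclass
class SolarPosition:
    """Sun angles and extraterrestrial irradiance for one or more instants.

    ``elevation`` is degrees above the horizon, ``azimuth`` degrees
    clockwise from north (180 at solar noon in the northern hemisphere).
    ``extraterrestrial_horizontal`` is the top-of-atmosphere flux on a
    horizontal plane, zero whenever the sun is at or below the horizon.
    """

    elevation: np.ndarray | float
    azimuth: np.ndarray | float
    declination: np.ndarray | float
    hour_angle: np.ndarray | float
    extraterrestrial_horizontal: np.ndarray | float


def solar_position(timestamps, latitude: float, longitude: float,
                   tz_offset: float = 0.0) -> SolarPosition:
    """Solar elevation, azimuth, declination and hour angle from clock time.

    Standard astronomical relations: Spencer Fourier series for declination
    and the equation of time, longitude correction from the time-zone
    meridian, and the spherical elevation/azimuth formulas.  Accepts a
    single timestamp or a DatetimeIndex (interval-ending local clock time).

    Not valid poleward of the polar circles (no polar day/night handling).
    """
    if abs(latitude) >= 66.5:
        raise InvalidInputError("latitude must lie equatorward of the polar circles")
    scalar = not hasattr(timestamps, "__len__")
    times = pd.DatetimeIndex([timestamps] if scalar else timestamps)
    doy = times.dayofyear.to_numpy(dtype=float)
    clock_hour = (
        times.hour.to_numpy(dtype=float)
        + times.minute.to_numpy(dtype=float) / 60.0
        + times.second.to_numpy(dtype=float) / 3600.0
    )
    gamma = 2.0 * np.pi * (doy - 1.0 + (clock_hour - 12.0) / 24.0) / 365.0
    decl = (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )
    eot_min = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )
    solar_hour = clock_hour + (4.0 * (longitude - 15.0 * tz_offset) + eot_min) / 60.0
    omega = np.deg2rad(15.0 * (solar_hour - 12.0))
    lat = np.deg2rad(latitude)
    sin_beta = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(omega)
    beta = np.arcsin(np.clip(sin_beta, -1.0, 1.0))
    azimuth = np.rad2deg(
        np.arctan2(np.sin(omega), np.cos(omega) * np.sin(lat) - np.tan(decl) * np.cos(lat))
    ) + 180.0
    ecc = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    extra = np.where(sin_beta > 0, SOLAR_CONSTANT * ecc * sin_beta, 0.0)
    if scalar:
        return SolarPosition(
            float(np.rad2deg(beta)[0]), float(azimuth[0]), float(np.rad2deg(decl)[0]),
            float(np.rad2deg(omega)[0]), float(extra[0]),
        )
    return SolarPosition(
        np.rad2deg(beta), azimuth, np.rad2deg(decl), np.rad2deg(omega), extra
    )


def diffuse_fraction(sw_global, pos: SolarPosition):
    """Diffuse fraction of measured global shortwave from the clearness index.

    Piecewise hourly partition: fully diffuse for clearness index
    k_t <= 0.22; 1 - 6.4 (k_t - 0.22)^2 up to k_t = 0.35; then the linear
    branch 1.47 - 1.66 k_t, floored at the elevation-dependent clear-sky
    limit R = 0.847 - 1.61 sin(beta) + 1.04 sin^2(beta).  When the sun is
    down (or extraterrestrial flux is zero) any measured flux is treated as
    fully diffuse.
    """
    sw = np.asarray(sw_global, dtype=float)
    if np.any(sw < 0):
        raise InvalidInputError("global shortwave must be non-negative")
    extra = np.asarray(pos.extraterrestrial_horizontal, dtype=float)
    sin_beta = np.sin(np.deg2rad(np.asarray(pos.elevation, dtype=float)))
    with np.errstate(divide="ignore", invalid="ignore"):
        kt = np.where(extra > 0, sw / extra, 0.0)
    fd = np.ones_like(kt)
    mid = (kt > 0.22) & (kt <= 0.35)
    fd = np.where(mid, 1.0 - 6.4 * (kt - 0.22) ** 2, fd)
    high = kt > 0.35
    floor = 0.847 - 1.61 * sin_beta + 1.04 * sin_beta**2
    fd = np.where(high, np.maximum(1.47 - 1.66 * kt, floor), fd)
    fd = np.where(extra <= 0, 1.0, np.clip(fd, 0.0, 1.0))
    scalar = np.isscalar(sw_global)
    return float(fd) if scalar else fd


def direct_interception(beam_horizontal, pos: SolarPosition,
                        geometry: CanopyGeometry, porosity,
                        leaf_albedo: float = DEFAULT_LEAF_ALBEDO):
    """Direct beam absorbed by the canopy, W per m^2 of ground.

    Beam flux on the horizontal times the shaded ground fraction, with the
    transmitted gap fraction (porosity) and the leaf-reflected fraction
    removed.
    """
    beam = np.asarray(beam_horizontal, dtype=float)
    frac = rowgeom.beam_shadow_fraction(
        pos.elevation, pos.azimuth,
        row_spacing=geometry.row_spacing, canopy_width=geometry.canopy_width,
        wall_height=geometry.wall_height, row_azimuth=geometry.row_azimuth,
    )
    out = beam * np.asarray(frac) * (1.0 - np.asarray(porosity)) * (1.0 - leaf_albedo)
    out = np.where(np.asarray(pos.elevation) > 0, out, 0.0)
    return float(out) if out.ndim == 0 else out


def diffuse_interception(diffuse_horizontal, geometry: CanopyGeometry, porosity,
                         leaf_albedo: float = DEFAULT_LEAF_ALBEDO):
    """Diffuse sky radiation absorbed by the canopy, W per m^2 of ground."""
    d = np.asarray(diffuse_horizontal, dtype=float)
    if np.any(d < 0):
        raise InvalidInputError("diffuse flux must be non-negative")
    f_diff = rowgeom.sky_interception_fraction(geometry)
    out = d * f_diff * (1.0 - np.asarray(porosity)) * (1.0 - leaf_albedo)
    return float(out) if out.ndim == 0 else out


def soil_reflected_interception(sw_to_ground, soil_albedo, geometry: CanopyGeometry,
                                porosity, leaf_albedo: float = DEFAULT_LEAF_ALBEDO):
    """Soil-reflected shortwave absorbed by the canopy, W per m^2 of ground.

    Shortwave reaching the ground, reflected with the soil albedo, with the
    ground-to-canopy fraction from the row geometry and the same porosity
    and leaf-albedo reductions as the downward streams.
    """
    sw = np.asarray(sw_to_ground, dtype=float)
    if np.any(sw < 0) or not 0 <= soil_albedo <= 1 or not 0 <= leaf_albedo <= 1:
        raise InvalidInputError("fluxes must be >= 0 and albedos in [0, 1]")
    f_up = rowgeom.ground_to_canopy_fraction(geometry)
    out = sw * soil_albedo * f_up * (1.0 - np.asarray(porosity)) * (1.0 - leaf_albedo)
    return float(out) if out.ndim == 0 else out


def stefan_boltzmann_flux(t_c, emissivity: float = DEFAULT_EMISSIVITY,
                          constants: PhysicalConstants | None = None):
    """Grey-body emitted flux epsilon * sigma * T^4, W m^-2 (T in degC)."""
    constants = constants or PhysicalConstants()
    t = np.asarray(t_c, dtype=float)
    if np.any(t <= -273.15):
        raise InvalidInputError("temperature must exceed absolute zero")
    if not 0 <= emissivity <= 1:
        raise InvalidInputError("emissivity must lie in [0, 1]")
    out = emissivity * constants.sigma_sb * (t + 273.15) ** 4
    return float(out) if np.isscalar(t_c) else out


def longwave_net(lw_sky, t_ground, t_canopy, geometry: CanopyGeometry, porosity,
                 emissivity_canopy: float = DEFAULT_EMISSIVITY,
                 emissivity_ground: float = DEFAULT_EMISSIVITY,
                 constants: PhysicalConstants | None = None):
    """Net long-wave absorbed by the canopy, W per m^2 of ground (may be < 0).

    Each canopy face (two vertical walls and the top) receives sky, ground
    and adjacent-row radiation weighted by its view factors, absorbs it with
    the silhouette interception (1 - porosity) and the canopy emissivity,
    and emits epsilon_c sigma T_c^4 from the same effective area.  Face
    areas are converted to per-unit-ground-area via the row spacing.
    Adjacent rows are assumed to radiate at the measured in-canopy
    temperature.
    """
    constants = constants or PhysicalConstants()
    if lw_sky is None or t_ground is None:
        raise ConfigurationError("long-wave budget requires lw_sky and t_ground")
    lw_sky = np.asarray(lw_sky, dtype=float)
    vf = rowgeom.face_view_factors(geometry)
    e_ground = stefan_boltzmann_flux(t_ground, emissivity_ground, constants)
    e_canopy = stefan_boltzmann_flux(t_canopy, emissivity_canopy, constants)
    p = np.asarray(porosity, dtype=float)
    s = geometry.row_spacing
    areas = {"wall": 2.0 * geometry.wall_height / s, "top": geometry.canopy_width / s}
    net = 0.0
    for face, area in areas.items():
        f = vf[face]
        incident = f["sky"] * lw_sky + f["ground"] * e_ground + f["adjacent"] * e_canopy
        net = net + area * (1.0 - p) * emissivity_canopy * (
            incident - stefan_boltzmann_flux(t_canopy, 1.0, constants)
        )
    return float(net) if np.ndim(net) == 0 else net


@dataclass
class RadiationComponents:
    """Absorbed radiation components, all W per m^2 of ground."""

    sw_direct_abs: np.ndarray | float
    sw_diffuse_abs: np.ndarray | float
    sw_soil_reflected_abs: np.ndarray | float
    lw_net_abs: np.ndarray | float
    r_c: np.ndarray | float


def canopy_net_radiation(met: pd.DataFrame, geometry: CanopyGeometry,
                         porosity, *, leaf_albedo: float = DEFAULT_LEAF_ALBEDO,
                         soil_albedo: float = DEFAULT_SOIL_ALBEDO,
                         include_longwave: bool = False,
                         tz_offset: float = 0.0,
                         constants: PhysicalConstants | None = None) -> pd.DataFrame:
    """Assemble R_c for an aligned 15-minute meteorological table.

    ``met`` must be indexed by timestamp with columns ``t_canopy_C``,
    ``rh_pct`` and ``sw_global_Wm2`` (plus ``lw_sky_Wm2`` and ``t_ground_C``
    when ``include_longwave`` is set).  ``porosity`` may be a scalar or an
    array aligned with the table.  Returns a DataFrame with the absorbed
    components and their sum ``r_c``.
    """
    pos = solar_position(met.index, geometry.latitude, geometry.longitude, tz_offset)
    sw = met["sw_global_Wm2"].to_numpy(dtype=float)
    fd = diffuse_fraction(sw, pos)
    diffuse_h = fd * sw
    beam_h = sw - diffuse_h
    direct = direct_interception(beam_h, pos, geometry, porosity, leaf_albedo)
    diffuse = diffuse_interception(diffuse_h, geometry, porosity, leaf_albedo)
    # transmitted streams (interception removes absorbed + leaf-reflected)
    f_beam = rowgeom.beam_shadow_fraction(
        pos.elevation, pos.azimuth,
        row_spacing=geometry.row_spacing, canopy_width=geometry.canopy_width,
        wall_height=geometry.wall_height, row_azimuth=geometry.row_azimuth,
    )
    f_diff = rowgeom.sky_interception_fraction(geometry)
    keep = 1.0 - np.asarray(porosity)
    sw_to_ground = beam_h * (1.0 - np.asarray(f_beam) * keep) + diffuse_h * (1.0 - f_diff * keep)
    soil = soil_reflected_interception(
        sw_to_ground, soil_albedo, geometry, porosity, leaf_albedo
    )
    if include_longwave:
        missing = [c for c in ("lw_sky_Wm2", "t_ground_C") if c not in met.columns]
        if missing:
            raise ConfigurationError(
                f"long-wave budget enabled but met table lacks columns {missing}"
            )
        lw = longwave_net(
            met["lw_sky_Wm2"].to_numpy(dtype=float),
            met["t_ground_C"].to_numpy(dtype=float),
            met["t_canopy_C"].to_numpy(dtype=float),
            geometry, porosity, constants=constants,
        )
    else:
        lw = np.zeros_like(sw)
    r_c = direct + diffuse + soil + lw
    return pd.DataFrame(
        {
            "sw_direct_abs": direct,
            "sw_diffuse_abs": diffuse,
            "sw_soil_reflected_abs": soil,
            "lw_net_abs": lw,
            "r_c": r_c,
        },
        index=met.index,
    )
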