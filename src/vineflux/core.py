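"""Physical constants, canopy geometry and micrometeorological primitives.

Everything downstream of this module works per unit of vineyard ground area
attributable to one vine (row spacing x vine spacing).  Temperatures are in
degrees Celsius, pressures in Pa, fluxes in W m^-2, resistances in s m^-1 and
conductances in m s^-1 unless a function name says otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InvalidInputError

logger = logging.getLogger(__name__)

#: Tetens saturation vapor pressure coefficients (over water).
TETENS_BASE_PA = 610.78
TETENS_A = 17.27
TETENS_B = 237.3


@dataclass(frozen=True)
class PhysicalConstants:
    """Fixed physical coefficients of the flux equations.

    Defaults are the 20 degC / 1 atm values used throughout; they are held
    fixed (rather than recomputed per record) so that the forward and
    inverted flux equations are exact algebraic mirrors of each other.

    Attributes
    ----------
    lambda_v : float
        Latent heat of vaporization of water, J g^-1.
    gamma : float
        Psychrometric constant, Pa degC^-1.
    delta : float
        Slope of the saturation vapor pressure curve, Pa degC^-1.
    rho_cp : float
        Volumetric heat capacity of air, Pa degC^-1.
    n_stomatal_sides : float
        2 for hypostomatous leaves (stomata on one side only), as for
        grapevine; 1 for amphistomatous leaves.
    molar_volume_air : float
        Moles of air per cubic metre at 1 atm and 20 degC, mol m^-3.
    sigma_sb : float
        Stefan-Boltzmann constant, W m^-2 K^-4.
    """

    lambda_v: float = 2257.0
    gamma: float = 65.8
    delta: float = 145.0
    rho_cp: float = 1212.0
    n_stomatal_sides: float = 2.0
    molar_volume_air: float = 41.04
    sigma_sb: float = 5.6704e-8

    def __post_init__(self) -> None:
        for name in (
            "lambda_v",
            "gamma",
            "delta",
            "rho_cp",
            "n_stomatal_sides",
            "molar_volume_air",
            "sigma_sb",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise InvalidInputError(f"{name} must be strictly positive, got {value!r}")


def _as_series(values, name: str) -> pd.Series | None:
    if values is None:
        return None
    series = pd.Series(values, dtype=float).copy()
    series.index = pd.DatetimeIndex(series.index)
    if not series.index.is_monotonic_increasing or series.index.has_duplicates:
        raise InvalidInputError(f"{name} must have sorted, unique dates")
    return series


@dataclass
class CanopyGeometry:
    """Dimensions and aerodynamic ratios of an open hedgerow vine canopy.

    The canopy cross-section is a rectangle of width ``canopy_width``
    spanning heights ``canopy_bottom_h``..``canopy_top_h``, repeated with
    period ``row_spacing`` along the cross-row axis and effectively infinite
    along the row.

    ``displacement_ratio`` (d/h) and ``roughness_ratio`` (z_o/h) place the
    zero-plane displacement and roughness length as fractions of total
    canopy height; their sum times the height is the mean canopy height z_c,
    the level at which in-canopy temperature and humidity are taken as well
    mixed (and where the T/RH probes hang).
    """

    row_spacing: float = 1.8
    vine_spacing: float = 1.0
    canopy_top_h: float = 1.5
    canopy_bottom_h: float = 0.5
    canopy_width: float = 0.4
    row_azimuth: float = 0.0
    displacement_ratio: float = 2.0 / 3.0
    roughness_ratio: float = 0.10
    latitude: float = 44.7833
    longitude: float = -0.5775
    lai_series: pd.Series | None = field(default=None, repr=False)
    porosity_series: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.canopy_top_h < self.canopy_bottom_h or self.canopy_bottom_h < 0:
            raise InvalidInputError("require canopy_top_h > canopy_bottom_h >= 0")
        if not (0 < self.canopy_width < self.row_spacing):
            raise InvalidInputError("require 0 < canopy_width < row_spacing")
        if self.row_spacing <= 0 or self.vine_spacing <= 0:
            raise ConfigurationError("row and vine spacing must be positive")
        if not (0 < self.displacement_ratio < 1 and 0 < self.roughness_ratio < 1):
            raise InvalidInputError("displacement and roughness ratios must lie in (0, 1)")
        self.lai_series = _as_series(self.lai_series, "lai_series")
        self.porosity_series = _as_series(self.porosity_series, "porosity_series")
        if self.lai_series is not None and (self.lai_series <= 0).any():
            raise InvalidInputError("LAI must be > 0 on all dates")
        if self.porosity_series is not None and (
            (self.porosity_series < 0) | (self.porosity_series > 1)
        ).any():
            raise InvalidInputError("porosity values must lie in [0, 1]")

    @property
    def ground_area_per_vine(self) -> float:
        """Vineyard ground area attributable to one vine, m^2."""
        return self.row_spacing * self.vine_spacing

    @property
    def wall_height(self) -> float:
        """Height of the vertical canopy face, m."""
        return self.canopy_top_h - self.canopy_bottom_h

    @property
    def d(self) -> float:
        """Zero-plane displacement height, m."""
        return self.displacement_ratio * self.canopy_top_h

    @property
    def z_o(self) -> float:
        """Roughness length, m."""
        return self.roughness_ratio * self.canopy_top_h

    @property
    def z_c(self) -> float:
        """Mean canopy height d + z_o, m."""
        return self.d + self.z_o

    def lai_at(self, when) -> np.ndarray | float:
        if self.lai_series is None:
            raise ConfigurationError("geometry has no LAI series")
        return interpolate_to_times(self.lai_series, when)

    def porosity_at(self, when) -> np.ndarray | float:
        if self.porosity_series is None:
            raise ConfigurationError("geometry has no porosity series")
        return interpolate_to_times(self.porosity_series, when)


def mean_canopy_height(geometry: CanopyGeometry) -> float:
    """Mean canopy height z_c = (d/h + z_o/h) * h in metres.

    For the default ratios (d = 2/3 h, z_o = 0.10 h) and a 1.5 m canopy this
    puts the well-mixed level at 1.15 m above the ground.
    """
    return geometry.z_c


def saturation_vapor_pressure(t_c) -> np.ndarray | float:
    """Saturation vapor pressure (Pa) from air temperature (degC).

    Uses the Tetens formulation over liquid water,
    ``e_s = 610.78 * exp(17.27 T / (T + 237.3))``.

    Raises
    ------
    InvalidInputError
        If any input is non-finite or at/below -40 degC, where the
        over-water form is no longer meaningful.
    """
    t = np.asarray(t_c, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InvalidInputError("temperature must be finite")
    if np.any(t <= -40.0):
        raise InvalidInputError("temperature out of supported range (> -40 degC)")
    out = TETENS_BASE_PA * np.exp(TETENS_A * t / (t + TETENS_B))
    return float(out) if np.isscalar(t_c) else out


def vapor_pressure_deficit(t_c, rh) -> np.ndarray | float:
    """Vapor pressure deficit D (Pa) from temperature (degC) and RH (%).

    ``D = e_s(T) * (1 - RH/100)``; zero at saturation.
    """
    rh_arr = np.asarray(rh, dtype=float)
    if np.any(~np.isfinite(rh_arr)) or np.any(rh_arr < 0) or np.any(rh_arr > 100):
        raise InvalidInputError("relative humidity must lie in [0, 100] %")
    e_s = np.asarray(saturation_vapor_pressure(t_c), dtype=float)
    out = e_s * (1.0 - rh_arr / 100.0)
    scalar = np.isscalar(t_c) and np.isscalar(rh)
    return float(out) if scalar else out


def clamp_relative_humidity(rh, max_excursion: float = 2.0) -> np.ndarray | float:
    """Clamp slightly out-of-range RH sensor readings into [0, 100] %.

    Sensor jitter commonly reports 100.3 % at dew; excursions up to
    ``max_excursion`` percentage points are clamped with a warning, larger
    ones are rejected as instrument faults.
    """
    arr = np.asarray(rh, dtype=float)
    bad = (arr < -max_excursion) | (arr > 100.0 + max_excursion)
    if np.any(bad & np.isfinite(arr)):
        raise InvalidInputError(
            f"RH excursion beyond {max_excursion} points outside [0, 100]"
        )
    n_clamped = int(np.sum((arr < 0) | (arr > 100)))
    if n_clamped:
        logger.warning("clamped %d RH readings into [0, 100]", n_clamped)
        warnings.warn(f"clamped {n_clamped} RH readings into [0, 100]", stacklevel=2)
    out = np.clip(arr, 0.0, 100.0)
    return float(out) if np.isscalar(rh) else out


def scale_sap_flow(sensor_flow, leaf_area_ratio, geometry: CanopyGeometry):
    """Scale sensor sap flow (g s^-1) to canopy transpiration flux E_c.

    The sensor meters only the shoots downstream of it; whole-vine flow is
    the sensor flow times the whole-vine to downstream leaf-area ratio, and
    E_c (g s^-1 m^-2) is that divided by the ground area attributable to
    the vine.
    """
    flow = np.asarray(sensor_flow, dtype=float)
    ratio = np.asarray(leaf_area_ratio, dtype=float)
    if np.any(ratio < 1.0):
        raise InvalidInputError("leaf_area_ratio must be >= 1")
    area = geometry.ground_area_per_vine
    if area <= 0:
        raise ConfigurationError("ground area per vine must be positive")
    out = flow * ratio / area
    scalar = np.isscalar(sensor_flow) and np.isscalar(leaf_area_ratio)
    return float(out) if scalar else out


def conductance_to_molar(g, constants: PhysicalConstants | None = None):
    """Convert conductance from m s^-1 to mmol m^-2 s^-1.

    Multiplies by the molar volume of air (41.04 mol m^-3 at 1 atm, 20 degC)
    and by 1000 to express the result in millimoles.
    """
    constants = constants or PhysicalConstants()
    arr = np.asarray(g, dtype=float)
    if np.any(arr < 0):
        raise InvalidInputError("conductance must be non-negative")
    out = arr * constants.molar_volume_air * 1000.0
    return float(out) if np.isscalar(g) else out


def interpolate_to_times(series: pd.Series, when) -> np.ndarray | float:
    """Piecewise-linear value of a dated series at arbitrary timestamps.

    Outside the observed span the endpoint values are held constant.
    """
    series = _as_series(series, "series")
    scalar = not hasattr(when, "__len__")
    times = pd.DatetimeIndex([when]) if scalar else pd.DatetimeIndex(when)
    x = series.index.asi8.astype(float)
    out = np.interp(times.asi8.astype(float), x, series.to_numpy(dtype=float))
    return float(out[0]) if scalar else out


def interpolate_to_interval(series: pd.Series, target_step) -> pd.Series:
    """Resample a dated series to a regular cadence by linear interpolation.

    Used to bring hourly pyranometer readings and sparse canopy surveys to
    the common 15-minute grid.  Requires at least two points with strictly
    increasing timestamps; the output grid spans the observed range.
    """
    series = _as_series(series, "series")
    if len(series) < 2:
        raise InvalidInputError("need at least two points to interpolate")
    grid = pd.date_range(series.index[0], series.index[-1], freq=target_step)
    values = interpolate_to_times(series, grid)
    return pd.Series(values, index=grid, name=series.name)
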