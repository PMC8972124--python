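"""Seeded synthetic vineyard seasons for end-to-end testing.

Emulates the study design the method targets: a Bordeaux-like site
(44.78 N), north-south rows 1.8 m apart with 1.0 m vine spacing and a
0.5-1.5 m tall, 0.4 m wide hedgerow, a July to mid-September season on a
15-minute grid, a seasonal drought drift in predawn water potential with
one mid-August rainfall recovery, and sap flow produced by the forward
flux equation plus multiplicative sensor noise.

The prescribed "true" bulk conductance follows a Jarvis-type
multiplicative response — saturating in absorbed radiation, exponentially
declining in vapor pressure deficit, linearly shutting down with predawn
water potential — chosen because it reproduces the qualitative diurnal and
seasonal behaviour of real vines while remaining simple and invertible for
tests.  It is not a fitted model of any particular vineyard.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import radiation
from .conductance import bulk_boundary_resistances, canopy_latent_heat
from .core import (
    CanopyGeometry,
    PhysicalConstants,
    interpolate_to_times,
    vapor_pressure_deficit,
)
from .exceptions import InvalidInputError


def _default_geometry() -> CanopyGeometry:
    # LAI rises then falls back after mid-season hedging (canopy dimensions
    # are maintained by trimming in a managed vineyard); porosity mirrors it
    return CanopyGeometry(
        lai_series=pd.Series(
            [1.1, 1.4, 1.25],
            index=pd.to_datetime(["2020-07-05", "2020-08-05", "2020-09-05"]),
        ),
        porosity_series=pd.Series(
            [0.33, 0.26, 0.29],
            index=pd.to_datetime(["2020-07-05", "2020-08-05", "2020-09-05"]),
        ),
    )


def _default_psi_pd() -> pd.Series:
    # Six campaigns ~12 days apart; the August rebound mirrors the one
    # significant rainfall of a dry season infiltrating the upper root zone.
    return pd.Series(
        [-0.05, -0.25, -0.50, -0.75, -0.35, -1.00],
        index=pd.to_datetime(
            ["2020-07-03", "2020-07-15", "2020-07-27",
             "2020-08-08", "2020-08-20", "2020-09-10"]
        ),
    )


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic season generator.

    ``g_max`` (mm s^-1) is the unstressed light- and VPD-saturated bulk
    conductance; ``radiation_response_halfsat`` (W m^-2) the absorbed
    radiation at which the light response reaches half of g_max;
    ``vpd_sensitivity`` (Pa^-1) the exponential decline rate with D_c
    (2.0e-4 halves conductance near 3.5 kPa); ``psi_pd_series`` (MPa,
    <= 0) drives the seasonal drought shutdown, reaching full closure at
    -1.5 MPa.

    Real canopies show substantial conductance variability that no smooth
    weather response explains (stomatal patchiness, wind gusts, hydraulic
    transients); ``g_fluct_sd`` adds a mean-one lognormal AR(1) fluctuation
    with correlation time ``g_fluct_tau_hours`` on top of the deterministic
    response, shared by all vines.  ``lai_spread`` gives each vine its own
    uniform leaf-area multiplier in [1 - s, 1 + s], as between real vines.
    Noise terms: multiplicative lognormal on sap flow, additive Gaussian on
    temperature (degC) and relative humidity (%).  ``n_vines`` defaults to
    the ten-vine pooled design of the field study the generator emulates.
    """

    start: str = "2020-07-01"
    end: str = "2020-09-15"
    geometry: CanopyGeometry = field(default_factory=_default_geometry)
    tz_offset: float = 0.0
    g_max: float = 10.0
    radiation_response_halfsat: float = 50.0
    vpd_sensitivity: float = 2.0e-4
    psi_pd_series: pd.Series = field(default_factory=_default_psi_pd)
    g_fluct_sd: float = 0.25
    g_fluct_tau_hours: float = 6.0
    lai_spread: float = 0.15
    noise_sd_sapflow: float = 0.1
    noise_sd_met_t: float = 0.2
    noise_sd_met_rh: float = 1.0
    leaf_area_ratio: float = 3.0
    n_vines: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g_max <= 0:
            raise InvalidInputError("g_max must be > 0")
        for name in ("noise_sd_sapflow", "noise_sd_met_t", "noise_sd_met_rh"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        if (pd.Series(self.psi_pd_series) > 0).any():
            raise InvalidInputError("psi_pd values must be <= 0 MPa")


@dataclass
class SyntheticSeason:
    """Generated tables: met, canopy survey, per-vine sap flow and truth."""

    config: SyntheticConfig
    met: pd.DataFrame
    canopy: pd.DataFrame
    sapflow: pd.DataFrame
    truth: pd.DataFrame
    radiation: pd.DataFrame


def generate_weather(config: SyntheticConfig,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate a 15-minute in-canopy weather table.

    Shortwave is a 0.75-transmittance clear-sky envelope scaled by a daily
    cloudiness factor in (0.2, 1.0] (skewed toward clear, as in a dry
    summer); temperature follows a sinusoid peaking mid-afternoon, warmer
    on clear days; relative humidity is anti-correlated with temperature.
    Sky long-wave and ground temperature columns are included so the
    optional long-wave budget can be exercised.
    """
    rng = rng or np.random.default_rng(config.seed)
    times = pd.date_range(
        pd.Timestamp(config.start) + pd.Timedelta(minutes=15),
        pd.Timestamp(config.end) + pd.Timedelta(days=1),
        freq="15min",
    )
    geom = config.geometry
    pos = radiation.solar_position(times, geom.latitude, geom.longitude, config.tz_offset)
    sw_clear = 0.75 * pos.extraterrestrial_horizontal

    days = times.normalize()
    unique_days = days.unique()
    cloud = 1.0 - 0.8 * rng.random(len(unique_days)) ** 2  # mostly clear
    # seasonal heat bump peaking in early August, as atmospheric demand
    # builds alongside the soil drought in a Mediterranean summer
    doy = unique_days.dayofyear.to_numpy(dtype=float)
    seasonal = 4.0 * np.exp(-0.5 * ((doy - 221.0) / 18.0) ** 2)
    t_base = 19.0 + seasonal + 5.0 * cloud + rng.normal(0.0, 1.0, len(unique_days))
    day_map = pd.Series(cloud, index=unique_days)
    base_map = pd.Series(t_base, index=unique_days)
    c_d = day_map.reindex(days).to_numpy()
    b_d = base_map.reindex(days).to_numpy()

    sw = c_d * sw_clear
    hours = times.hour + times.minute / 60.0
    t = b_d + (2.0 + 5.0 * c_d) * np.cos(2.0 * np.pi * (hours - 15.0) / 24.0)
    t = t + rng.normal(0.0, config.noise_sd_met_t, len(times))
    rh = 105.0 - 3.0 * t + rng.normal(0.0, config.noise_sd_met_rh, len(times))
    rh = np.clip(rh, 20.0, 100.0)

    sigma = PhysicalConstants().sigma_sb
    # simple grey-sky downwelling and sun-warmed ground surface
    lw_sky = (0.75 + 0.2 * (1.0 - c_d)) * sigma * (t + 273.15) ** 4
    t_ground = t + 10.0 * sw / 1000.0

    return pd.DataFrame(
        {
            "t_canopy_C": t,
            "rh_pct": rh,
            "sw_global_Wm2": sw,
            "lw_sky_Wm2": lw_sky,
            "t_ground_C": t_ground,
        },
        index=pd.Index(times, name="timestamp"),
    )


def true_conductance(r_c, d_c, psi_pd, config: SyntheticConfig):
    """Prescribed bulk conductance (mm s^-1) from its three drivers.

    g = g_max * R_c/(R_c + K_R) * exp(-k_D D_c) * max(0, 1 + psi/1.5);
    bounded in [0, g_max], zero in darkness or at psi <= -1.5 MPa.
    """
    r_c = np.asarray(r_c, dtype=float)
    d_c = np.asarray(d_c, dtype=float)
    light = r_c / (r_c + config.radiation_response_halfsat)
    vpd = np.exp(-config.vpd_sensitivity * d_c)
    water = np.maximum(0.0, 1.0 + np.asarray(psi_pd, dtype=float) / 1.5)
    out = config.g_max * light * vpd * water
    return float(out) if out.ndim == 0 else out


def forward_sapflow(true_g_mm_s, met: pd.DataFrame, r_c, r_bh,
                    config: SyntheticConfig,
                    rng: np.random.Generator | None = None,
                    constants: PhysicalConstants | None = None) -> pd.Series:
    """Sensor sap flow (g s^-1) from prescribed conductance via the forward model.

    lambda E_c is evaluated with r_bs = 1000 / g (infinite when the stomata
    are closed), scaled down to the sensor with the ground area and
    leaf-area ratio, and multiplied by lognormal noise exp(N(0, sd)).
    With zero noise the pipeline inversion recovers the prescribed
    conductance exactly on unfiltered intervals.
    """
    rng = rng or np.random.default_rng(config.seed)
    c = constants or PhysicalConstants()
    g = np.asarray(true_g_mm_s, dtype=float)
    with np.errstate(divide="ignore"):
        r_bs = np.where(g > 0, 1000.0 / np.where(g > 0, g, 1.0), np.inf)
    d_c = vapor_pressure_deficit(
        met["t_canopy_C"].to_numpy(), met["rh_pct"].to_numpy()
    )
    lam_e = canopy_latent_heat(r_bs, r_c, d_c, r_bh, c)
    e_c = lam_e / c.lambda_v
    sensor = e_c * config.geometry.ground_area_per_vine / config.leaf_area_ratio
    if config.noise_sd_sapflow > 0:
        sensor = sensor * np.exp(rng.normal(0.0, config.noise_sd_sapflow, len(sensor)))
    return pd.Series(sensor, index=met.index, name="sensor_flow_g_s")


def conductance_fluctuation(n: int, config: SyntheticConfig,
                            rng: np.random.Generator) -> np.ndarray:
    """Mean-one lognormal AR(1) multiplier for the prescribed conductance.

    exp(sigma x_t - sigma^2 / 2) with x_t a standard AR(1) process whose
    correlation time is ``g_fluct_tau_hours`` on the 15-minute grid.
    """
    sigma = config.g_fluct_sd
    if sigma <= 0:
        return np.ones(n)
    a = float(np.exp(-0.25 / config.g_fluct_tau_hours))
    eps = rng.normal(size=n)
    x = np.empty(n)
    x[0] = eps[0]
    for i in range(1, n):
        x[i] = a * x[i - 1] + np.sqrt(1.0 - a * a) * eps[i]
    return np.exp(sigma * x - 0.5 * sigma * sigma)


def generate_season(config: SyntheticConfig | None = None) -> SyntheticSeason:
    """Generate a full synthetic season: weather, truth and per-vine sap flow.

    All randomness derives from ``config.seed``; the same seed reproduces
    the same season bit-for-bit.  The prescribed conductance (deterministic
    response times the shared AR(1) fluctuation) is common to all vines;
    vines differ in their leaf-area multiplier and sensor noise.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    met = generate_weather(config, rng)
    geom = config.geometry

    porosity = geom.porosity_at(met.index)
    rad = radiation.canopy_net_radiation(
        met, geom, porosity, include_longwave=False, tz_offset=config.tz_offset
    )
    r_c = rad["r_c"].to_numpy()
    d_c = vapor_pressure_deficit(
        met["t_canopy_C"].to_numpy(), met["rh_pct"].to_numpy()
    )
    psi = interpolate_to_times(config.psi_pd_series, met.index)
    fluct = conductance_fluctuation(len(met), config, rng)
    g_true = true_conductance(r_c, d_c, psi, config) * fluct
    truth = pd.DataFrame({"true_g_mm_s": g_true, "psi_pd_MPa": psi}, index=met.index)

    lai_base = np.asarray(geom.lai_at(met.index), dtype=float)
    lai_mult = rng.uniform(1.0 - config.lai_spread, 1.0 + config.lai_spread,
                           config.n_vines)

    frames = []
    for v in range(config.n_vines):
        r_bh, _ = bulk_boundary_resistances(lai_base * lai_mult[v])
        flow = forward_sapflow(g_true, met, r_c, r_bh, config, rng)
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": met.index,
                    "vine_id": f"V{v + 1:02d}",
                    "sensor_flow_g_s": flow.to_numpy(),
                }
            )
        )
    sapflow = pd.concat(frames, ignore_index=True)

    survey_dates = geom.lai_series.index
    canopy_rows = []
    for v in range(config.n_vines):
        for date in survey_dates:
            canopy_rows.append(
                {
                    "date": date.date().isoformat(),
                    "vine_id": f"V{v + 1:02d}",
                    "lai_m2m2": float(geom.lai_series.loc[date]) * lai_mult[v],
                    "porosity_frac": float(geom.porosity_series.loc[date]),
                }
            )
    canopy = pd.DataFrame(canopy_rows)
    return SyntheticSeason(config, met, canopy, sapflow, truth, rad)


def with_drought_scale(config: SyntheticConfig, scale: float) -> SyntheticConfig:
    """A copy of ``config`` with the drought drift scaled by ``scale``."""
    return replace(config, psi_pd_series=config.psi_pd_series * scale)
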