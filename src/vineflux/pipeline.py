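"""End-to-end runs: estimate conductance, generate fixtures, run sensitivity.

These are the library entry points behind the command-line interface; each
takes a :class:`RunConfig` (or explicit tables) and writes the standard
output tables with provenance headers plus a JSON run report that counts
every filtered record by reason.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, radiation, sensitivity, synthetic
from .conductance import (
    DEFAULT_R_BL,
    DEFAULT_RC_THRESHOLD,
    bulk_boundary_resistances,
    compute_flux_records,
    daily_max_hourly_running_mean,
)
from .core import (
    CanopyGeometry,
    PhysicalConstants,
    clamp_relative_humidity,
    interpolate_to_times,
    vapor_pressure_deficit,
)
from .exceptions import ConfigurationError, InvalidInputError

logger = logging.getLogger(__name__)

GEOMETRY_KEYS = (
    "row_spacing", "vine_spacing", "canopy_top_h", "canopy_bottom_h",
    "canopy_width", "row_azimuth", "displacement_ratio", "roughness_ratio",
    "latitude", "longitude",
)
CONSTANT_KEYS = (
    "lambda_v", "gamma", "delta", "rho_cp", "n_stomatal_sides",
    "molar_volume_air", "sigma_sb",
)


@dataclass
class RunConfig:
    """Configuration for a pipeline run."""

    met_path: str | None = None
    sapflow_path: str | None = None
    canopy_path: str | None = None
    output_dir: str = "."
    geometry_overrides: dict = field(default_factory=dict)
    constants_overrides: dict = field(default_factory=dict)
    include_longwave: bool = False
    rc_threshold: float = DEFAULT_RC_THRESHOLD
    r_bl: float = DEFAULT_R_BL
    leaf_area_ratio: float = 3.0
    leaf_albedo: float = radiation.DEFAULT_LEAF_ALBEDO
    soil_albedo: float = radiation.DEFAULT_SOIL_ALBEDO
    tz_offset: float = 0.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.rc_threshold < 0:
            raise ConfigurationError("rc_threshold must be >= 0")
        if self.r_bl <= 0:
            raise ConfigurationError("r_bl must be > 0")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = io.read_config(path)
        kwargs: dict = {}
        geometry: dict = {}
        constants: dict = {}
        for key, value in raw.items():
            if key in GEOMETRY_KEYS:
                geometry[key] = value
            elif key in CONSTANT_KEYS:
                constants[key] = value
            elif key in {f.name for f in dataclasses.fields(cls)}:
                kwargs[key] = value
            else:
                raise ConfigurationError(f"unknown config key {key!r}")
        return cls(geometry_overrides=geometry, constants_overrides=constants, **kwargs)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def constants(self) -> PhysicalConstants:
        return PhysicalConstants(**self.constants_overrides)


def _build_geometry(config: RunConfig, canopy: pd.DataFrame, vine_id) -> CanopyGeometry:
    sub = canopy[canopy["vine_id"] == vine_id].sort_values("date")
    if sub.empty:
        raise ConfigurationError(f"no canopy survey rows for vine {vine_id!r}")
    return CanopyGeometry(
        lai_series=pd.Series(sub["lai_m2m2"].to_numpy(), index=sub["date"]),
        porosity_series=pd.Series(sub["porosity_frac"].to_numpy(), index=sub["date"]),
        **config.geometry_overrides,
    )


def run_estimate(config: RunConfig) -> dict:
    """Compute radiation and conductance tables from the configured inputs.

    Writes ``radiation.csv``, ``gbs.csv``, ``daily.csv`` and
    ``report.json`` to the output directory and returns the report dict.
    """
    for name in ("met_path", "sapflow_path", "canopy_path"):
        path = getattr(config, name)
        if path is None or not Path(path).exists():
            raise ConfigurationError(f"{name} missing or does not exist: {path!r}")
    met = io.read_met_csv(config.met_path)
    sapflow = io.read_sapflow_csv(config.sapflow_path)
    canopy = io.read_canopy_csv(config.canopy_path)
    met = met.copy()
    met["rh_pct"] = clamp_relative_humidity(met["rh_pct"].to_numpy())
    constants = config.constants()

    overlap = met.index.intersection(pd.DatetimeIndex(sapflow["timestamp"].unique()))
    if len(overlap) == 0:
        raise ConfigurationError("met and sap-flow time ranges do not overlap")

    provenance = {
        "tool": f"vineflux {__version__}",
        "config_hash": io.config_hash(config.as_dict()),
        "seed": config.seed,
    }
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    gbs_frames = []
    rad_frames = []
    daily_frames = []
    counts: dict[str, int] = {}
    for vine_id, group in sapflow.groupby("vine_id"):
        geometry = _build_geometry(config, canopy, vine_id)
        flows = group.set_index("timestamp")["sensor_flow_g_s"].reindex(met.index)
        porosity = geometry.porosity_at(met.index)
        rad = radiation.canopy_net_radiation(
            met, geometry, porosity,
            leaf_albedo=config.leaf_albedo, soil_albedo=config.soil_albedo,
            include_longwave=config.include_longwave,
            tz_offset=config.tz_offset, constants=constants,
        )
        lai = geometry.lai_at(met.index)
        r_bh, _ = bulk_boundary_resistances(lai, config.r_bl,
                                            constants.n_stomatal_sides)
        d_c = vapor_pressure_deficit(
            met["t_canopy_C"].to_numpy(), met["rh_pct"].to_numpy()
        )
        e_c = flows.to_numpy() * config.leaf_area_ratio / geometry.ground_area_per_vine
        records = compute_flux_records(
            e_c, d_c, rad["r_c"].to_numpy(), r_bh,
            constants=constants, rc_threshold=config.rc_threshold,
            index=met.index,
        )
        records.insert(0, "vine_id", vine_id)
        records.index.name = "timestamp"
        gbs_frames.append(records)
        rad_vine = rad.copy()
        rad_vine.insert(0, "vine_id", vine_id)
        rad_vine.index.name = "timestamp"
        rad_frames.append(rad_vine)
        daily = daily_max_hourly_running_mean(records["g_bs_mm_s"])
        daily_frames.append(
            pd.DataFrame({"vine_id": vine_id, "daily_max_hourly_g_bs": daily})
        )
        for reason, n in records["filter_reason"].value_counts().items():
            if reason:
                counts[reason] = counts.get(reason, 0) + int(n)

    gbs = pd.concat(gbs_frames)
    rad_all = pd.concat(rad_frames)
    daily_all = pd.concat(daily_frames)
    daily_all.index.name = "date"
    io.write_table(rad_all, outdir / "radiation.csv", provenance=provenance, index=True)
    io.write_table(gbs, outdir / "gbs.csv", provenance=provenance, index=True)
    io.write_table(daily_all, outdir / "daily.csv", provenance=provenance, index=True)

    report = {
        "tool_version": __version__,
        "config": config.as_dict(),
        "records_read": int(len(met)),
        "vines": sorted(sapflow["vine_id"].unique().tolist()),
        "records_total": int(len(gbs)),
        "records_unfiltered": int((~gbs["filtered"]).sum()),
        "filtered_by_reason": counts,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def run_synth(config: synthetic.SyntheticConfig, output_dir) -> dict:
    """Generate a synthetic season and write the input-table fixtures."""
    season = synthetic.generate_season(config)
    outdir = Path(output_dir)
    provenance = {
        "tool": f"vineflux {__version__}",
        "config_hash": io.config_hash({"seed": config.seed, "start": config.start,
                                       "end": config.end, "g_max": config.g_max}),
        "seed": config.seed,
    }
    met = season.met.copy()
    met.index.name = "timestamp"
    io.write_table(met, outdir / "met.csv", provenance=provenance, index=True)
    io.write_table(season.sapflow, outdir / "sapflow.csv", provenance=provenance)
    io.write_table(season.canopy, outdir / "canopy.csv", provenance=provenance)
    truth = season.truth.copy()
    truth.index.name = "timestamp"
    io.write_table(truth, outdir / "truth.csv", provenance=provenance, index=True)
    return {
        "records": int(len(season.met)),
        "vines": config.n_vines,
        "seed": config.seed,
        "output_dir": str(outdir),
    }


def run_sensitivity(gbs_path, output_dir, *, response: str = "g_bs_mm_s",
                    predictors: list[str] | None = None,
                    n_trees: int = sensitivity.DEFAULT_N_TREES,
                    tune: bool = True,
                    seed: int = 0) -> sensitivity.SensitivityResult:
    """Run the forest sensitivity analysis on an unfiltered gbs table.

    Hyperparameters are first optimized by the out-of-bag grid search
    (disable with ``tune=False`` to use the fixed defaults).
    """
    predictors = predictors or ["e_c", "d_c", "r_c", "r_bh"]
    gbs = pd.read_csv(gbs_path, comment="#")
    data = gbs[~gbs["filtered"]]
    if len(data) < 50:
        raise InvalidInputError(
            f"sensitivity analysis needs >= 50 unfiltered rows, got {len(data)}"
        )
    result = sensitivity.analyze(
        data, response, predictors, n_trees=n_trees, tune=tune, seed=seed
    )
    outdir = Path(output_dir)
    provenance = {
        "tool": f"vineflux {__version__}",
        "seed": seed,
        "hyperparameters": json.dumps(result.hyperparameters),
        "oob_r2": f"{result.oob_r2:.4f}",
        "response": response,
    }
    depth_table = result.minimal_depth.rename_axis("predictor").reset_index()
    io.write_table(depth_table, outdir / "sensitivity.csv", provenance=provenance)
    inter = (
        result.interaction_matrix.rename_axis("v")
        .reset_index()
        .melt(id_vars="v", var_name="w", value_name="value")
        .dropna()
    )
    io.write_table(inter, outdir / "interactions.csv", provenance=provenance)
    return result


def score_against_truth(gbs: pd.DataFrame, truth: pd.DataFrame,
                        min_r_c: float = 0.0) -> pd.DataFrame:
    """Join recovered conductance with generator truth and report errors."""
    merged = gbs.reset_index().merge(
        truth.reset_index(), on="timestamp", how="inner"
    )
    merged = merged[~merged["filtered"] & (merged["r_c"] >= min_r_c)]
    merged = merged[merged["true_g_mm_s"] > 0]
    merged["rel_error"] = (
        np.abs(merged["g_bs_mm_s"] - merged["true_g_mm_s"]) / merged["true_g_mm_s"]
    )
    return merged
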