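"""Generate a synthetic season, invert it, and score against the truth.

With zero sensor noise the inversion is an exact algebraic mirror of the
forward model, so the recovered conductance matches the prescribed one to
numerical precision; with 10% lognormal sap-flow noise the error budget of
the method becomes visible.
"""

import numpy as np

from vineflux.conductance import bulk_boundary_resistances, compute_flux_records
from vineflux.core import interpolate_to_times, vapor_pressure_deficit
from vineflux.pipeline import score_against_truth
from vineflux.synthetic import SyntheticConfig, generate_season
import pandas as pd


def invert_vine(season, vine_id):
    config = season.config
    met = season.met
    flows = season.sapflow[season.sapflow["vine_id"] == vine_id]
    flows = flows.set_index("timestamp")["sensor_flow_g_s"].reindex(met.index)
    survey = season.canopy[season.canopy["vine_id"] == vine_id]
    lai = interpolate_to_times(
        pd.Series(survey["lai_m2m2"].to_numpy(), index=pd.to_datetime(survey["date"])),
        met.index,
    )
    r_bh, _ = bulk_boundary_resistances(lai)
    d_c = vapor_pressure_deficit(met["t_canopy_C"].to_numpy(), met["rh_pct"].to_numpy())
    e_c = flows.to_numpy() * config.leaf_area_ratio / config.geometry.ground_area_per_vine
    return compute_flux_records(e_c, d_c, season.radiation["r_c"].to_numpy(),
                                r_bh, index=met.index)


for noise in (0.0, 0.1):
    config = SyntheticConfig(start="2020-07-01", end="2020-07-28",
                             n_vines=1, noise_sd_sapflow=noise, seed=7)
    season = generate_season(config)
    records = invert_vine(season, "V01")
    scored = score_against_truth(records, season.truth, min_r_c=200.0)
    print(f"sap-flow noise sd = {noise:.1f}:")
    print(f"  unfiltered high-radiation intervals : {len(scored)}")
    print(f"  median |relative error| in g_bs     : {scored['rel_error'].median():.2e}")
    print(f"  90th percentile                     : {scored['rel_error'].quantile(0.9):.2e}")

print()
print("Zero noise recovers the prescribed conductance to ~1e-16 (machine")
print("precision); 10% flux noise propagates to a ~10% median error in")
print("conductance on well-lit intervals, the method's working accuracy.")
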