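"""Forest-based sensitivity analysis of the inverted flux equation.

Pools a multi-vine synthetic season, regresses recovered conductance on
its four inputs with a random forest, and reports minimal depths and the
pairwise maximal-subtree interaction matrix.
"""

import pandas as pd

from vineflux.conductance import bulk_boundary_resistances, compute_flux_records
from vineflux.core import interpolate_to_times, vapor_pressure_deficit
from vineflux.sensitivity import analyze
from vineflux.synthetic import SyntheticConfig, generate_season


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


season = generate_season(SyntheticConfig(start="2020-07-01", end="2020-08-15",
                                         n_vines=6, seed=3))
records = pd.concat(
    invert_vine(season, v) for v in sorted(season.sapflow["vine_id"].unique())
)
ok = records[~records["filtered"]]

result = analyze(ok, "g_bs_mm_s", ["e_c", "d_c", "r_c", "r_bh"],
                 n_trees=300, tune=True, seed=3)

print(f"rows: {len(ok)}, out-of-bag R^2: {result.oob_r2:.3f}, "
      f"mtry: {result.hyperparameters['mtry']}")
print("\nminimal depth (0 = most important):")
for name, depth in result.minimal_depth.sort_values().items():
    print(f"  {name:5s} {depth:6.2f}")
print("\npairwise normalized interaction (0 = strong, 1 = none):")
print(result.interaction_matrix.round(2).to_string())
print()
print("The sap-flow flux e_c dominates, vapor pressure deficit follows,")
print("and the boundary-layer resistance r_bh contributes least - the")
print("basis for assuming a fixed leaf resistance instead of measuring")
print("wind above the canopy.")
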