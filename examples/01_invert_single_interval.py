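"""Invert one 15-minute interval of measurements to bulk conductance.

Builds the inputs of the flux equation by hand — a sap-flow reading scaled
to transpiration flux, an in-canopy vapor pressure deficit, an absorbed
net radiation, and the bulk boundary-layer resistance from LAI — then
inverts to bulk stomatal resistance and conductance.
"""

from vineflux import (
    CanopyGeometry,
    PhysicalConstants,
    bulk_boundary_resistances,
    conductance_to_molar,
    invert_to_r_bs,
    scale_sap_flow,
    vapor_pressure_deficit,
)

constants = PhysicalConstants()
geometry = CanopyGeometry()  # 1.8 m rows x 1.0 m vines, 0.5-1.5 m canopy

# one mid-morning interval: 0.02 g/s at the sensor, sensor meters a third
# of the vine's leaf area; 27 degC and 45% RH in the canopy; 320 W/m^2
# absorbed by the canopy; LAI 1.3
e_c = scale_sap_flow(sensor_flow=0.02, leaf_area_ratio=3.0, geometry=geometry)
d_c = vapor_pressure_deficit(27.0, 45.0)
r_bh, r_bv = bulk_boundary_resistances(lai=1.3, r_bl=25.0)
r_bs = invert_to_r_bs(e_c, r_c=320.0, d_c=d_c, r_bh=r_bh)
g_mm_s = 1000.0 / r_bs
g_mmol = conductance_to_molar(g_mm_s / 1000.0)

print(f"E_c                 : {e_c:8.4f} g s^-1 m^-2  (transpiration flux)")
print(f"lambda E_c          : {constants.lambda_v * e_c:8.1f} W m^-2       (latent heat flux)")
print(f"D_c                 : {d_c:8.0f} Pa           (vapor pressure deficit)")
print(f"r_bh                : {r_bh:8.2f} s m^-1       (bulk boundary-layer, heat)")
print(f"r_bs                : {r_bs:8.1f} s m^-1       (bulk stomatal resistance)")
print(f"g_bs                : {g_mm_s:8.2f} mm s^-1      (bulk stomatal conductance)")
print(f"g_bs (molar)        : {g_mmol:8.1f} mmol m^-2 s^-1")
print()
print("A mid-range vine under moderate demand: conductance of a few mm/s,")
print("well inside the envelope reported for field-grown grapevines.")
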