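# Methods

## The problem

Stomatal conductance integrated to the whole canopy — *bulk stomatal
conductance*, `g_bs` (mm s⁻¹ per unit vineyard ground area) — is the
quantity that couples vine water use to atmospheric demand and drought
stress, but it cannot be measured directly at canopy scale.  For open,
row-trained canopies (vertical shoot positioning, wide inter-row gaps) a
big-leaf Penman–Monteith treatment is inappropriate: the canopy and the
bare inter-row soil are separate sources.  This package implements the
two-source alternative: treat the hedgerow canopy as a well-mixed source
at the mean canopy height `z_c = d + z_o` and invert its latent-heat flux
equation for the bulk stomatal resistance, using sap flow as the measured
flux.

## Flux model and inversion

Canopy latent heat flux per unit ground area:

    λE_c = (Δ·R_c + ρCp·D_c / r_bh) / (Δ + γ·(n + r_bs / r_bh))

with `E_c` transpiration flux (g s⁻¹ m⁻²), `R_c` net radiation absorbed by
the canopy (W m⁻²), `D_c` vapor pressure deficit at `z_c` (Pa), `r_bs` and
`r_bh` the bulk stomatal and boundary-layer resistances (s m⁻¹), and
`n = 2` for hypostomatous (one-sided-stomata) grapevine leaves.  The
coefficients are fixed at their 20 °C / 1 atm values — λ = 2257 J g⁻¹,
γ = 65.8 Pa °C⁻¹, Δ = 145 Pa °C⁻¹, ρCp = 1212 Pa °C⁻¹ — so that the
forward and inverted forms are exact algebraic mirrors; an opt-in
temperature-dependent Δ would break that mirror and is deliberately not
the default.

Solving for the resistance given a measured flux:

    r_bs = (Δ·R_c·r_bh + ρCp·D_c) / (γ·λ·E_c) − r_bh·(Δ/γ + n)

and `g_bs = 1 / r_bs` (mm s⁻¹ when r_bs is in s m⁻¹), optionally
converted to molar units with the molar volume of air at 20 °C / 1 atm
(×41.04 → mmol m⁻² s⁻¹).  The sign of the `n` term is sometimes printed
inconsistently in the literature; only the `+n` form is the true inverse,
which the test suite enforces by a round-trip identity (forward ∘ inverse
= identity to 1e-9 relative) and by agreement with a bracketed numerical
root solve.

Bulk boundary-layer resistances come from a one-sided leaf-level value:
`r_bh = r_bl / (2·LAI)` and `r_bv = n·r_bh`.  The default `r_bl` is the
standard no-wind-data assumption of 25 s m⁻¹, justified a posteriori by
the sensitivity analysis (r_bh is the least influential input).  The leaf
equivalent of a bulk resistance is `r_s = 2·LAI·r_bs / n`.

Vapor pressure deficit uses the Tetens saturation curve over liquid water
(610.78 Pa, 17.27, 237.3 °C); the source measurements name the equation
without coefficients, so the common over-water set is adopted and stated.

## Sap-flow scaling

A heat-balance sap-flow gauge meters one cane.  Whole-vine flow is the
gauge reading times the ratio of whole-vine leaf area to leaf area
downstream of the gauge (≥ 1); dividing by the ground area per vine
(row spacing × vine spacing, default 1.8 m²) gives `E_c`.

## Absorbed radiation

`R_c` is modelled, not measured.  The canopy cross-section is a rectangle
(default 0.5–1.5 m tall, 0.4 m wide, rows 1.8 m apart) repeated
indefinitely along and across rows.  Measured global shortwave (hourly,
linearly interpolated to 15 min) is split into beam and diffuse with a
piecewise clearness-index model (fully diffuse below k_t = 0.22;
1 − 6.4(k_t−0.22)² to 0.35; 1.47 − 1.66·k_t above, floored at the
elevation-dependent clear-sky limit), using in-package solar geometry
(Spencer declination and equation of time, solar constant 1367 W m⁻² with
eccentricity correction).

Three absorbed components, each per unit ground area and each reduced by
canopy porosity `p` (gap fraction: transmitted fraction = p) and leaf
albedo (default 0.20):

* **beam** — shadow projection: shaded ground fraction
  `min(1, [W + H·cotβ·|sin(az − az_row)|] / S)`, exact for opaque
  rectangular rows including the mutual-shading cap;
* **diffuse sky** — the cosine-weighted hemisphere average of the same
  shadow fraction, evaluated by Gauss quadrature in cos(zenith) ×
  azimuth; cached per geometry;
* **soil-reflected** — shortwave transmitted to the ground, reflected
  with soil albedo (default 0.18), times a ground→canopy interception
  fraction computed by a periodic slab ray test integrated over ground
  positions and the upward hemisphere.

All geometric fractions live in one module (`rowgeom`) so a different
row-canopy parameterization can be swapped in; every fraction is verified
against an independent seeded Monte-Carlo ray tracer to within 2 %.

An optional long-wave budget uses per-face view factors (2-D infinite-strip
rule; closure `F_sky + F_ground + F_adjacent = 1` is exact by
construction), Stefan–Boltzmann sources with emissivity 0.98 for foliage
and ground, and canopy emission from both walls and the top at in-canopy
temperature.  It is **disabled by default**: under the radiation filter
below the term is small, and omitting it removes two instruments (sky
pyrgeometer, ground IR thermometer) from the field requirement.

## Filtering and summaries

The inversion is ill-conditioned at low energy input.  Records are
*marked*, never deleted, with one reason each, and only unfiltered records
enter summaries:

* `low_radiation` — `R_c` strictly below 50 W m⁻² (threshold
  configurable); an interval at exactly the threshold is retained;
* `nonpositive_flux`, `nonpositive_vpd` — Eq. inputs for which the
  inverse is undefined;
* `nonphysical_rbs` — a computed `r_bs ≤ 0` (possible under noise at low
  D_c); reported as-is, never clamped;
* `missing` — any non-finite input.

The seasonal summary is the daily maximum of the hourly running mean: a
trailing 4-sample window on the 15-min series, windows containing any
filtered value skipped, then a per-calendar-day maximum.  Trailing alignment is a documented
choice; there is no single standard convention for aligning such a
window.

## Synthetic seasons

No field data are deposited, so the generator is the test bed.  It
emulates the study design: Bordeaux-like site (44.78° N), N–S rows,
July 1 – September 15 on a 15-minute grid, ten vines pooled.  Weather is a
0.75-transmittance clear-sky envelope scaled by a seeded daily cloudiness
factor in (0.2, 1] skewed toward clear; temperature is a sinusoid peaking
mid-afternoon plus a ~4 °C seasonal bump peaking in early August (demand
drifts with the drought, as in a Mediterranean summer); RH is
anti-correlated with temperature.

Prescribed conductance is a Jarvis-type product —
`g_max · R_c/(R_c+K_R) · exp(−k_D·D_c) · max(0, 1 + Ψ_PD/1.5)` — times a
mean-one lognormal AR(1) fluctuation (sd 0.25, correlation time 6 h)
representing the variability real canopies show beyond any smooth weather
response.  Defaults: `g_max` = 10 mm s⁻¹, `K_R` = 50 W m⁻²,
`k_D` = 2.0e-4 Pa⁻¹ (halving near 3.5 kPa), chosen once so the default
season's recovered daily maxima land in the 5–15 mm s⁻¹ envelope observed
on field vines.  Ψ_PD follows six campaigns ~12 days apart from −0.05 to
−1.0 MPa with a mid-August rainfall rebound.  LAI per vine is three survey
values (1.1 → 1.4 → 1.25 — non-monotone because hedged canopies are
maintained, not free-growing) times a per-vine multiplier U(0.85, 1.15);
porosity mirrors LAI.

Sap flow is produced by the *forward* flux equation with
`r_bs = 1000 / g_true`, scaled down to the gauge, times lognormal sensor
noise (sd 0.1 by default).  With zero noise the pipeline inversion
recovers the prescribed conductance exactly (the module's core oracle);
with 10 % noise the median conductance error on intervals above
200 W m⁻² is ~9–10 %, the method's working accuracy.

What the generator does **not** emulate: soil water balance, varietal
response differences, sensor drift and data gaps, within-canopy gradients,
and any correlation between Ψ_PD and the particular weather sequence.
Passing tests therefore demonstrate the correctness and conditioning of
the *computation*, not the field accuracy of sap-flow gauges.

## Sensitivity analysis

Pooled unfiltered records (response `g_bs`; predictors `E_c`, `D_c`,
`R_c`, `r_bh`) are strongly collinear, so importance is read from a
random-forest regression rather than linear screens.  *Minimal depth*:
per tree, the depth of the shallowest split on a predictor (root = 0);
trees never splitting on it contribute the tree's maximal depth + 1 (a
stated convention); averaged over trees.  *Second-order maximal subtrees*:
for an ordered pair (v, w), the minimal depth of w inside v's maximal
subtrees (v-splits with no v-split ancestor), relative to the subtree
root and normalized by (deepest relative depth + 1) to [0, 1]; 1 when w
never appears there; 0 indicates strong association.  The matrix is not
symmetric.

The forest is scikit-learn's `RandomForestRegressor`; depth statistics
are computed by walking the fitted trees.  Fixed defaults: 1000 trees,
⌈p/3⌉ candidates per split, minimum node size 5, seeded.  The pipeline
entry point first optimizes the per-split candidate count by an
out-of-bag grid search from ⌈p/3⌉ to p (`tune_mtry`) — a reproducible
stand-in for an external tuning routine.  Near-ties (within 5e-4 of the
best OOB R²) resolve to the *largest* candidate count: with few
candidates per split, shallow nodes are frequently forced onto random
substitute variables, which blurs minimal-depth orderings, so among
statistically indistinguishable forests the least-randomized one yields
the cleanest depth statistics.  On the default synthetic season the
search selects all-predictors splits, and the depths reproduce the
qualitative structure expected for this model: the measured flux first
(depth ≈ 0), vapor pressure deficit second (≈ 1), absorbed radiation and
the boundary-layer resistance far behind, `r_bh` last.

## Numerical choices and edge cases

* Resistances are carried in s m⁻¹ throughout; conductance is derived
  only at output time (no double inversions).
* `r_bs = ∞` (closed stomata) evaluates to zero forward flux.
* Timestamps are interval-ending local clock time; radiation and canopy
  surveys are linearly interpolated to the grid, temperature/RH and sap
  flow join by exact match; unmatched intervals become `missing`, never
  zero.
* RH readings up to 2 points outside [0, 100] are clamped with a warning
  (probe jitter); larger excursions are rejected.
* Geometric quadratures: 48 Gauss nodes in cos(zenith) × 96 azimuths
  (× 48 ground points for the ground→canopy fraction); results cached per
  geometry.  Agreement with the Monte-Carlo oracle is ~0.1 %, well inside
  the 2 % test tolerance.
* Solar positions are valid equatorward of the polar circles only.
* Problem sizes in the test suite: two- to four-week single-vine seasons
  for recovery checks, the full ten-vine default season for the
  sensitivity ranking; forests of 150–300 trees for property tests and
  1000 for the reference configuration.

## Known limitations

* The shortwave row model is a documented geometric reconstruction of a
  cited-but-unpublished scheme: rectangular cross-section, no
  within-canopy radiative transfer, no PAR/NIR split, flat terrain.
* Porosity multiplies all three shortwave streams identically; whether
  soil-reflected flux should see a different gap fraction is unresolved.
* The two-source form omits soil heat flux and above-canopy aerodynamic
  resistance by design; it is not suited to sprawling or pergola canopies
  approaching full cover.
* Fixed 20 °C coefficients bias λE_c slightly at temperature extremes;
  the bias cancels exactly in the round trip but not against independent
  flux measurements.
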