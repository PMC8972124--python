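"""Forward canopy latent-heat flux and its inversion to bulk conductance.

The two-source Penman-Monteith form evaluates latent heat flux from the
vine canopy per unit ground area,

    lambda E_c = (Delta R_c + rho Cp D_c / r_bh)
                 / (Delta + gamma (n + r_bs / r_bh)),

with all fluxes and resistances expressed per unit of vineyard ground
attributable to one vine.  Measuring E_c by sap flow and rearranging gives
the bulk stomatal resistance

    r_bs = (Delta R_c r_bh + rho Cp D_c) / (gamma lambda E_c)
           - r_bh (Delta / gamma + n),

the exact algebraic inverse of the forward form (verified in-package by a
round-trip identity and a bracketed numerical root solve), and bulk
stomatal conductance g_bs = 1 / r_bs.  Bulk boundary-layer resistances
come from the one-sided leaf value: r_bh = r_bl / (2 LAI), r_bv = n r_bh.

Records where the inversion is ill-conditioned — absorbed net radiation
below 50 W m^-2, non-positive transpiration flux or vapor pressure
deficit, or a non-physical (<= 0) resistance — are flagged, never
deleted, so filtering is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PhysicalConstants, conductance_to_molar
from .exceptions import InvalidInputError

#: Default absorbed-radiation filter threshold, W m^-2.
DEFAULT_RC_THRESHOLD = 50.0
#: Default one-sided leaf boundary-layer resistance, s m^-1 (the standard
#: no-wind-data assumption; justified by the low importance of r_bh).
DEFAULT_R_BL = 25.0

FILTER_NONE = ""
FILTER_LOW_RADIATION = "low_radiation"
FILTER_NONPOSITIVE_FLUX = "nonpositive_flux"
FILTER_NONPOSITIVE_VPD = "nonpositive_vpd"
FILTER_NONPHYSICAL_RBS = "nonphysical_rbs"
FILTER_MISSING = "missing"


@dataclass
class ResistanceSet:
    """Canopy-scale resistances, s m^-1 (per unit ground area)."""

    r_bh: float
    r_bv: float
    r_bl: float
    lai: float


def bulk_boundary_resistances(lai, r_bl: float = DEFAULT_R_BL,
                              n: float = 2.0):
    """Bulk boundary-layer resistances to heat and vapor from leaf r_bl.

    r_bh = r_bl / (2 LAI): every leaf face exchanges heat, so the leaf
    resistance acts across twice the leaf area index.  r_bv = n r_bh:
    hypostomatous leaves (n = 2) exchange vapor through one face only.

    Returns ``(r_bh, r_bv)``; inputs may be scalars or arrays.
    """
    lai_arr = np.asarray(lai, dtype=float)
    if np.any(lai_arr <= 0):
        raise InvalidInputError("LAI must be > 0")
    if np.any(np.asarray(r_bl) <= 0):
        raise InvalidInputError("r_bl must be > 0")
    r_bh = np.asarray(r_bl, dtype=float) / (2.0 * lai_arr)
    r_bv = n * r_bh
    if np.isscalar(lai) and np.isscalar(r_bl):
        return float(r_bh), float(r_bv)
    return r_bh, r_bv


def canopy_latent_heat(r_bs, r_c, d_c, r_bh,
                       constants: PhysicalConstants | None = None):
    """Forward model: latent heat flux lambda E_c (W m^-2) from r_bs.

    Strictly decreasing in r_bs; zero when both R_c and D_c are zero.
    ``r_bs = inf`` is allowed and gives zero flux (closed stomata).
    """
    c = constants or PhysicalConstants()
    r_bs = np.asarray(r_bs, dtype=float)
    r_bh_arr = np.asarray(r_bh, dtype=float)
    if np.any(r_bh_arr <= 0):
        raise InvalidInputError("r_bh must be > 0")
    if np.any(r_bs < 0):
        raise InvalidInputError("r_bs must be >= 0")
    num = c.delta * np.asarray(r_c, dtype=float) + c.rho_cp * np.asarray(d_c, dtype=float) / r_bh_arr
    den = c.delta + c.gamma * (c.n_stomatal_sides + r_bs / r_bh_arr)
    with np.errstate(invalid="ignore"):
        out = np.where(np.isinf(r_bs), 0.0, num / den)
    return float(out) if out.ndim == 0 else out


def invert_to_r_bs(e_c, r_c, d_c, r_bh,
                   constants: PhysicalConstants | None = None):
    """Invert the flux equation: bulk stomatal resistance (s m^-1) from E_c.

    ``e_c`` is the sap-flow-derived transpiration flux in g s^-1 m^-2
    (lambda e_c is the latent heat flux).  The closed form is the exact
    algebraic inverse of :func:`canopy_latent_heat`; a non-positive result
    (possible under measurement noise at low D_c) is returned as-is for the
    caller to flag — it is never clamped.
    """
    c = constants or PhysicalConstants()
    e = np.asarray(e_c, dtype=float)
    r_bh_arr = np.asarray(r_bh, dtype=float)
    if np.any(r_bh_arr <= 0):
        raise InvalidInputError("r_bh must be > 0")
    if np.any(e <= 0):
        raise InvalidInputError("E_c must be > 0 for inversion (filter first)")
    num = c.delta * np.asarray(r_c, dtype=float) * r_bh_arr + c.rho_cp * np.asarray(d_c, dtype=float)
    out = num / (c.gamma * c.lambda_v * e) - r_bh_arr * (c.delta / c.gamma + c.n_stomatal_sides)
    return float(out) if out.ndim == 0 else out


def leaf_stomatal_equivalent(r_bs, lai, n: float = 2.0):
    """Equivalent leaf-level stomatal resistance r_s = 2 LAI r_bs / n.

    Inverse of the bulk aggregation r_bs = n r_s / (2 LAI): the canopy
    resistance is the parallel sum of all leaf resistances per unit ground
    area.
    """
    lai_arr = np.asarray(lai, dtype=float)
    if np.any(lai_arr <= 0):
        raise InvalidInputError("LAI must be > 0")
    out = 2.0 * lai_arr * np.asarray(r_bs, dtype=float) / n
    return float(out) if out.ndim == 0 else out


def compute_flux_records(e_c, d_c, r_c, r_bh, *,
                         constants: PhysicalConstants | None = None,
                         rc_threshold: float = DEFAULT_RC_THRESHOLD,
                         index=None) -> pd.DataFrame:
    """Invert aligned series to conductance with full filter bookkeeping.

    All inputs are aligned 1-D arrays (one value per 15-minute interval).
    Returns a DataFrame with columns ``e_c``, ``lambda_e_c``, ``d_c``,
    ``r_c``, ``r_bh``, ``r_bs``, ``g_bs_mm_s``, ``g_bs_mmol``, ``filtered``
    and ``filter_reason``; every input row is preserved.
    """
    c = constants or PhysicalConstants()
    e_c = np.asarray(e_c, dtype=float)
    d_c = np.asarray(d_c, dtype=float)
    r_c = np.asarray(r_c, dtype=float)
    r_bh = np.broadcast_to(np.asarray(r_bh, dtype=float), e_c.shape).copy()
    if rc_threshold < 0:
        raise InvalidInputError("rc_threshold must be >= 0")

    reason = np.full(e_c.shape, FILTER_NONE, dtype=object)
    missing = ~(np.isfinite(e_c) & np.isfinite(d_c) & np.isfinite(r_c) & np.isfinite(r_bh))
    reason[missing] = FILTER_MISSING
    low_rc = ~missing & (r_c < rc_threshold)
    reason[low_rc] = FILTER_LOW_RADIATION
    bad_e = ~missing & ~low_rc & (e_c <= 0)
    reason[bad_e] = FILTER_NONPOSITIVE_FLUX
    bad_d = ~missing & ~low_rc & ~bad_e & (d_c <= 0)
    reason[bad_d] = FILTER_NONPOSITIVE_VPD

    ok = reason == FILTER_NONE
    r_bs = np.full(e_c.shape, np.nan)
    if np.any(ok):
        r_bs[ok] = invert_to_r_bs(e_c[ok], r_c[ok], d_c[ok], r_bh[ok], c)
    nonphys = ok & ~(r_bs > 0)
    reason[nonphys] = FILTER_NONPHYSICAL_RBS
    ok &= r_bs > 0

    g_mm_s = np.where(ok, 1000.0 / r_bs, np.nan)
    g_mmol = np.where(ok, conductance_to_molar(np.where(ok, g_mm_s, 0.0) / 1000.0, c), np.nan)
    return pd.DataFrame(
        {
            "e_c": e_c,
            "lambda_e_c": c.lambda_v * e_c,
            "d_c": d_c,
            "r_c": r_c,
            "r_bh": r_bh,
            "r_bs": r_bs,
            "g_bs_mm_s": g_mm_s,
            "g_bs_mmol": g_mmol,
            "filtered": reason != FILTER_NONE,
            "filter_reason": reason,
        },
        index=index,
    )


def filter_low_radiation(records: pd.DataFrame,
                         threshold: float = DEFAULT_RC_THRESHOLD) -> pd.DataFrame:
    """Mark records whose absorbed net radiation falls below the threshold.

    The rule is strictly "less than": an interval at exactly the threshold
    is retained.  Rows are marked, not dropped, so the original count is
    preserved; rows already filtered for another reason keep their reason.
    """
    if threshold < 0:
        raise InvalidInputError("threshold must be >= 0")
    out = records.copy()
    hit = (out["r_c"] < threshold) & (out["filter_reason"] == FILTER_NONE)
    out.loc[hit, "filter_reason"] = FILTER_LOW_RADIATION
    out.loc[hit, "filtered"] = True
    out.loc[hit, ["g_bs_mm_s", "g_bs_mmol"]] = np.nan
    return out


def daily_max_hourly_running_mean(series: pd.Series) -> pd.Series:
    """Daily maximum of the hourly (4-sample) trailing running mean.

    ``series`` is a 15-minute-cadence series in which filtered or missing
    intervals are NaN.  Windows containing any NaN are skipped; days with
    no complete window yield NaN.  This is the summary used for
    day-to-day comparison of conductance against plant water status.
    """
    if not isinstance(series.index, pd.DatetimeIndex):
        raise InvalidInputError("series must be indexed by timestamp")
    hourly = series.rolling(window=4, min_periods=4).mean()
    daily = hourly.groupby(hourly.index.normalize()).max()
    daily.index.name = "date"
    return daily
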