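"""Independent oracles for the test suite.

Deliberately written on a different route from the package code:
interception fractions by brute-force Monte-Carlo ray tracing against an
explicit list of axis-aligned canopy blocks, and the flux-equation
inversion by a bracketed 1-D numerical root solve of the forward model.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from vineflux.conductance import canopy_latent_heat

#: periods of canopy blocks checked either side of the origin; rays still
#: airborne beyond this are counted as escaping (grazing-angle weight is
#: far below the comparison tolerance).
K_PERIODS = 220


def _block_edges(geometry):
    S, W = geometry.row_spacing, geometry.canopy_width
    k = np.arange(-K_PERIODS, K_PERIODS + 1)
    xa = k * S - W / 2.0
    return xa, xa + W


def _first_block_hit_t(x0, z0, dx, dz, geometry):
    """Smallest positive ray parameter hitting any canopy block, else inf.

    2-D slab test in the cross-row plane; ``dx`` is the cross-row direction
    component, ``dz`` vertical.  Vectorized over rays.
    """
    za, zb = geometry.canopy_bottom_h, geometry.canopy_top_h
    xa, xb = _block_edges(geometry)
    x0 = x0[:, None]
    z0 = z0[:, None]
    dxn = np.where(np.abs(dx) < 1e-300, 1e-300, dx)[:, None]
    dzn = np.where(np.abs(dz) < 1e-300, 1e-300, dz)[:, None]
    tx1 = (xa[None, :] - x0) / dxn
    tx2 = (xb[None, :] - x0) / dxn
    tz1 = (za - z0) / dzn
    tz2 = (zb - z0) / dzn
    t_enter = np.maximum(np.minimum(tx1, tx2), np.minimum(tz1, tz2))
    t_exit = np.minimum(np.maximum(tx1, tx2), np.maximum(tz1, tz2))
    valid = (t_exit >= t_enter) & (t_exit > 1e-9)
    t_hit = np.where(valid, np.maximum(t_enter, 0.0), np.inf)
    return t_hit.min(axis=1)


def mc_sky_interception(geometry, n_rays: int, seed: int) -> float:
    """Fraction of cosine-weighted diffuse sky flux intercepted by the rows."""
    rng = np.random.default_rng(seed)
    S = geometry.row_spacing
    x0 = rng.uniform(-S / 2.0, S / 2.0, n_rays)
    z0 = np.full(n_rays, geometry.canopy_top_h + 1.0)
    mu = np.sqrt(rng.random(n_rays))  # cos(zenith), cosine-weighted
    phi = rng.uniform(0.0, 2.0 * np.pi, n_rays)
    sin_z = np.sqrt(1.0 - mu**2)
    dx = sin_z * np.sin(phi)
    dz = -mu
    t_hit = _first_block_hit_t(x0, z0, dx, dz, geometry)
    t_ground = (0.0 - z0) / dz
    return float(np.mean(t_hit < t_ground))


def mc_ground_to_canopy(geometry, n_rays: int, seed: int) -> float:
    """Fraction of Lambertian upwelling ground flux striking a canopy row."""
    rng = np.random.default_rng(seed)
    S = geometry.row_spacing
    x0 = rng.uniform(-S / 2.0, S / 2.0, n_rays)
    z0 = np.zeros(n_rays)
    mu = np.sqrt(rng.random(n_rays))
    phi = rng.uniform(0.0, 2.0 * np.pi, n_rays)
    sin_z = np.sqrt(1.0 - mu**2)
    dx = sin_z * np.sin(phi)
    dz = mu
    t_hit = _first_block_hit_t(x0, z0, dx, dz, geometry)
    return float(np.mean(np.isfinite(t_hit)))


def mc_wall_view_factors(geometry, n_rays: int, seed: int) -> dict:
    """View factors from a vertical canopy face by 2-D Monte-Carlo tracing.

    In 2-D (infinite rows) the diffuse direction density about the face
    normal is cos(theta)/2, sampled via theta = arcsin(2u - 1).
    """
    rng = np.random.default_rng(seed)
    za, zb = geometry.canopy_bottom_h, geometry.canopy_top_h
    # left wall of the block centred on x=0, outward normal -x
    x0 = np.full(n_rays, -geometry.canopy_width / 2.0 - 1e-9)
    z0 = rng.uniform(za, zb, n_rays)
    theta = np.arcsin(2.0 * rng.random(n_rays) - 1.0)
    dx = -np.cos(theta)
    dz = np.sin(theta)
    t_hit = _first_block_hit_t(x0, z0, dx, dz, geometry)
    with np.errstate(divide="ignore"):
        t_ground = np.where(dz < 0, -z0 / dz, np.inf)
    canopy = t_hit < t_ground
    ground = ~canopy & np.isfinite(t_ground)
    sky = ~canopy & ~ground
    n = float(n_rays)
    return {
        "sky": float(sky.sum() / n),
        "ground": float(ground.sum() / n),
        "adjacent": float(canopy.sum() / n),
    }


def solve_r_bs_numerically(e_c, r_c, d_c, r_bh, constants, lo=1e-6, hi=1e7):
    """Bracketed 1-D root solve of the forward flux equation for r_bs."""
    target = constants.lambda_v * e_c

    def residual(r_bs):
        return canopy_latent_heat(r_bs, r_c, d_c, r_bh, constants) - target

    return brentq(residual, lo, hi, xtol=1e-12, rtol=1e-14)
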