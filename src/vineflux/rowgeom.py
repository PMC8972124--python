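"""Geometric interception fractions for a rectangular hedgerow canopy.

All formulas for the 2-D (infinite-row) rectangular cross-section live here
so an alternative row-canopy parameterization can be swapped in behind the
same three quantities:

``beam_shadow_fraction``
    fraction of horizontal-plane beam flux intercepted by opaque rows;
``sky_interception_fraction``
    same for an isotropic diffuse sky (cosine-weighted hemisphere average
    of the beam fraction);
``ground_to_canopy_fraction``
    fraction of Lambertian upwelling flux from the ground that strikes a
    canopy row rather than escaping to the sky;
``wall_view_factors`` / ``face_view_factors``
    long-wave view factors from the canopy faces to {sky, ground,
    adjacent row}, closing to 1 on each face.

Porosity and albedo multipliers are applied by the caller; everything here
treats the canopy silhouette as opaque.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

__all__ = [
    "beam_shadow_fraction",
    "sky_interception_fraction",
    "ground_to_canopy_fraction",
    "face_view_factors",
]


def beam_shadow_fraction(elevation_deg, azimuth_deg, *, row_spacing, canopy_width,
                         wall_height, row_azimuth=0.0):
    """Shaded ground fraction cast by opaque rectangular rows.

    The shadow of one row has width W + H * cot(beta) * |sin(az - az_row)|
    on the cross-row axis; with rows repeating every S metres the shaded
    fraction is that width over S, capped at 1 (mutual shading).
    Zero when the sun is at or below the horizon.
    """
    beta = np.deg2rad(np.asarray(elevation_deg, dtype=float))
    up = beta > 0
    rel = np.deg2rad(np.asarray(azimuth_deg, dtype=float) - row_azimuth)
    with np.errstate(divide="ignore", invalid="ignore"):
        run = np.where(up, np.abs(np.sin(rel)) / np.tan(beta), 0.0)
    width = canopy_width + wall_height * run
    frac = np.where(up, np.minimum(1.0, width / row_spacing), 0.0)
    if np.isscalar(elevation_deg) and np.isscalar(azimuth_deg):
        return float(frac)
    return frac


def _quadrature(n_mu: int, n_phi: int):
    # Gauss-Legendre in mu = cos(zenith) on (0,1); uniform in azimuth.
    nodes, weights = np.polynomial.legendre.leggauss(n_mu)
    mu = 0.5 * (nodes + 1.0)
    w_mu = 0.5 * weights
    phi = (np.arange(n_phi) + 0.5) * (2.0 * math.pi / n_phi)
    w_phi = np.full(n_phi, 1.0 / n_phi)
    return mu, w_mu, phi, w_phi


@lru_cache(maxsize=64)
def _sky_fraction_cached(S, W, H, n_mu, n_phi):
    mu, w_mu, phi, w_phi = _quadrature(n_mu, n_phi)
    mu2 = mu[:, None]
    # run per unit rise resolved onto the cross-row axis
    run = np.sqrt(1.0 - mu2**2) / mu2 * np.abs(np.sin(phi[None, :]))
    frac = np.minimum(1.0, (W + H * run) / S)
    # flux-weighted hemisphere average: weight mu, normalized by 1/2
    return float((w_mu[:, None] * mu2 * frac * w_phi[None, :]).sum() * 2.0)


def sky_interception_fraction(geometry, n_mu: int = 48, n_phi: int = 96) -> float:
    """Fraction of isotropic diffuse sky flux intercepted by opaque rows.

    Cosine-weighted average of the beam shadow fraction over the sky dome;
    evaluated by Gauss quadrature in cos(zenith) and uniform azimuthal
    nodes.  Depends only on geometry, so the result is cached.
    """
    return _sky_fraction_cached(
        geometry.row_spacing, geometry.canopy_width, geometry.wall_height,
        n_mu, n_phi,
    )


def _hits_block(u0, length, S, W):
    # Does the cross-row interval [u0, u0+length] (mod S) touch a block
    # occupying [0, W] mod S?  Blocks repeat every S.
    u = np.mod(u0, S)
    return (u <= W) | (u + length >= S)


@lru_cache(maxsize=64)
def _ground_fraction_cached(S, W, z_b, z_t, n_x, n_mu, n_phi):
    mu, w_mu, phi, w_phi = _quadrature(n_mu, n_phi)
    x = (np.arange(n_x) + 0.5) * (S / n_x)  # ground points across one period
    run = np.sqrt(1.0 - mu**2) / mu  # horizontal run per unit rise
    # broadcast (x, mu, phi)
    r = run[None, :, None] * np.abs(np.sin(phi[None, None, :]))
    # cross-row sweep while the ray climbs through the canopy layer
    u0 = x[:, None, None] - W / 2.0 + r * z_b  # rows centred on x = W/2 mod S
    # sign of travel is symmetric; |sin| already folds it in
    length = r * (z_t - z_b)
    hit = _hits_block(u0, length, S, W)
    w = w_mu[None, :, None] * mu[None, :, None] * w_phi[None, None, :] * 2.0
    return float((hit * w).sum() / n_x)


def ground_to_canopy_fraction(geometry, n_x: int = 48, n_mu: int = 48,
                              n_phi: int = 96) -> float:
    """Fraction of Lambertian upwelling ground flux striking a canopy row.

    Averages, over ground positions across one row period and over the
    cosine-weighted upward hemisphere, whether the ray crosses a canopy
    rectangle (periodic slab test) before escaping above the canopy top.
    """
    return _ground_fraction_cached(
        geometry.row_spacing, geometry.canopy_width,
        geometry.canopy_bottom_h, geometry.canopy_top_h,
        n_x, n_mu, n_phi,
    )


@lru_cache(maxsize=64)
def _wall_vf_cached(S, W, z_b, z_t, n_z, n_theta):
    # View factors from one vertical canopy face, per the 2-D strip rule
    # (valid for infinitely long rows): radiance weight cos(theta)/2 over
    # the half-circle about the outward normal.
    gap = S - W  # clear distance to the adjacent row's facing wall
    z0 = z_b + (np.arange(n_z) + 0.5) * ((z_t - z_b) / n_z)
    nodes, weights = np.polynomial.legendre.leggauss(n_theta)
    theta = nodes * (math.pi / 2.0)  # angle from outward (horizontal) normal
    w = weights * (math.pi / 2.0) * np.cos(theta) / 2.0
    dz = np.sin(theta)[None, :]  # vertical component, + up
    dx = np.cos(theta)[None, :]  # outward component, always > 0
    z0c = z0[:, None]
    up_hit = (dz >= 0) & (z0c + gap * dz / dx <= z_t)
    down_hit = (dz < 0) & (z0c - gap * (-dz) / dx >= z_b)
    canopy = up_hit | down_hit
    sky = (dz > 0) & ~canopy
    ground = (dz <= 0) & ~canopy
    total = w.sum()  # = 1 up to quadrature rounding
    f = lambda mask: float((mask * w[None, :]).sum() / (n_z * total))
    return {"sky": f(sky), "ground": f(ground), "adjacent": f(canopy)}


def face_view_factors(geometry, n_z: int = 64, n_theta: int = 128) -> dict:
    """Long-wave view factors from each canopy face to sky/ground/adjacent row.

    Returns a dict keyed by face name ('wall' for either vertical face by
    symmetry, 'top') whose values map {'sky', 'ground', 'adjacent'} to view
    factors summing to 1.  With equal-height rows the top face sees only
    sky.
    """
    wall = _wall_vf_cached(
        geometry.row_spacing, geometry.canopy_width,
        geometry.canopy_bottom_h, geometry.canopy_top_h,
        n_z, n_theta,
    )
    top = {"sky": 1.0, "ground": 0.0, "adjacent": 0.0}
    return {"wall": wall, "top": top}
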