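"""A-priori observation-probability surface from a biweight kernel density.

Presence-only data carry no absences, so the model needs a prior belief
about where an observation could plausibly have been made.  Following the
standard point-pattern approach, the curated presences are smoothed with a
compactly supported quartic (biweight) kernel

    K_h(d) = 3 / (pi h^2) * (1 - d^2 / h^2)^2   for d <= h, else 0,

which integrates to 1 over the plane, and the resulting density surface is
rescaled by its maximum and clamped to [eps, 1 - eps] to give a per-cell
prior probability p* of an observation.  The max-normalisation is a
declared design choice: it is the simplest monotone map of a density onto
(0, 1), and the clamp keeps every Bernoulli(p*) likelihood term proper.

No edge correction is applied: kernels are simply truncated at the study
area boundary, and the normalisation by the maximum absorbs the overall
scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geodata import PointSet, RasterGrid, StudyArea


@dataclass
class PriorSurface:
    """Prior observation probability p* on a grid, with its provenance."""

    grid: RasterGrid
    bandwidth_km: float
    epsilon: float = 1e-3

    @property
    def p_star(self) -> np.ndarray:
        return self.grid.band("p_star")

    def sample_at(self, x, y) -> np.ndarray:
        return self.grid.sample("p_star", x, y)


def kde_density(points: PointSet, grid: RasterGrid, bandwidth_km: float) -> RasterGrid:
    """Biweight (quartic) kernel density of points, evaluated at cell centres.

    Returns a grid with a single band ``density``; each point's kernel
    integrates to 1, so the surface integral is ~n up to boundary
    truncation.
    """
    if points.n < 1:
        raise ValueError("kernel density requires at least one point")
    if bandwidth_km <= 0:
        raise ValueError("bandwidth must be positive")
    h = float(bandwidth_km)
    cx, cy = grid.cell_centers()
    flat_x = cx.ravel()
    flat_y = cy.ravel()
    density = np.zeros(flat_x.size, dtype=float)
    norm = 3.0 / (np.pi * h * h)
    # chunk over cells to bound memory on large grids
    chunk = max(1, int(2_000_000 / max(points.n, 1)))
    for start in range(0, flat_x.size, chunk):
        sl = slice(start, start + chunk)
        d2 = (flat_x[sl, None] - points.x[None, :]) ** 2 + (
            flat_y[sl, None] - points.y[None, :]
        ) ** 2
        u = 1.0 - d2 / (h * h)
        np.clip(u, 0.0, None, out=u)
        density[sl] = norm * np.sum(u * u * (u > 0), axis=1)
    out = grid.copy_geometry()
    dens = density.reshape(grid.shape)
    dens[grid.nodata_mask] = 0.0
    out.add_band("density", dens)
    return out


def density_to_prior(density: RasterGrid, epsilon: float = 1e-3, bandwidth_km: float = float("nan")) -> PriorSurface:
    """Rescale a density band by its maximum and clamp into [eps, 1 - eps]."""
    dens = np.asarray(density.band("density"), dtype=float)
    valid = ~density.nodata_mask
    peak = dens[valid].max() if valid.any() else 0.0
    if peak <= 0:
        raise ValueError("density is zero everywhere; prior undefined")
    p = np.clip(dens / peak, epsilon, 1.0 - epsilon)
    p[~valid] = np.nan
    out = density.copy_geometry()
    out.add_band("p_star", p)
    return PriorSurface(grid=out, bandwidth_km=bandwidth_km, epsilon=epsilon)


def choose_bandwidth(points: PointSet, area: StudyArea | None = None) -> float:
    """Normal-reference bandwidth: h = 1.06 * sigma_hat * n^(-1/5) (km).

    ``sigma_hat`` is the mean of the two axis-wise sample standard
    deviations (ddof=1) of the projected coordinates.  The study area is
    accepted for signature compatibility but unused; the rule depends only
    on the point spread.
    """
    if points.n < 2:
        raise ValueError("bandwidth selection requires at least two points")
    sx = float(np.std(points.x, ddof=1))
    sy = float(np.std(points.y, ddof=1))
    sigma = 0.5 * (sx + sy)
    if sigma <= 0:
        raise ValueError("all points identical; bandwidth undefined")
    return 1.06 * sigma * points.n ** (-0.2)


def build_prior(
    points: PointSet,
    grid: RasterGrid,
    bandwidth_km: float | None = None,
    epsilon: float = 1e-3,
) -> PriorSurface:
    """KDE -> max-normalised clamped prior, with an automatic bandwidth default."""
    if bandwidth_km is None:
        bandwidth_km = choose_bandwidth(points)
    dens = kde_density(points, grid, bandwidth_km)
    return density_to_prior(dens, epsilon=epsilon, bandwidth_km=bandwidth_km)
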