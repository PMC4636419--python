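"""Virtual study systems with known truth, for testing and calibration.

Everything the real pipeline consumes can be generated here: smooth
spatially autocorrelated covariate rasters, a virtual species whose
occurrence probability follows the spatially expanded logistic model with
*known* coefficients, presence-only records sampled with (optionally
biased) observer effort, matched-density background sites, and a layout of
small protected areas with presence reports drawn from the true occupancy.

The occupancy surface is computed through :func:`bselsdm.bsel_model.
linear_predictor` — the generator and the fitter share one definition of
the model, so drift between them is structurally impossible.  Every output
is reproducible bitwise from the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon

from . import bsel_model
from .background import LabeledSiteSet, assemble_sites, impute_labels, sample_background
from .bsel_model import BSELSpec
from .geodata import PointSet, RasterGrid, StudyArea
from .occurrence_prep import OccurrenceTable, from_xy
from .prior_surface import PriorSurface, build_prior


@dataclass
class SyntheticTruth:
    """True parameters behind a generated study system."""

    beta0: float
    deltas: dict[str, tuple[float, float, float]]  # name -> (d0, du, dv)
    correlation_km: float
    seed: int

    @property
    def active_covariates(self) -> list[str]:
        return [c for c, d in self.deltas.items() if any(abs(v) > 0 for v in d)]

    def spec(self, prior_sd: float = 10.0) -> BSELSpec:
        cov = tuple(self.deltas.keys())
        exp = tuple(c for c, d in self.deltas.items() if d[1] != 0 or d[2] != 0)
        return BSELSpec(covariates=cov, expanded=exp, prior_sd=prior_sd)

    def theta(self, spec: BSELSpec) -> np.ndarray:
        """Coefficient vector for ``spec``, zeros for terms truth lacks."""
        vals = {"beta0": self.beta0}
        for c, (d0, du, dv) in self.deltas.items():
            vals[f"{c}:d0"] = d0
            vals[f"{c}:du"] = du
            vals[f"{c}:dv"] = dv
        return np.array([vals.get(p, 0.0) for p in spec.param_names])


def make_covariates(
    n_rows: int,
    n_cols: int,
    n_bands: int = 3,
    correlation_km: float = 50.0,
    cell_size: float = 5.0,
    seed: int | None = None,
    band_prefix: str = "bio",
) -> RasterGrid:
    """Smooth mutually independent Gaussian random fields, z-scored over cells.

    Each band is white noise convolved with a Gaussian kernel whose sigma
    is ``correlation_km`` expressed in cells, then standardized to mean 0 /
    sd 1 over the grid, so bands are dimensionless and directly comparable.
    """
    if n_rows < 8 or n_cols < 8:
        raise ValueError("grid must be at least 8x8")
    rng = np.random.default_rng(seed)
    sigma_cells = correlation_km / cell_size
    grid = RasterGrid(
        origin_x=0.0,
        origin_y=n_rows * cell_size,
        cell_size=cell_size,
        n_rows=n_rows,
        n_cols=n_cols,
    )
    for b in range(n_bands):
        noise = rng.normal(size=(n_rows, n_cols))
        fld = ndimage.gaussian_filter(noise, sigma=sigma_cells, mode="wrap")
        fld = (fld - fld.mean()) / fld.std()
        grid.add_band(f"{band_prefix}{b + 1}", fld)
    return grid


def simulate_species(grid: RasterGrid, truth: SyntheticTruth) -> np.ndarray:
    """True occupancy probability band p(s) on the grid, from truth coefficients.

    Covariates and coordinates are standardized over grid cells exactly as
    the fitter standardizes them, and the probability is evaluated through
    the shared linear-predictor implementation.
    """
    from scipy.special import expit

    from .background import grid_standardization

    std = grid_standardization(grid)
    ok = ~grid.nodata_mask
    cx, cy = grid.cell_centers()
    u = (cx[ok] - std.coord_mean[0]) / std.coord_sd[0]
    v = (cy[ok] - std.coord_mean[1]) / std.coord_sd[1]
    covs = {
        c: (np.asarray(grid.band(c), dtype=float)[ok] - std.means[c]) / std.sds[c]
        for c in truth.deltas.keys()
    }
    spec = truth.spec()
    eta = bsel_model.linear_predictor(spec, truth.theta(spec), covs, u, v)
    band = np.full(grid.shape, np.nan)
    band[ok] = expit(eta)
    return band


def sample_presence_only(
    grid: RasterGrid,
    p_band: np.ndarray,
    n_target: int = 244,
    effort: np.ndarray | None = None,
    seed: int | None = None,
    jitter: bool = True,
) -> OccurrenceTable:
    """Presence-only records: cells drawn with intensity ∝ p x effort.

    ``n_target`` distinct cells are drawn without replacement (Gumbel
    top-k on the log-intensities), one record per cell, placed at the cell
    centre plus an optional sub-cell uniform jitter.  Uniform effort
    (default) reproduces the equal-sampling-intensity assumption behind
    the prior surface; a spatially varying effort emulates observer bias.
    """
    ok = ~grid.nodata_mask
    p = np.asarray(p_band, dtype=float)[ok]
    if effort is None:
        eff = np.ones_like(p)
    else:
        eff = np.asarray(effort, dtype=float)[ok]
        if np.any(eff < 0):
            raise ValueError("effort must be non-negative")
    intensity = p * eff
    if not np.any(intensity > 0):
        raise ValueError("sampling intensity is zero everywhere")
    if n_target > int((intensity > 0).sum()):
        raise ValueError("n_target exceeds the number of cells with positive intensity")
    rng = np.random.default_rng(seed)
    with np.errstate(divide="ignore"):
        logw = np.where(intensity > 0, np.log(intensity), -np.inf)
    gumbel = rng.gumbel(size=logw.size)
    chosen = np.argsort(logw + gumbel)[::-1][:n_target]

    cx, cy = grid.cell_centers()
    x = cx[ok][chosen]
    y = cy[ok][chosen]
    if jitter:
        half = 0.5 * grid.cell_size
        x = x + rng.uniform(-half, half, size=n_target)
        y = y + rng.uniform(-half, half, size=n_target)
    years = rng.integers(1950, 2013, size=n_target)
    dates = pd.to_datetime([f"{yr}-06-15" for yr in years])
    return from_xy(x, y, dates=dates, sources="synthetic")


def make_protected_areas(
    area: StudyArea,
    n_pa: int,
    grid: RasterGrid,
    p_band: np.ndarray,
    seed: int | None = None,
    size_km: tuple[float, float] = (8.0, 25.0),
) -> pd.DataFrame:
    """Random square protected areas with presence reports drawn from truth.

    ``reported_present`` is a Bernoulli draw from the maximum true
    occupancy probability over the cells inside each square, giving known
    ground truth for omission/commission checks.
    """
    import shapely

    if n_pa < 1:
        raise ValueError("n_pa must be >= 1")
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = area.bounds
    ok = ~grid.nodata_mask
    cx, cy = grid.cell_centers()
    cell_x, cell_y = cx[ok], cy[ok]
    p = np.asarray(p_band, dtype=float)[ok]
    rows = []
    while len(rows) < n_pa:
        half = 0.5 * rng.uniform(*size_km)
        gx = rng.uniform(x0 + half, x1 - half)
        gy = rng.uniform(y0 + half, y1 - half)
        poly = Polygon(
            [(gx - half, gy - half), (gx + half, gy - half), (gx + half, gy + half), (gx - half, gy + half)]
        )
        inside = shapely.intersects_xy(poly, cell_x, cell_y)
        if not inside.any():
            continue
        p_true = float(np.nanmax(p[inside]))
        rows.append(
            {
                "name": f"PA_{len(rows):03d}",
                "geometry": poly,
                "p_true": p_true,
                "reported_present": int(rng.random() < p_true),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class Scenario:
    """A complete generated study system plus everything the pipeline needs."""

    truth: SyntheticTruth
    grid: RasterGrid
    p_true: np.ndarray
    area: StudyArea
    occurrences: OccurrenceTable
    prior: PriorSurface
    sites: LabeledSiteSet
    pa_table: pd.DataFrame
    background_density: float
    metadata: dict = field(default_factory=dict)


def default_truth(seed: int = 0) -> SyntheticTruth:
    """One active covariate with a spatially varying effect; two inert ones."""
    return SyntheticTruth(
        beta0=-0.5,
        deltas={
            "bio1": (1.6, 0.5, -0.3),
            "bio2": (0.0, 0.0, 0.0),
            "bio3": (0.0, 0.0, 0.0),
        },
        correlation_km=50.0,
        seed=seed,
    )


def make_scenario(
    seed: int = 0,
    n_rows: int = 60,
    n_cols: int = 60,
    n_presences: int = 244,
    M: int = 10,
    truth: SyntheticTruth | None = None,
    background_density: float | None = None,
    bandwidth_km: float | None = None,
    effort: np.ndarray | None = None,
) -> Scenario:
    """Generate the flagship end-to-end recovery scenario.

    60x60 cells of 5 km, three covariate bands (one truly active, with a
    spatially varying effect), 244 presence records under uniform effort,
    background sites at the density of the observed records (the
    matched-density rule), and M = 10 label imputations from the KDE prior.
    All child seeds derive from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_cov, s_pres, s_bg, s_lab, s_pa = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
    )
    if truth is None:
        truth = default_truth(seed)
    grid = make_covariates(
        n_rows, n_cols, n_bands=len(truth.deltas),
        correlation_km=truth.correlation_km, seed=s_cov,
    )
    p_true = simulate_species(grid, truth)
    area = StudyArea.from_grid(grid)
    occ = sample_presence_only(grid, p_true, n_target=n_presences, effort=effort, seed=s_pres)
    pts = occ.kept_points()
    prior = build_prior(pts, grid, bandwidth_km=bandwidth_km)
    if background_density is None:
        # matched-density rule: background at the density of the observations
        background_density = pts.n / area.area_km2
    bg = sample_background(area, density_per_km2=background_density, seed=s_bg)
    bg_kept, labels, bg_pstar = impute_labels(bg, prior, M=M, seed=s_lab)
    sites = assemble_sites(occ, bg_kept, labels, bg_pstar, grid,
                           presence_p_star=prior.sample_at(pts.x, pts.y))
    pa_table = make_protected_areas(area, n_pa=20, grid=grid, p_band=p_true, seed=s_pa)
    return Scenario(
        truth=truth,
        grid=grid,
        p_true=p_true,
        area=area,
        occurrences=occ,
        prior=prior,
        sites=sites,
        pa_table=pa_table,
        background_density=background_density,
        metadata={
            "seed": seed,
            "n_presences": pts.n,
            "n_background": int((~sites.is_presence).sum()),
            "bandwidth_km": prior.bandwidth_km,
            "M": M,
        },
    )
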