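"""Pseudo-absence (background) sites and their label uncertainty.

Background sites stand in for the unvisited locations of a presence-only
study.  They are placed uniformly at random inside the study area at a
density matched to the observed records (~0.0004 per km2 in the motivating
dataset).  Because we do not actually know whether the species occurs
there, each background site's 0/1 label is *imputed* from the prior
surface: M independent label vectors are drawn with
label ~ Bernoulli(p*), the occurrence model is fitted to each, and the
posteriors are pooled as an equal-weight mixture.  This carries the
pseudo-absence uncertainty all the way into the parameter estimates.
Presence sites keep label 1 in every imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geodata import PointSet, RasterGrid, StudyArea
from .occurrence_prep import OccurrenceTable
from .prior_surface import PriorSurface


@dataclass
class Standardization:
    """Z-score constants computed over the study grid's non-nodata cells."""

    means: dict[str, float]
    sds: dict[str, float]
    coord_mean: tuple[float, float]
    coord_sd: tuple[float, float]
    zero_variance: list[str] = field(default_factory=list)


@dataclass
class LabeledSiteSet:
    """Presence + background sites, covariates and M imputed label vectors.

    ``labels`` has shape (M, n_sites); presence sites are 1 everywhere.
    ``u, v`` are the standardized easting/northing used by the spatial
    expansion; ``covariates`` holds standardized per-site covariate values.
    """

    x: np.ndarray
    y: np.ndarray
    site_kind: np.ndarray  # "presence" | "background"
    labels: np.ndarray  # (M, n)
    covariates: pd.DataFrame
    u: np.ndarray
    v: np.ndarray
    p_star: np.ndarray
    standardization: Standardization | None = None

    @property
    def n_sites(self) -> int:
        return self.x.size

    @property
    def n_imputations(self) -> int:
        return self.labels.shape[0]

    @property
    def is_presence(self) -> np.ndarray:
        return self.site_kind == "presence"

    def covariate_names(self) -> list[str]:
        return list(self.covariates.columns)

    def subset_labels(self, m: int) -> np.ndarray:
        return self.labels[m]


def sample_background(
    area: StudyArea,
    density_per_km2: float = 0.0004,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PointSet:
    """Uniform random background sites at a target density (rejection sampling).

    N = round(density * area_km2) points, drawn uniformly inside the
    polygon from its bounding box.  Deterministic given the seed.
    """
    if density_per_km2 <= 0:
        raise ValueError("density must be positive")
    n = int(round(density_per_km2 * area.area_km2))
    if n == 0:
        raise ValueError(
            f"target density {density_per_km2}/km2 over {area.area_km2:.0f} km2 "
            "yields zero background sites"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = area.bounds
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    got = 0
    while got < n:
        m = max(2 * (n - got), 16)
        cand_x = rng.uniform(x0, x1, size=m)
        cand_y = rng.uniform(y0, y1, size=m)
        ok = area.contains_points(cand_x, cand_y)
        xs.append(cand_x[ok])
        ys.append(cand_y[ok])
        got += int(ok.sum())
    x = np.concatenate(xs)[:n]
    y = np.concatenate(ys)[:n]
    return PointSet(x=x, y=y)


def impute_labels(
    background: PointSet,
    prior: PriorSurface,
    M: int = 10,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PointSet, np.ndarray, np.ndarray]:
    """Draw M independent Bernoulli(p*) label vectors for background sites.

    Sites falling on nodata prior cells are dropped with a warning.
    Returns (kept sites, labels of shape (M, n_kept), p* at kept sites).
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    p = prior.sample_at(background.x, background.y)
    ok = np.isfinite(p)
    if not ok.all():
        import warnings

        warnings.warn(
            f"dropped {int((~ok).sum())} background sites on nodata prior cells",
            stacklevel=2,
        )
    sites = PointSet(x=background.x[ok], y=background.y[ok])
    p = p[ok]
    if rng is None:
        rng = np.random.default_rng(seed)
    labels = (rng.random((M, sites.n)) < p[None, :]).astype(np.int8)
    return sites, labels, p


def grid_standardization(covars: RasterGrid, names: list[str] | None = None) -> Standardization:
    """Z-score constants over non-nodata cells, flagging zero-variance bands."""
    if names is None:
        names = list(covars.bands.keys())
    valid = ~covars.nodata_mask
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    zero_var: list[str] = []
    for name in names:
        vals = np.asarray(covars.band(name), dtype=float)[valid]
        mu = float(vals.mean())
        sd = float(vals.std())
        means[name] = mu
        sds[name] = sd
        if sd <= 1e-12:
            zero_var.append(name)
    cx, cy = covars.cell_centers()
    ux = cx[valid]
    vy = cy[valid]
    return Standardization(
        means=means,
        sds=sds,
        coord_mean=(float(ux.mean()), float(vy.mean())),
        coord_sd=(float(ux.std()), float(vy.std())),
        zero_variance=zero_var,
    )


def assemble_sites(
    presences: OccurrenceTable | PointSet,
    background_sites: PointSet,
    background_labels: np.ndarray,
    background_p_star: np.ndarray,
    covars: RasterGrid,
    presence_p_star: np.ndarray | None = None,
) -> LabeledSiteSet:
    """Fuse presences and background into one standardized modelling table.

    Covariates are sampled at each site by nearest-cell lookup, then
    z-scored using statistics over the study grid's cells (recorded in the
    result); zero-variance bands are excluded from the candidate set.
    Coordinates are standardized the same way into (u, v) for the spatial
    expansion.  Sites on nodata covariate cells are dropped with a warning.
    """
    import warnings

    if isinstance(presences, OccurrenceTable):
        pres = presences.kept_points()
    else:
        pres = presences
    std = grid_standardization(covars)
    names = [n for n in covars.bands.keys() if n not in std.zero_variance]
    if std.zero_variance:
        warnings.warn(
            f"zero-variance covariates excluded: {std.zero_variance}", stacklevel=2
        )

    x = np.concatenate([pres.x, background_sites.x])
    y = np.concatenate([pres.y, background_sites.y])
    kind = np.array(["presence"] * pres.n + ["background"] * background_sites.n)
    M = background_labels.shape[0]
    labels = np.concatenate(
        [np.ones((M, pres.n), dtype=np.int8), background_labels.astype(np.int8)], axis=1
    )
    if presence_p_star is None:
        presence_p_star = np.ones(pres.n)
    p_star = np.concatenate([np.asarray(presence_p_star, dtype=float), background_p_star])

    cov = {}
    ok = np.ones(x.size, dtype=bool)
    for name in names:
        vals = covars.sample(name, x, y)
        ok &= np.isfinite(vals)
        cov[name] = vals
    if not ok.all():
        warnings.warn(
            f"dropped {int((~ok).sum())} sites on nodata covariate cells", stacklevel=2
        )
    covariates = pd.DataFrame(
        {n: (cov[n][ok] - std.means[n]) / std.sds[n] for n in names}
    )
    u = (x[ok] - std.coord_mean[0]) / std.coord_sd[0]
    v = (y[ok] - std.coord_mean[1]) / std.coord_sd[1]
    return LabeledSiteSet(
        x=x[ok],
        y=y[ok],
        site_kind=kind[ok],
        labels=labels[:, ok],
        covariates=covariates,
        u=u,
        v=v,
        p_star=p_star[ok],
        standardization=std,
    )
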