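"""Prediction surfaces, AUC evaluation, thresholds and protected-area checks.

The fitted model is pushed over the covariate grid to produce per-cell
posterior summaries of occurrence probability: the histogram mode (the
map usually shown), the median and the 2.5% / 97.5% quantiles, whose
difference — the length of the 95% credible interval — is the per-cell
uncertainty measure, 0 meaning precise and 1 maximally imprecise.

Evaluation offers two AUC readings (both reconstructions, since AUC needs
binary labels): presence-vs-background discrimination of the median map,
and a contrast against the prior surface in which labels are repeatedly
drawn per cell from Bernoulli(p*).  Threshold reports describe where the
map's uncertainty sits relative to candidate presence thresholds
(t = 0.4 / 0.5 / 0.6), and the protected-area validation classifies each
area as omission / commission / agreement against reported presence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .background import LabeledSiteSet
from .bsel_model import BSELSpec, PosteriorFit, _bernoulli_loglik, design_matrix, histogram_mode
from .geodata import RasterGrid
from .prior_surface import PriorSurface


@dataclass
class PredictionRaster:
    """Posterior occurrence-probability summaries on the analysis grid."""

    grid: RasterGrid  # bands: p_mode, p_median, p_lo025, p_hi975, ci_length

    def band(self, name: str) -> np.ndarray:
        return self.grid.band(name)

    def check_invariants(self) -> None:
        ok = ~self.grid.nodata_mask
        for name in ("p_mode", "p_median", "p_lo025", "p_hi975", "ci_length"):
            vals = self.grid.band(name)[ok]
            assert np.all((vals >= 0) & (vals <= 1)), f"band {name} outside [0,1]"
        lo = self.grid.band("p_lo025")[ok]
        md = self.grid.band("p_median")[ok]
        hi = self.grid.band("p_hi975")[ok]
        assert np.all(lo <= md + 1e-12) and np.all(md <= hi + 1e-12)
        assert np.allclose(self.grid.band("ci_length")[ok], hi - lo)


def predict_surface(
    fit: PosteriorFit,
    grid: RasterGrid,
    standardization,
    spec: BSELSpec | None = None,
    max_draws: int = 2000,
    seed: int | None = None,
) -> PredictionRaster:
    """Per-cell posterior of p over the covariate grid.

    Pooled draws are thinned to at most ``max_draws`` (evenly, after a
    seeded offset) for tractability; quantiles are empirical, the mode is
    the 100-bin histogram mode.
    """
    from scipy.special import expit

    if spec is None:
        spec = fit.spec
    for c in spec.covariates:
        if c not in grid.bands:
            raise KeyError(f"grid lacks covariate band {c!r}")
    pooled = fit.pooled()
    n_draws = pooled.shape[0]
    if n_draws > max_draws:
        rng = np.random.default_rng(seed)
        stride = n_draws / max_draws
        offset = rng.integers(0, max(int(stride), 1))
        idx = (offset + np.arange(max_draws) * stride).astype(int) % n_draws
        pooled = pooled[idx]

    ok = ~grid.nodata_mask
    cx, cy = grid.cell_centers()
    mu_x, mu_y = standardization.coord_mean
    sd_x, sd_y = standardization.coord_sd
    u = (cx[ok] - mu_x) / sd_x
    v = (cy[ok] - mu_y) / sd_y
    covs = {
        c: (np.asarray(grid.band(c), dtype=float)[ok] - standardization.means[c])
        / standardization.sds[c]
        for c in spec.covariates
    }
    Z = design_matrix(spec, covs, u, v)

    n_cells = Z.shape[0]
    p_mode = np.empty(n_cells)
    quants = np.empty((3, n_cells))
    chunk = max(1, int(4_000_000 // max(pooled.shape[0], 1)))
    for s in range(0, n_cells, chunk):
        sl = slice(s, min(s + chunk, n_cells))
        p = expit(pooled @ Z[sl].T)  # (draws, cells)
        quants[:, sl] = np.quantile(p, [0.025, 0.5, 0.975], axis=0)
        for j in range(sl.start, sl.stop):
            p_mode[j] = histogram_mode(p[:, j - sl.start])

    out = grid.copy_geometry()
    full = np.full(grid.shape, np.nan)
    for name, vals in [
        ("p_mode", p_mode),
        ("p_lo025", quants[0]),
        ("p_median", quants[1]),
        ("p_hi975", quants[2]),
        ("ci_length", quants[2] - quants[0]),
    ]:
        band = full.copy()
        band[ok] = vals
        out.add_band(name, band)
    pred = PredictionRaster(grid=out)
    pred.check_invariants()
    return pred


def compute_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney statistic with the standard 1/2 tie credit."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC needs both classes present")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def presence_background_auc(pred: PredictionRaster, sites: LabeledSiteSet) -> float:
    """AUC of the median map scoring presences against background sites."""
    scores = pred.grid.sample("p_median", sites.x, sites.y)
    ok = np.isfinite(scores)
    labels = sites.is_presence.astype(int)
    return compute_auc(scores[ok], labels[ok])


def auc_prior_contrast(
    pred: PredictionRaster,
    prior: PriorSurface,
    K: int = 100,
    seed: int | None = None,
) -> tuple[float, float, int]:
    """Mean +/- sd AUC of the median map against Bernoulli(p*) cell labels.

    Draws one label per grid cell from the prior surface, K times; draws
    yielding a single class are skipped and the effective K reported.
    """
    if not pred.grid.geometry_matches(prior.grid):
        raise ValueError("prediction and prior grids are not aligned")
    ok = ~pred.grid.nodata_mask & ~prior.grid.nodata_mask
    scores = pred.grid.band("p_median")[ok]
    p_star = prior.p_star[ok]
    rng = np.random.default_rng(seed)
    aucs = []
    for _ in range(K):
        labels = (rng.random(p_star.size) < p_star).astype(int)
        if labels.min() == labels.max():
            continue
        aucs.append(compute_auc(scores, labels))
    if not aucs:
        raise ValueError("no valid label draws (prior surface degenerate)")
    a = np.asarray(aucs)
    return float(a.mean()), float(a.std()), len(aucs)


def threshold_report(
    pred: PredictionRaster, thresholds=(0.4, 0.5, 0.6)
) -> pd.DataFrame:
    """Cell counts and uncertainty on each side of candidate thresholds.

    Per threshold t: how many cells are predicted present (p_mode >= t) /
    absent, and the mean / max CI length on each side, plus the fraction of
    cells on each side with CI length > 0.5 ("high uncertainty").
    """
    ok = ~pred.grid.nodata_mask
    p = pred.grid.band("p_mode")[ok]
    ci = pred.grid.band("ci_length")[ok]
    rows = []
    for t in thresholds:
        above = p >= t
        for side, mask in (("present", above), ("absent", ~above)):
            n = int(mask.sum())
            rows.append(
                {
                    "threshold": t,
                    "side": side,
                    "n_cells": n,
                    "fraction": n / p.size,
                    "mean_ci_length": float(ci[mask].mean()) if n else np.nan,
                    "max_ci_length": float(ci[mask].max()) if n else np.nan,
                    "frac_ci_gt_0.5": float((ci[mask] > 0.5).mean()) if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def validate_protected_areas(
    pred: PredictionRaster, pa_table: pd.DataFrame, t: float = 0.5
) -> pd.DataFrame:
    """Classify each protected area as omission / commission / agreement.

    ``pa_table`` needs columns ``name, reported_present`` and either a
    ``geometry`` column of shapely polygons or ``x, y`` centroids.  The
    area's predicted probability is the max of cell ``p_median`` over cells
    whose centres fall inside the polygon (nearest cell for centroids); the
    mean is also emitted for transparency.  Areas outside the grid are
    flagged and excluded from the summary counts.
    """
    import shapely

    grid = pred.grid
    ok = ~grid.nodata_mask
    cx, cy = grid.cell_centers()
    cell_x, cell_y = cx[ok], cy[ok]
    pmed = grid.band("p_median")[ok]
    rows = []
    for _, rec in pa_table.iterrows():
        if "geometry" in pa_table.columns and rec["geometry"] is not None:
            inside = shapely.intersects_xy(rec["geometry"], cell_x, cell_y)
            if not inside.any():
                # fall back to the nearest cell to the polygon centroid
                cen = rec["geometry"].centroid
                d = np.hypot(cell_x - cen.x, cell_y - cen.y)
                inside = d == d.min()
        else:
            d = np.hypot(cell_x - rec["x"], cell_y - rec["y"])
            inside = d == d.min()
        vals = pmed[inside]
        if vals.size == 0 or not np.isfinite(vals).any():
            rows.append(
                {
                    "name": rec["name"],
                    "reported_present": int(rec["reported_present"]),
                    "predicted_p": np.nan,
                    "predicted_p_mean": np.nan,
                    "classification": "outside_grid",
                }
            )
            continue
        p_max = float(np.nanmax(vals))
        reported = int(rec["reported_present"])
        predicted_present = p_max >= t
        if reported == 1 and not predicted_present:
            cls = "omission"
        elif reported == 0 and predicted_present:
            cls = "commission"
        else:
            cls = "agreement"
        rows.append(
            {
                "name": rec["name"],
                "reported_present": reported,
                "predicted_p": p_max,
                "predicted_p_mean": float(np.nanmean(vals)),
                "classification": cls,
            }
        )
    return pd.DataFrame(rows)


def pa_summary_counts(validation: pd.DataFrame) -> dict[str, int]:
    counted = validation[validation["classification"] != "outside_grid"]
    return {
        "omission": int((counted["classification"] == "omission").sum()),
        "commission": int((counted["classification"] == "commission").sum()),
        "agreement": int((counted["classification"] == "agreement").sum()),
        "excluded": int((validation["classification"] == "outside_grid").sum()),
    }
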