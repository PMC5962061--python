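"""Prediction grid, abundance surfaces and delta-method uncertainty.

The fitted density model is evaluated over a regular grid of equal-area
cells (1.96 km^2 by default, matching the segment size) covering the
study landscape; cells at >= 95 % forest cover are excluded, mirroring
the segment rule. Per-cell expected abundance is exp(eta_c) * area, the
total is the sum over retained cells, and coefficient uncertainty is
propagated by the delta method on the log link (with an optional
posterior-simulation cross-check).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from .gam import FittedDSM
from .segments import FOREST_EXCLUSION
from .synthetic import Landscape

__all__ = [
    "PredictionGrid", "AbundanceSurface", "build_grid", "predict_cells",
    "total_abundance", "uncertainty",
]


@dataclass
class _Cell:
    id: str
    x: float
    y: float
    half: float

    @property
    def strip(self):
        return box(self.x - self.half, self.y - self.half,
                   self.x + self.half, self.y + self.half)

    @property
    def centroid(self):
        return (self.x, self.y)


@dataclass
class PredictionGrid:
    """Exclusion-filtered tessellation of the study area.

    ``cells`` has one row per grid cell: id, centroid x/y (m), area (km^2),
    elevation (m), dist_coast (m), forest fraction and the excluded flag.
    """

    cells: pd.DataFrame
    cell_area_km2: float
    n_total: int
    n_excluded: int

    @property
    def n_retained(self) -> int:
        return self.n_total - self.n_excluded

    @property
    def retained(self) -> pd.DataFrame:
        return self.cells.loc[~self.cells["excluded"]].reset_index(drop=True)


@dataclass
class AbundanceSurface:
    """Per-cell expected abundance and CV plus seasonal totals."""

    cells: pd.DataFrame          # id, x, y, area, Nhat, cv, extrapolated
    season: str = ""

    @property
    def total(self) -> float:
        return float(self.cells["Nhat"].sum())

    @property
    def area_km2(self) -> float:
        return float(self.cells["area"].sum())

    @property
    def mean_density(self) -> float:
        """Individuals per km^2 over the retained cells."""
        return self.total / self.area_km2


def build_grid(landscape: Landscape, cell_area_km2: float = 1.96,
               forest_threshold: float = FOREST_EXCLUSION) -> PredictionGrid:
    """Tile the landscape with equal-area square cells and summarize
    covariates per cell exactly as for segments.

    The grid is anchored at the landscape origin; partial edge cells are
    dropped so every cell has the configured area. Cells at or above the
    forest threshold are flagged excluded. Raises when the cell does not
    fit in the extent or when every cell is excluded.
    """
    if cell_area_km2 <= 0:
        raise ValueError("cell area must be positive")
    side = np.sqrt(cell_area_km2) * 1000.0
    x0, y0, x1, y1 = landscape.extent
    ncx = int(np.floor((x1 - x0) / side + 1e-9))
    ncy = int(np.floor((y1 - y0) / side + 1e-9))
    if ncx < 1 or ncy < 1:
        raise ValueError("cell area larger than the landscape extent")

    # fast path: grid aligned with the raster -> exact block averaging
    rows = []
    half = side / 2.0
    from .segments import summarize_covariates
    for iy in range(ncy):
        for ix in range(ncx):
            cx = x0 + (ix + 0.5) * side
            cy = y0 + (iy + 0.5) * side
            cell = _Cell(id=f"c{iy}-{ix}", x=cx, y=cy, half=half)
            w, elev, forest = landscape.weighted_values(cell.strip)
            d = landscape.distance_to_coast(np.array([[cx, cy]]))[0]
            rows.append({
                "id": cell.id, "x": cx, "y": cy, "area": cell_area_km2,
                "elevation": elev, "dist_coast": d, "forest": forest,
                "excluded": bool(forest >= forest_threshold),
            })
    cells = pd.DataFrame(rows)
    n_excl = int(cells["excluded"].sum())
    if n_excl == len(cells):
        raise ValueError("every grid cell is excluded by the forest rule")
    return PredictionGrid(cells=cells, cell_area_km2=cell_area_km2,
                          n_total=len(cells), n_excluded=n_excl)


def predict_cells(fit: FittedDSM, grid: PredictionGrid,
                  season: str = "") -> AbundanceSurface:
    """Expected abundance per retained cell: exp(linear predictor) * area.

    The model's offset convention (log effort area, km^2) makes the linear
    predictor a log density per km^2, so the per-cell abundance is density
    times cell area. Cells whose covariates fall outside the fitted range
    are flagged ``extrapolated`` (reported, never censored).
    """
    ret = grid.retained
    if len(ret) == 0:
        raise ValueError("no retained cells to predict on")
    needed = {c for t in fit.spec.terms for c in t.covariates}
    missing = needed - set(ret.columns)
    if missing:
        raise KeyError(f"grid lacks covariates required by the model: {sorted(missing)}")
    eta = fit.linear_predictor(ret)
    dens = np.exp(eta)
    cells = ret[["id", "x", "y", "area"]].copy()
    cells["Nhat"] = dens * ret["area"].to_numpy()
    cells["cv"] = np.nan
    cells["extrapolated"] = fit.extrapolation_mask(ret)
    return AbundanceSurface(cells=cells, season=season)


def total_abundance(surface: AbundanceSurface) -> tuple[float, float]:
    """Total abundance and mean density (individuals / km^2) over the
    retained cells."""
    if len(surface.cells) == 0:
        raise ValueError("empty abundance surface")
    return surface.total, surface.mean_density


def uncertainty(fit: FittedDSM, grid: PredictionGrid,
                surface: AbundanceSurface | None = None,
                method: str = "delta", n_draws: int = 10_000,
                seed: int = 0, season: str = "") -> AbundanceSurface:
    """Per-cell and total coefficient of variation of the abundance surface.

    ``delta``: on the log link, Var(Nhat_c) = Nhat_c^2 x_c' V x_c with V
    the conditional coefficient covariance, and the total variance is
    a' Xp V Xp' a with a the per-cell abundances (full covariance between
    cells retained). ``posterior-sim``: coefficients are drawn from
    N(beta, V) with a fixed seed and empirical CVs reported.

    Returns a surface whose ``cells.cv`` column is filled and with
    ``total_cv`` stored in ``cells.attrs`` (also returned via
    :func:`summarize_uncertainty`).
    """
    V = np.asarray(fit.Vb)
    ev_min = float(np.linalg.eigvalsh(0.5 * (V + V.T)).min())
    if ev_min < -1e-8 * max(np.abs(V).max(), 1e-300):
        raise np.linalg.LinAlgError("coefficient covariance is not PSD")
    if surface is None:
        surface = predict_cells(fit, grid, season=season)
    ret = grid.retained
    Xp = fit.design(ret)
    a = surface.cells["Nhat"].to_numpy()

    if method == "delta":
        var_eta = np.einsum("ij,jk,ik->i", Xp, V, Xp)
        cv_cells = np.sqrt(np.maximum(var_eta, 0.0))  # CV of lognormal-ish: sd(eta)
        total_var = float(a @ (Xp @ V @ Xp.T) @ a)
        total_cv = np.sqrt(max(total_var, 0.0)) / surface.total
    elif method == "posterior-sim":
        rng = np.random.default_rng(seed)
        Vs = 0.5 * (V + V.T) + 1e-12 * np.eye(V.shape[0])
        L = np.linalg.cholesky(Vs)
        draws = fit.beta[None, :] + rng.standard_normal((n_draws, V.shape[0])) @ L.T
        eta = draws @ Xp.T  # (n_draws, n_cells)
        area = ret["area"].to_numpy()
        N = np.exp(eta) * area[None, :]
        cv_cells = N.std(axis=0, ddof=1) / N.mean(axis=0)
        tot = N.sum(axis=1)
        total_cv = float(tot.std(ddof=1) / tot.mean())
    else:
        raise ValueError("method must be 'delta' or 'posterior-sim'")

    out = surface.cells.copy()
    out["cv"] = cv_cells
    res = AbundanceSurface(cells=out, season=surface.season)
    res.cells.attrs["total_cv"] = float(total_cv)
    return res


def total_cv(surface: AbundanceSurface) -> float:
    """Total-abundance CV attached by :func:`uncertainty`."""
    return float(surface.cells.attrs["total_cv"])
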