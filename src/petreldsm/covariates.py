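"""Environmental covariate engineering for the density surface models.

Per-cell covariates: Euclidean distances to the coastline and to the
500 m isobath (continental-shelf-edge proxy), seabed depth (clamped to
<= 0 where a cell centre sits over land artefacts), Horn-style gradient
magnitudes of depth and of the dynamic fields (chl-a, SST, SSS), a
land-avoiding colony proximity score (breeding pairs / squared over-sea
distance, summed over colonies), 8-day temporal compositing, inverse-
distance-weighted appending of scattered values, and Box-Cox transforms
whose lambda / shift are persisted so exactly the same transform is
re-applied on the prediction grid.

Grids are numpy arrays of shape (ny, nx) indexed [iy, ix]; land is NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from scipy.stats import boxcox_llf, skew

from .nbgam import _golden_min


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def distance_to_set(points: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Euclidean distance (km) from each point to the nearest target point."""
    target = np.atleast_2d(np.asarray(target, dtype=float))
    if target.size == 0:
        raise ValueError("empty target set")
    d, _ = cKDTree(target).query(np.atleast_2d(np.asarray(points, dtype=float)))
    return d


def boundary_points(land_mask: np.ndarray, grid) -> np.ndarray:
    """Midpoints of cell edges separating land from sea (the coastline)."""
    land = np.asarray(land_mask, dtype=bool)
    pts = []
    ny, nx = land.shape
    cx = grid.x0 + (np.arange(nx) + 0.5) * grid.cell_km
    cy = grid.y0 + (np.arange(ny) + 0.5) * grid.cell_km
    h = grid.cell_km / 2.0
    vert = land[:, :-1] ^ land[:, 1:]           # boundary between ix and ix+1
    for iy, ix in zip(*np.nonzero(vert)):
        pts.append((cx[ix] + h, cy[iy]))
    horiz = land[:-1, :] ^ land[1:, :]
    for iy, ix in zip(*np.nonzero(horiz)):
        pts.append((cx[ix], cy[iy] + h))
    return np.array(pts, dtype=float).reshape(-1, 2)


def contour_points(field: np.ndarray, level: float, grid) -> np.ndarray:
    """Cell-edge midpoints where ``field`` crosses ``level`` (e.g. -500 m)."""
    f = np.asarray(field, dtype=float)
    below = f < level
    valid = np.isfinite(f)
    pts = []
    ny, nx = f.shape
    cx = grid.x0 + (np.arange(nx) + 0.5) * grid.cell_km
    cy = grid.y0 + (np.arange(ny) + 0.5) * grid.cell_km
    h = grid.cell_km / 2.0
    cross_v = (below[:, :-1] ^ below[:, 1:]) & valid[:, :-1] & valid[:, 1:]
    for iy, ix in zip(*np.nonzero(cross_v)):
        pts.append((cx[ix] + h, cy[iy]))
    cross_h = (below[:-1, :] ^ below[1:, :]) & valid[:-1, :] & valid[1:, :]
    for iy, ix in zip(*np.nonzero(cross_h)):
        pts.append((cx[ix], cy[iy] + h))
    return np.array(pts, dtype=float).reshape(-1, 2)


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------


def terrain_gradient(field: np.ndarray, cell_km: float) -> np.ndarray:
    """Gradient magnitude per cell (field units per km), Horn's 3x3 method.

    Edge cells are handled by replicate padding (effectively one-sided
    differences).  Missing (NaN) cells are filled from their nearest valid
    neighbour before differencing and re-masked afterwards, so coastal sea
    cells keep a finite gradient while land stays missing.
    """
    f = np.asarray(field, dtype=float)
    mask = ~np.isfinite(f)
    if mask.all():
        return np.full_like(f, np.nan)
    if mask.any():
        idx = ndimage.distance_transform_edt(mask, return_distances=False,
                                             return_indices=True)
        f = f[tuple(idx)]
    z = np.pad(f, 1, mode="edge")
    gx = ((z[:-2, 2:] + 2 * z[1:-1, 2:] + z[2:, 2:])
          - (z[:-2, :-2] + 2 * z[1:-1, :-2] + z[2:, :-2])) / (8.0 * cell_km)
    gy = ((z[2:, :-2] + 2 * z[2:, 1:-1] + z[2:, 2:])
          - (z[:-2, :-2] + 2 * z[:-2, 1:-1] + z[:-2, 2:])) / (8.0 * cell_km)
    g = np.hypot(gx, gy)
    g[mask] = np.nan
    return g


def slope_degrees(depth_m: np.ndarray, cell_km: float) -> np.ndarray:
    """Seabed slope in degrees from the depth grid (metres, negative down)."""
    g = terrain_gradient(depth_m, cell_km)  # m per km
    return np.degrees(np.arctan(g / 1000.0))


# ---------------------------------------------------------------------------
# interpolation and temporal matching
# ---------------------------------------------------------------------------


def idw_append(points: np.ndarray, values: np.ndarray, query: np.ndarray,
               power: float = 2.0, max_radius: float | None = None) -> np.ndarray:
    """Inverse-distance-weighted interpolation of scattered values.

    An exact hit (distance < 1e-9) returns the source value; queries with
    no source inside ``max_radius`` come back as NaN.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    values = np.asarray(values, dtype=float)
    query = np.atleast_2d(np.asarray(query, dtype=float))
    if points.shape[0] == 0:
        raise ValueError("need at least one source point")
    d = np.sqrt(((query[:, None, :] - points[None, :, :]) ** 2).sum(axis=2))
    out = np.empty(query.shape[0])
    for i in range(query.shape[0]):
        di = d[i]
        if max_radius is not None:
            keep = di <= max_radius
            if not keep.any():
                out[i] = np.nan
                continue
        else:
            keep = np.ones_like(di, dtype=bool)
        hit = di < 1e-9
        if hit.any():
            out[i] = values[np.argmax(hit)]
        else:
            w = di[keep] ** (-power)
            out[i] = float(w @ values[keep] / w.sum())
    return out


def composite_window(julian_day: int) -> tuple[int, int]:
    """The 8-day composite window [8k+1, 8k+8] containing ``julian_day``."""
    if not 1 <= julian_day <= 366:
        raise ValueError("julian_day outside 1..366")
    k = (julian_day - 1) // 8
    return 8 * k + 1, 8 * k + 8


def temporal_match(layers: dict[int, np.ndarray], julian_day: int) -> np.ndarray:
    """The 8-day composite layer (keyed by window start day) covering a day."""
    start, _ = composite_window(julian_day)
    if start not in layers:
        raise KeyError(f"no composite layer starting at day {start}")
    return layers[start]


def eight_day_mean(daily_layers: dict[int, np.ndarray], julian_day: int) -> np.ndarray:
    """Mean of the 8 daily layers in the composite window (used for SSS)."""
    start, end = composite_window(julian_day)
    missing = [d for d in range(start, end + 1) if d not in daily_layers]
    if missing:
        raise KeyError(f"daily layers missing for days {missing}")
    return np.mean([daily_layers[d] for d in range(start, end + 1)], axis=0)


# ---------------------------------------------------------------------------
# colony proximity score
# ---------------------------------------------------------------------------


def sea_distance(land_mask: np.ndarray, source_cell: tuple[int, int],
                 cell_km: float) -> np.ndarray:
    """Least-cost over-sea path length (km) from one sea cell to every cell.

    8-connected cell graph; orthogonal steps cost ``cell_km``, diagonal
    steps ``cell_km * sqrt(2)``.  Land cells are impassable (NaN);
    unreachable sea cells (enclosed basins) come back infinite.
    """
    land = np.asarray(land_mask, dtype=bool)
    ny, nx = land.shape
    sea_idx = np.flatnonzero(~land.ravel())
    pos = -np.ones(ny * nx, dtype=int)
    pos[sea_idx] = np.arange(sea_idx.size)
    iy, ix = np.unravel_index(sea_idx, (ny, nx))
    rows, cols, wts = [], [], []
    for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
        jy, jx = iy + dy, ix + dx
        ok = (jy >= 0) & (jy < ny) & (jx >= 0) & (jx < nx)
        nb = np.full(sea_idx.size, -1, dtype=int)
        nb[ok] = pos[jy[ok] * nx + jx[ok]]
        ok &= nb >= 0
        w = cell_km * (np.sqrt(2.0) if dx and dy else 1.0)
        rows.append(np.arange(sea_idx.size)[ok])
        cols.append(nb[ok])
        wts.append(np.full(ok.sum(), w))
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    w = np.concatenate(wts)
    g = coo_matrix((np.concatenate([w, w]), (np.concatenate([r, c]),
                                             np.concatenate([c, r]))),
                   shape=(sea_idx.size, sea_idx.size)).tocsr()
    sy, sx = source_cell[1], source_cell[0]
    if land[sy, sx]:
        raise ValueError("source cell is on land")
    src = pos[sy * nx + sx]
    d = dijkstra(g, indices=src, directed=False)
    out = np.full(ny * nx, np.nan)
    out[sea_idx] = d
    return out.reshape(ny, nx)


def snap_to_sea(land_mask: np.ndarray, grid, location) -> tuple[int, int]:
    """Nearest sea cell (ix, iy) to a colony location by centre distance."""
    land = np.asarray(land_mask, dtype=bool)
    c = grid.centres()
    sea = c[~land[c["iy"], c["ix"]]]
    d2 = (sea["x"] - location[0]) ** 2 + (sea["y"] - location[1]) ** 2
    row = sea.loc[d2.idxmin()]
    return int(row["ix"]), int(row["iy"])


def colony_proximity_score(grid, colonies: pd.DataFrame,
                           land_mask: np.ndarray) -> np.ndarray:
    """Sum over colonies of breeding pairs / max(d, d_min)^2 (pairs km^-2).

    ``d`` is the land-avoiding over-sea distance from each sea-cell centre
    to the colony's snapped sea cell; ``d_min = cell_km / 2`` guards the
    colony's own cell.  Unreachable cells get no contribution from that
    colony (logged).  Land cells are NaN.
    """
    land = np.asarray(land_mask, dtype=bool)
    d_min = grid.cell_km / 2.0
    score = np.zeros(land.shape)
    for col in colonies.itertuples():
        src = snap_to_sea(land_mask, grid, (col.x, col.y))
        d = sea_distance(land_mask, src, grid.cell_km)
        unreachable = np.isinf(d)
        if unreachable.any():
            warnings.warn(
                f"colony {getattr(col, 'name', col.Index)}: "
                f"{int(unreachable.sum())} sea cell(s) unreachable", RuntimeWarning)
        contrib = col.pairs / np.maximum(d, d_min) ** 2
        contrib[unreachable] = 0.0
        score += np.where(land, np.nan, contrib)
    score[land] = np.nan
    return score


# ---------------------------------------------------------------------------
# full per-cell covariate table
# ---------------------------------------------------------------------------


def covariate_table(grid, land_mask: np.ndarray, fields: dict[str, np.ndarray],
                    colonies: pd.DataFrame | None = None,
                    shelf_depth_m: float = -500.0) -> pd.DataFrame:
    """Engineer the full per-sea-cell covariate table.

    From the gridded environment (``fields`` must contain ``depth`` and may
    contain ``chl_a``, ``sst``, ``sss``): distance to the coastline and to
    the 500 m isobath, depth (clamped <= 0), seabed slope in degrees,
    gradient magnitudes of the dynamic fields, and — when colonies are
    given — the land-avoiding colony proximity score.
    """
    land = np.asarray(land_mask, dtype=bool)
    c = grid.centres()
    sea = ~land[c["iy"], c["ix"]]
    out = c[sea].reset_index(drop=True)
    pts = out[["x", "y"]].to_numpy()

    coast = boundary_points(land, grid)
    out["dist_coast"] = (distance_to_set(pts, coast) if coast.size
                         else np.zeros(len(out)))
    depth = np.minimum(np.asarray(fields["depth"], dtype=float), 0.0)
    shelf = contour_points(depth, shelf_depth_m, grid)
    out["dist_shelf"] = (distance_to_set(pts, shelf) if shelf.size
                         else np.full(len(out), np.nan))
    out["depth"] = depth[out["iy"], out["ix"]]
    out["slope"] = slope_degrees(np.where(land, np.nan, depth),
                                 grid.cell_km)[out["iy"], out["ix"]]
    for name, short in (("chl_a", "chl"), ("sst", "sst"), ("sss", "sss")):
        if name in fields:
            out[name] = np.asarray(fields[name], dtype=float)[out["iy"], out["ix"]]
            g = terrain_gradient(np.asarray(fields[name], dtype=float), grid.cell_km)
            out[f"grad_{short}"] = g[out["iy"], out["ix"]]
    if colonies is not None and len(colonies):
        score = colony_proximity_score(grid, colonies, land)
        out["colony_score"] = score[out["iy"], out["ix"]]
    return out


def attach_covariates(records: pd.DataFrame, cov_table: pd.DataFrame) -> pd.DataFrame:
    """Merge per-cell covariates onto the (cell, pass) survey records.

    Rows whose cell is absent from the covariate table (centre over land)
    are dropped with a warning — they cannot enter the habitat model.
    """
    cols = [c for c in cov_table.columns if c not in ("x", "y")]
    out = records.merge(cov_table[cols], on=["ix", "iy"], how="inner")
    if len(out) < len(records):
        warnings.warn(f"{len(records) - len(out)} record(s) in cells without "
                      "covariates (land-centred) dropped", RuntimeWarning)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoxCoxTransform:
    """A fitted Box-Cox transform: y = ((x + shift)^lambda - 1) / lambda.

    The shift makes the input strictly positive; lambda and shift are
    persisted so the prediction grid is transformed with exactly the same
    parameters as the training data.
    """

    lmbda: float
    shift: float

    def transform(self, x) -> np.ndarray:
        z = np.asarray(x, dtype=float) + self.shift
        if np.any(z <= 0):
            raise ValueError("non-positive values after shift")
        if abs(self.lmbda) < 1e-12:
            return np.log(z)
        return (z**self.lmbda - 1.0) / self.lmbda

    def inverse(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if abs(self.lmbda) < 1e-12:
            return np.exp(y) - self.shift
        return (self.lmbda * y + 1.0) ** (1.0 / self.lmbda) - self.shift


def fit_boxcox(x, lmbda: float | None = None) -> tuple[np.ndarray, BoxCoxTransform]:
    """Box-Cox transform a positive vector, estimating lambda if not given.

    lambda maximises the profile log-likelihood, scanned on a 0.01 grid
    over [-2, 2] and refined by golden-section search.  Inputs with
    min(x) <= 0 are shifted by 1 - min(x) first (shift recorded).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    shift = 0.0
    if np.min(x) <= 0:
        shift = 1.0 - np.min(x)
    z = x + shift
    if lmbda is None:
        grid = np.arange(-2.0, 2.0 + 1e-9, 0.01)
        ll = np.array([boxcox_llf(l, z) for l in grid])
        j = int(np.argmax(ll))
        lo, hi = grid[max(j - 1, 0)], grid[min(j + 1, grid.size - 1)]
        lmbda = _golden_min(lambda l: -boxcox_llf(l, z), lo, hi, tol=1e-6)
    tr = BoxCoxTransform(float(lmbda), shift)
    return tr.transform(x), tr


def boxcox_where_required(table: pd.DataFrame, columns: list[str],
                          skew_threshold: float = 1.0):
    """Transform the listed covariates whose |skewness| exceeds the threshold.

    Returns the transformed table and the dict of fitted transforms (the
    JSON-serialisable lambda/shift sidecar).
    """
    out = table.copy()
    transforms: dict[str, BoxCoxTransform] = {}
    for col in columns:
        v = out[col].to_numpy(dtype=float)
        ok = np.isfinite(v)
        if ok.sum() < 10:
            continue
        if abs(skew(v[ok])) > skew_threshold:
            y, tr = fit_boxcox(v[ok])
            w = v.copy()
            w[ok] = y
            out[col] = w
            transforms[col] = tr
    return out, transforms
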