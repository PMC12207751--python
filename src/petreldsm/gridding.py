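"""Analysis grid, strip-transect effort areas and count aggregation.

The survey strip is the trackline buffered by a fixed half width (200 m a
side for these aerial surveys).  Effort per 4 x 4 km grid cell and survey
pass is the area of the on-effort strip clipped to the cell, with
overlapping strips within a pass geometrically unioned first so nothing is
double counted.  A *pass* is one transect flight (each transect carries a
single Julian day and year); repeated coverage of a cell by different
transects yields separate rows, each with its own effort, mean sea state
and altitude class, which is what gives the log-effort offset its meaning
in the downstream count model.

Cell membership uses the half-open convention: a point on an interior cell
boundary belongs to the cell on its +x/+y side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, box
from shapely.ops import unary_union

STRIP_HALF_WIDTH_KM = 0.2  # 200 m each side of the trackline


@dataclass(frozen=True)
class Grid:
    """Regular planar grid tiling the study extent."""

    x0: float
    y0: float
    cell_km: float
    nx: int
    ny: int

    @property
    def cell_area(self) -> float:
        return self.cell_km**2

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (self.x0, self.x0 + self.nx * self.cell_km,
                self.y0, self.y0 + self.ny * self.cell_km)

    def cell_of(self, x, y):
        """Half-open cell indices; boundary points go to the +x/+y cell."""
        ix = np.floor((np.asarray(x, dtype=float) - self.x0) / self.cell_km).astype(int)
        iy = np.floor((np.asarray(y, dtype=float) - self.y0) / self.cell_km).astype(int)
        return ix, iy

    def centre(self, ix, iy):
        return (self.x0 + (np.asarray(ix) + 0.5) * self.cell_km,
                self.y0 + (np.asarray(iy) + 0.5) * self.cell_km)

    def centres(self) -> pd.DataFrame:
        iy, ix = np.mgrid[0:self.ny, 0:self.nx]
        x, y = self.centre(ix.ravel(), iy.ravel())
        return pd.DataFrame({"ix": ix.ravel(), "iy": iy.ravel(), "x": x, "y": y})

    def cell_box(self, ix: int, iy: int):
        x = self.x0 + ix * self.cell_km
        y = self.y0 + iy * self.cell_km
        return box(x, y, x + self.cell_km, y + self.cell_km)

    def contains(self, x, y) -> np.ndarray:
        x0, x1, y0, y1 = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= x0) & (x < x1) & (y >= y0) & (y < y1)


def build_grid(extent, cell_km: float = 4.0) -> Grid:
    """Grid covering ``extent = (x_min, x_max, y_min, y_max)``."""
    x_min, x_max, y_min, y_max = map(float, extent)
    if cell_km <= 0:
        raise ValueError("cell_km must be positive")
    if x_max <= x_min or y_max <= y_min:
        raise ValueError("extent must have strictly positive area")
    nx = int(np.ceil((x_max - x_min) / cell_km - 1e-9))
    ny = int(np.ceil((y_max - y_min) / cell_km - 1e-9))
    return Grid(x_min, y_min, cell_km, nx, ny)


# ---------------------------------------------------------------------------
# effort
# ---------------------------------------------------------------------------


def _candidate_cells(grid: Grid, bounds, pad: float):
    bx0, by0, bx1, by1 = bounds
    i0 = max(int(np.floor((bx0 - pad - grid.x0) / grid.cell_km)), 0)
    i1 = min(int(np.floor((bx1 + pad - grid.x0) / grid.cell_km)), grid.nx - 1)
    j0 = max(int(np.floor((by0 - pad - grid.y0) / grid.cell_km)), 0)
    j1 = min(int(np.floor((by1 + pad - grid.y0) / grid.cell_km)), grid.ny - 1)
    for ix in range(i0, i1 + 1):
        for iy in range(j0, j1 + 1):
            yield ix, iy


def effort_per_cell(grid: Grid, segments: pd.DataFrame,
                    strip_half_width_km: float = STRIP_HALF_WIDTH_KM) -> pd.DataFrame:
    """Per (cell, pass) effort area, mean sea state and pass metadata.

    ``segments`` has one row per constant-condition piece of trackline with
    columns ``transect_id, x0, y0, x1, y1, sea_state, effort, altitude,
    julian_day, year``; ``effort`` is the on/off-effort flag.  Off-effort
    pieces contribute no area.  Mean sea state is length-weighted along the
    in-cell trackline.
    """
    if strip_half_width_km <= 0:
        raise ValueError("strip_half_width_km must be positive")
    rows = []
    for tid, seg in segments.groupby("transect_id", sort=True):
        on = seg[seg["effort"].astype(bool)]
        if on.empty:
            continue
        lines, states = [], []
        for s in on.itertuples():
            ln = LineString([(s.x0, s.y0), (s.x1, s.y1)])
            if ln.length < 1e-12:
                warnings.warn(f"zero-length segment on transect {tid}", RuntimeWarning)
                continue
            lines.append(ln)
            states.append(float(s.sea_state))
        if not lines:
            continue
        strip = unary_union([ln.buffer(strip_half_width_km, cap_style="flat",
                                       join_style="mitre") for ln in lines])
        meta = on.iloc[0]
        for ix, iy in _candidate_cells(grid, strip.bounds, 0.0):
            cell = grid.cell_box(ix, iy)
            area = strip.intersection(cell).area
            if area <= 1e-12:
                continue
            wlen = wsum = 0.0
            for ln, st in zip(lines, states):
                L = ln.intersection(cell).length
                wlen += L
                wsum += L * st
            mean_ss = wsum / wlen if wlen > 1e-12 else states[0]
            rows.append({"ix": ix, "iy": iy, "pass_id": tid,
                         "effort_area": area, "sea_state": mean_ss,
                         "altitude": meta["altitude"],
                         "julian_day": int(meta["julian_day"]),
                         "year": int(meta["year"])})
    out = pd.DataFrame(rows, columns=["ix", "iy", "pass_id", "effort_area",
                                      "sea_state", "altitude", "julian_day", "year"])
    if not out.empty:
        x, y = grid.centre(out["ix"].to_numpy(), out["iy"].to_numpy())
        out.insert(2, "x", x)
        out.insert(3, "y", y)
    return out


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def aggregate_counts(grid: Grid, sightings: pd.DataFrame,
                     effort: pd.DataFrame) -> pd.DataFrame:
    """Attach summed group sizes to the effort table.

    Every effort row gains a ``count`` column (0 where nothing was seen).
    Sightings whose (cell, pass) has no surveyed strip are kept as rows
    with zero effort and trigger a consistency warning; sightings outside
    the grid extent are an error.  Total count is conserved exactly.
    """
    recs = effort.copy()
    recs["count"] = 0
    if sightings.empty:
        return recs
    sx = sightings["x"].to_numpy(dtype=float)
    sy = sightings["y"].to_numpy(dtype=float)
    if not np.all(grid.contains(sx, sy)):
        raise ValueError("sighting position outside the grid extent")
    ix, iy = grid.cell_of(sx, sy)
    agg = (pd.DataFrame({"ix": ix, "iy": iy,
                         "pass_id": sightings["transect_id"].to_numpy(),
                         "count": sightings["group_size"].to_numpy(dtype=int)})
           .groupby(["ix", "iy", "pass_id"], as_index=False)["count"].sum())
    key = ["ix", "iy", "pass_id"]
    merged = recs.drop(columns="count").merge(agg, on=key, how="outer", indicator=True)
    orphans = merged["_merge"] == "right_only"
    if orphans.any():
        warnings.warn(
            f"{int(orphans.sum())} sighting cell-pass group(s) fall outside the "
            "surveyed strips; retained with zero effort", RuntimeWarning)
        x, y = grid.centre(merged.loc[orphans, "ix"].to_numpy(),
                           merged.loc[orphans, "iy"].to_numpy())
        merged.loc[orphans, "x"] = x
        merged.loc[orphans, "y"] = y
        merged.loc[orphans, "effort_area"] = 0.0
    merged["count"] = merged["count"].fillna(0).astype(int)
    return merged.drop(columns="_merge")


def dual_altitude_subset(records: pd.DataFrame) -> pd.DataFrame:
    """Rows for cells surveyed at both altitude classes (all passes kept)."""
    surveyed = records[records["effort_area"] > 0]
    n_alt = surveyed.groupby(["ix", "iy"])["altitude"].nunique()
    both = n_alt[n_alt >= 2].index
    mask = surveyed.set_index(["ix", "iy"]).index.isin(both)
    return surveyed[mask].reset_index(drop=True)
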