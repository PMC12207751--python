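"""Synthetic survey worlds with fully known ground truth.

Everything the real analysis consumes — spatially autocorrelated
environmental fields, a coastline with islets, breeding colonies, a true
density surface built from known smooth functions of the covariates,
broad (high-altitude) and fine (low-altitude) strip transects with
piecewise-constant Beaufort sea states, and detection-thinned sightings —
is generated here from a single seeded random generator, so every
downstream stage can be tested against known truth without any external
data.

Default parameters emulate the study conditions the pipeline targets: a
~450,000 km^2 offshore study area on a 4 km grid, ~50,000 km of trackline
split between broad-scale lines and a denser fine-scale block, >= 95% of
effort at Beaufort sea state 3 or less, ~80% single-bird sightings, and a
true total abundance of ~150,000 birds (mean density ~0.33 birds/km^2).
Detection is perfect at sea state 0 and low altitude and declines
log-linearly with sea state, with an extra penalty at high altitude.

Grids are arrays of shape (ny, nx) indexed [iy, ix]; land cells are NaN
in the fields and True in the land mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from shapely.geometry import LineString

from . import covariates as cov
from .gridding import Grid, build_grid


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldSpec:
    """Gaussian-random-field parameters for one environmental variable.

    ``corr_km`` is the e^(-1/2) range of the Gaussian correlation
    function; ``transform="exp"`` exponentiates the field afterwards
    (log-normal variables such as chl-a).
    """

    mean: float
    sd: float
    corr_km: float
    transform: str | None = None


@dataclass(frozen=True)
class LandSpec:
    """One main elliptical island plus optional circular islets."""

    cx: float = 545.0
    cy: float = 380.0
    rx: float = 55.0
    ry: float = 170.0
    islets: tuple[tuple[float, float, float], ...] = ((470.0, 140.0, 8.0),
                                                      (480.0, 560.0, 10.0))


def _default_fields() -> dict[str, FieldSpec]:
    return {
        "depth_noise": FieldSpec(0.0, 60.0, 60.0),
        "chl_a": FieldSpec(np.log(0.5), 0.6, 50.0, transform="exp"),
        "sst": FieldSpec(13.5, 1.2, 80.0),
        "sss": FieldSpec(35.0, 0.35, 100.0),
    }


@dataclass(frozen=True)
class WorldConfig:
    extent: tuple[float, float, float, float] = (0.0, 600.0, 0.0, 752.0)
    cell_km: float = 4.0
    land: LandSpec = dc_field(default_factory=LandSpec)
    field_specs: dict[str, FieldSpec] = dc_field(default_factory=_default_fields)
    seed: int = 0

    def __post_init__(self):
        x0, x1, y0, y1 = self.extent
        if x1 <= x0 or y1 <= y0:
            raise ValueError("extent must have strictly positive area")
        if self.cell_km <= 0:
            raise ValueError("cell_km must be positive")
        for name, fs in self.field_specs.items():
            if fs.corr_km <= 0:
                raise ValueError(f"correlation length of {name!r} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "WorldConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "land" in raw:
            raw["land"] = LandSpec(**raw["land"])
        if "field_specs" in raw:
            raw["field_specs"] = {k: FieldSpec(**v) for k, v in raw["field_specs"].items()}
        if "extent" in raw:
            raw["extent"] = tuple(raw["extent"])
        return cls(**raw)


@dataclass(frozen=True)
class DetectParams:
    """Log-scale detection parameters.

    Retention probability of a group is
    ``min(1, exp(delta_alt * 1[high] + beta_ss[altitude] * sea_state))`` —
    exactly 1 at sea state 0 and low altitude.
    """

    delta_alt: float = np.log(0.5)
    beta_ss: dict[str, float] = dc_field(
        default_factory=lambda: {"high": -0.20, "low": -0.10})


GROUP_SIZE_PROBS = {1: 0.805, 2: 0.107}  # remaining 0.088 mass: 3 + Geometric(0.5)


@dataclass
class Environment:
    grid: Grid
    land_mask: np.ndarray
    fields: dict[str, np.ndarray]

    def sea_frame(self) -> pd.DataFrame:
        """Per-sea-cell covariate table (ix, iy, x, y + all fields)."""
        c = self.grid.centres()
        sea = ~self.land_mask[c["iy"], c["ix"]]
        out = c[sea].reset_index(drop=True)
        for name, f in self.fields.items():
            out[name] = f[out["iy"], out["ix"]]
        return out


@dataclass
class SyntheticTruth:
    """The generating density surface and detection regime."""

    density: np.ndarray            # expected birds per km^2 per cell, 0 on land
    partial_effects: dict[str, Callable]
    intercept: float
    dispersion_theta: float
    detect: DetectParams
    total: float                   # total_N_true = sum density * cell area
    covgrids: dict[str, np.ndarray]
    grid: Grid
    land_mask: np.ndarray


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------


def gaussian_random_field(shape, corr_cells: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance stationary field with Gaussian correlation.

    Gaussian-filtered white noise on a torus: the filter with kernel scale
    sigma = corr / sqrt(2) yields covariance exp(-r^2 / (2 corr^2)); the
    sample is then normalised to unit empirical variance.
    """
    if corr_cells <= 0:
        raise ValueError("correlation length must be positive")
    white = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(white, sigma=corr_cells / np.sqrt(2.0), mode="wrap")
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def _land_mask(config: WorldConfig, grid: Grid) -> np.ndarray:
    c = grid.centres()
    ls = config.land
    x = c["x"].to_numpy()
    y = c["y"].to_numpy()
    inside = ((x - ls.cx) / ls.rx) ** 2 + ((y - ls.cy) / ls.ry) ** 2 <= 1.0
    for (ix_, iy_, r_) in ls.islets:
        inside |= (x - ix_) ** 2 + (y - iy_) ** 2 <= r_**2
    mask = np.zeros((grid.ny, grid.nx), dtype=bool)
    mask[c["iy"], c["ix"]] = inside
    return mask


def gen_environment(config: WorldConfig) -> Environment:
    """Generate the gridded synthetic environment (reproducible per seed)."""
    grid = build_grid(config.extent, config.cell_km)
    rng = np.random.default_rng(config.seed)
    land = _land_mask(config, grid)
    fields: dict[str, np.ndarray] = {}
    for name, fs in config.field_specs.items():
        if fs.sd == 0:
            f = np.full((grid.ny, grid.nx), fs.mean)
        else:
            f = fs.mean + fs.sd * gaussian_random_field(
                (grid.ny, grid.nx), fs.corr_km / config.cell_km, rng)
        if fs.transform == "exp":
            f = np.exp(f)
        fields[name] = f

    # bathymetry: deepening away from land plus the noise field
    dist_land = ndimage.distance_transform_edt(~land) * config.cell_km
    depth = -(10.0 + 2.2 * dist_land + fields.pop("depth_noise", 0.0))
    depth = np.minimum(depth, 0.0)  # offshore depth never above sea level
    fields["depth"] = depth
    for name in fields:
        fields[name] = np.where(land, np.nan, fields[name])
    return Environment(grid, land, fields)


def gen_colonies(env: Environment, n: int = 6, total_pairs: int = 100_000,
                 seed: int = 1) -> pd.DataFrame:
    """Colonies on coastal land cells; pairs sum to ``total_pairs``."""
    rng = np.random.default_rng(seed)
    land = env.land_mask
    coastal = land & ~ndimage.binary_erosion(land)
    iy, ix = np.nonzero(coastal)
    if iy.size == 0:
        raise ValueError("no coastal land cells to place colonies on")
    pick = rng.choice(iy.size, size=min(n, iy.size), replace=False)
    x, y = env.grid.centre(ix[pick], iy[pick])
    w = rng.dirichlet(np.ones(pick.size) * 0.8)
    pairs = np.maximum((w * total_pairs).round().astype(int), 1)
    return pd.DataFrame({"name": [f"colony_{i}" for i in range(pick.size)],
                         "x": x, "y": y, "pairs": pairs})


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------


def default_effects() -> dict[str, Callable]:
    """Known smooth partial effects: coastal avoidance with a 20-40 km
    peak, preference for water deeper than ~160 m, mild SST effect."""
    return {
        "dist_coast": lambda d: 1.1 * np.exp(-((d - 30.0) / 45.0) ** 2)
                                - 1.6 * np.exp(-d / 8.0),
        "depth": lambda z: 0.8 / (1.0 + np.exp(-(-z - 160.0) / 40.0)),
        "sst": lambda t: 0.25 * (t - 13.5) / 1.2,
    }


def gen_truth(env: Environment, effect_spec: dict[str, Callable] | None = None,
              intercept: float | None = None, target_total: float = 150_000.0,
              theta: float = 2.0, detect: DetectParams | None = None) -> SyntheticTruth:
    """Build log-linear truth: log density = intercept + sum_k f_k(x_k).

    When ``intercept`` is None it is calibrated so the summed abundance
    equals ``target_total``.  Density is identically zero on land.
    """
    if effect_spec is None:
        effect_spec = default_effects()
    if detect is None:
        detect = DetectParams()
    grids = dict(env.fields)
    if "dist_coast" in effect_spec and "dist_coast" not in grids:
        grids["dist_coast"] = dist_coast_grid(env)
    missing = [k for k in effect_spec if k not in grids]
    if missing:
        raise KeyError(f"effect_spec references unknown covariate(s) {missing}")

    log_d = np.zeros((env.grid.ny, env.grid.nx))
    for name, f in effect_spec.items():
        log_d = log_d + f(grids[name])
    sea = ~env.land_mask
    if intercept is None:
        base = np.nansum(np.where(sea, np.exp(log_d), 0.0)) * env.grid.cell_area
        intercept = float(np.log(target_total / base))
    density = np.where(sea, np.exp(intercept + log_d), 0.0)
    density = np.nan_to_num(density, nan=0.0)
    total = float(density.sum() * env.grid.cell_area)
    return SyntheticTruth(density, dict(effect_spec), float(intercept), theta,
                          detect, total, grids, env.grid, env.land_mask)


def dist_coast_grid(env: Environment) -> np.ndarray:
    """Distance (km) from each cell centre to the land/sea boundary."""
    pts = cov.boundary_points(env.land_mask, env.grid)
    c = env.grid.centres()
    d = cov.distance_to_set(c[["x", "y"]].to_numpy(), pts)
    out = np.zeros((env.grid.ny, env.grid.nx))
    out[c["iy"], c["ix"]] = d
    return np.where(env.land_mask, np.nan, out)


# ---------------------------------------------------------------------------
# transects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransectDesign:
    broad_spacing_km: float = 10.0
    fine_spacing_km: float = 3.704          # two nautical miles
    fine_region: tuple[float, float, float, float] | None = (330.0, 490.0, 80.0, 280.0)
    state_block_km: float = 40.0
    off_effort_prob: float = 0.03
    sea_state_probs: tuple[float, ...] = (0.30, 0.30, 0.25, 0.12, 0.03)
    years: tuple[int, ...] = (2015, 2016, 2021, 2022)
    day_range: tuple[int, int] = (140, 260)


def _coast_x(env: Environment) -> np.ndarray:
    """Westernmost land x per cell row (transects stop short of land)."""
    grid = env.grid
    out = np.full(grid.ny, grid.extent[1])
    for iy in range(grid.ny):
        ixs = np.nonzero(env.land_mask[iy])[0]
        if ixs.size:
            out[iy] = grid.x0 + ixs.min() * grid.cell_km
    return out


def gen_transects(env: Environment, design: TransectDesign | None = None,
                  seed: int = 2) -> pd.DataFrame:
    """Parallel east-west strip transects, perpendicular to the coast.

    Broad lines (altitude "high") span the open sea at ``broad_spacing_km``;
    fine lines (altitude "low") fill ``fine_region`` at two-nautical-mile
    spacing.  Each transect carries a Julian day, a year, and a
    piecewise-constant sea-state sequence in blocks of ``state_block_km``
    drawn from ``sea_state_probs`` (>= 95% of mass at Beaufort <= 3);
    blocks go off effort with probability ``off_effort_prob``.

    Returns one row per constant-condition segment with columns
    ``transect_id, x0, y0, x1, y1, altitude, sea_state, effort,
    julian_day, year``.
    """
    if design is None:
        design = TransectDesign()
    if design.broad_spacing_km <= 0 or design.fine_spacing_km <= 0:
        raise ValueError("transect spacings must be positive")
    if sum(design.sea_state_probs[:4]) < 0.95:
        warnings.warn("sea-state distribution puts < 95% of effort at Beaufort <= 3",
                      RuntimeWarning)
    grid = env.grid
    x_min, x_max, y_min, y_max = grid.extent
    if design.fine_region is not None:
        fx0, fx1, fy0, fy1 = design.fine_region
        if not (x_min <= fx0 and fx1 <= x_max and y_min <= fy0 and fy1 <= y_max):
            raise ValueError("fine_region must lie inside the study extent")
    rng = np.random.default_rng(seed)
    coast = _coast_x(env)

    rows = []
    tid = 0

    def add_line(y, xa, xb, altitude):
        nonlocal tid
        length = xb - xa
        if length <= 0:
            return
        n_blocks = max(int(np.ceil(length / design.state_block_km)), 1)
        edges = np.linspace(xa, xb, n_blocks + 1)
        states = rng.choice(len(design.sea_state_probs), size=n_blocks,
                            p=design.sea_state_probs)
        effort = rng.random(n_blocks) >= design.off_effort_prob
        day = int(rng.integers(design.day_range[0], design.day_range[1] + 1))
        year = int(rng.choice(design.years))
        for b in range(n_blocks):
            rows.append({"transect_id": tid, "x0": edges[b], "y0": y,
                         "x1": edges[b + 1], "y1": y, "altitude": altitude,
                         "sea_state": int(states[b]), "effort": bool(effort[b]),
                         "julian_day": day, "year": year})
        tid += 1

    y = y_min + design.broad_spacing_km / 2.0
    while y < y_max:
        iy = min(int((y - y_min) / grid.cell_km), grid.ny - 1)
        add_line(y, x_min, coast[iy] - 2.0, "high")
        y += design.broad_spacing_km

    if design.fine_region is not None:
        fx0, fx1, fy0, fy1 = design.fine_region
        if (fx1 - fx0) > 0 and (fy1 - fy0) > 0:
            # lines on both block edges: span/spacing + 1 parallel lines
            y = fy0
            while y <= fy1 + 1e-9:
                add_line(y, fx0, fx1, "low")
                y += design.fine_spacing_km

    return pd.DataFrame(rows)


def total_trackline_km(segments: pd.DataFrame) -> float:
    dx = segments["x1"] - segments["x0"]
    dy = segments["y1"] - segments["y0"]
    return float(np.hypot(dx, dy).sum())


# ---------------------------------------------------------------------------
# detection and sightings
# ---------------------------------------------------------------------------


def detection_prob(detect: DetectParams, altitude: str, sea_state) -> np.ndarray:
    """Group retention probability; clamped at 1 with a logged warning."""
    lp = (detect.delta_alt * (altitude == "high")
          + detect.beta_ss[altitude] * np.asarray(sea_state, dtype=float))
    p = np.exp(lp)
    if np.any(p > 1.0 + 1e-12):
        warnings.warn("detection parameters imply p > 1; clamping", RuntimeWarning)
    return np.minimum(p, 1.0)


def sample_group_sizes(rng: np.random.Generator, n: int) -> np.ndarray:
    """Group sizes: 80.5% singles, 10.7% pairs, rest 3+ (geometric tail)."""
    u = rng.random(n)
    sizes = np.ones(n, dtype=int)
    sizes[u >= GROUP_SIZE_PROBS[1]] = 2
    big = u >= GROUP_SIZE_PROBS[1] + GROUP_SIZE_PROBS[2]
    sizes[big] = 3 + rng.geometric(0.5, size=int(big.sum())) - 1
    return sizes


def nb_counts(rng: np.random.Generator, mean, theta: float) -> np.ndarray:
    """NB2 (or Poisson when theta is inf) counts with the given means."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    if not np.isfinite(theta):
        out[pos] = rng.poisson(mean[pos])
    else:
        p = theta / (theta + mean[pos])
        out[pos] = rng.negative_binomial(theta, p)
    return out


def gen_sightings(truth: SyntheticTruth, segments: pd.DataFrame,
                  seed: int = 3, strip_half_width_km: float = 0.2) -> pd.DataFrame:
    """Detection-thinned sightings along the on-effort survey strips.

    Latent individuals per (cell, segment) intersection are NB with mean
    density x intersected strip area and size ``dispersion_theta``; they
    are partitioned into groups (~80% singletons) and each group is kept
    with the altitude/sea-state detection probability.  Positions are
    uniform along the in-cell trackline with a uniform lateral offset
    inside the strip.
    """
    rng = np.random.default_rng(seed)
    grid = truth.grid
    rows = []
    on = segments[segments["effort"].astype(bool)]
    for s in on.itertuples():
        p0 = np.array([s.x0, s.y0])
        p1 = np.array([s.x1, s.y1])
        seg_len = float(np.hypot(*(p1 - p0)))
        if seg_len < 1e-12:
            continue
        line = LineString([p0, p1])
        strip = line.buffer(strip_half_width_km, cap_style="flat", join_style="mitre")
        perp = np.array([-(p1 - p0)[1], (p1 - p0)[0]]) / seg_len
        p_det = float(detection_prob(truth.detect, s.altitude, s.sea_state))
        bx0, by0, bx1, by1 = strip.bounds
        i0 = max(int((bx0 - grid.x0) // grid.cell_km), 0)
        i1 = min(int((bx1 - grid.x0) // grid.cell_km), grid.nx - 1)
        j0 = max(int((by0 - grid.y0) // grid.cell_km), 0)
        j1 = min(int((by1 - grid.y0) // grid.cell_km), grid.ny - 1)
        for ix in range(i0, i1 + 1):
            for iy in range(j0, j1 + 1):
                lam = truth.density[iy, ix]
                if lam <= 0:
                    continue
                cell = grid.cell_box(ix, iy)
                area = strip.intersection(cell).area
                if area <= 1e-12:
                    continue
                latent = int(nb_counts(rng, np.array([lam * area]),
                                       truth.dispersion_theta)[0])
                if latent == 0:
                    continue
                inline = line.intersection(cell)
                remaining = latent
                while remaining > 0:
                    size = int(min(sample_group_sizes(rng, 1)[0], remaining))
                    remaining -= size
                    if rng.random() >= p_det:
                        continue
                    if inline.is_empty or inline.length < 1e-12:
                        px, py = cell.representative_point().coords[0]
                    else:
                        pt = inline.interpolate(rng.random() * inline.length)
                        off = (rng.random() * 2.0 - 1.0) * strip_half_width_km
                        px, py = pt.x + perp[0] * off, pt.y + perp[1] * off
                    rows.append({"transect_id": s.transect_id, "x": px, "y": py,
                                 "group_size": size})
    return pd.DataFrame(rows, columns=["transect_id", "x", "y", "group_size"])
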