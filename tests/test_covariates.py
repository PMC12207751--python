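"""Covariate engineering: distances, gradients, IDW, temporal windows,
land-avoiding colony scores and Box-Cox transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petreldsm import covariates as cov
from petreldsm.gridding import build_grid


class TestDistance:
    def test_point_on_target_is_zero(self):
        assert cov.distance_to_set([[3.0, 4.0]], [[3.0, 4.0]])[0] == 0.0

    def test_three_four_five(self):
        assert cov.distance_to_set([[3.0, 4.0]], [[0.0, 0.0]])[0] == pytest.approx(5.0)

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            cov.distance_to_set([[0.0, 0.0]], np.empty((0, 2)))

    def test_matches_exhaustive_minimum(self):
        """Brute-force min over target vertices on a 20x20 query set."""
        rng = np.random.default_rng(3)
        targets = rng.uniform(0, 80, size=(37, 2))
        g = build_grid((0, 80, 0, 80), 4.0)
        pts = g.centres()[["x", "y"]].to_numpy()
        got = cov.distance_to_set(pts, targets)
        want = np.array([min(np.hypot(*(p - t)) for t in targets) for p in pts])
        assert np.allclose(got, want, atol=1e-9)


class TestGradient:
    def test_constant_field_zero_everywhere(self):
        g = cov.terrain_gradient(np.full((8, 9), 3.7), 4.0)
        assert np.allclose(g, 0.0)

    def test_planar_ramp_exact_interior(self):
        x = np.arange(10) * 4.0
        f = np.tile(2.0 * x, (8, 1))  # f = 2x per km
        g = cov.terrain_gradient(f, 4.0)
        assert np.allclose(g[1:-1, 1:-1], 2.0, atol=1e-12)

    def test_matches_independent_horn_oracle(self):
        """Interior cells vs a plainly-written 3x3 Horn loop, 1e-10."""
        rng = np.random.default_rng(1)
        f = rng.standard_normal((12, 15))
        got = cov.terrain_gradient(f, 4.0)
        for iy in range(1, 11):
            for ix in range(1, 14):
                z = f[iy - 1:iy + 2, ix - 1:ix + 2]
                gx = ((z[0, 2] + 2 * z[1, 2] + z[2, 2])
                      - (z[0, 0] + 2 * z[1, 0] + z[2, 0])) / (8 * 4.0)
                gy = ((z[2, 0] + 2 * z[2, 1] + z[2, 2])
                      - (z[0, 0] + 2 * z[0, 1] + z[0, 2])) / (8 * 4.0)
                assert got[iy, ix] == pytest.approx(np.hypot(gx, gy), abs=1e-10)

    def test_linearity(self):
        rng = np.random.default_rng(2)
        f = rng.standard_normal((10, 10))
        assert np.allclose(cov.terrain_gradient(3.0 * f, 2.0),
                           3.0 * cov.terrain_gradient(f, 2.0))

    def test_all_missing_stays_missing(self):
        assert np.all(np.isnan(cov.terrain_gradient(np.full((5, 5), np.nan), 4.0)))

    def test_masked_cells_stay_masked_neighbours_finite(self):
        f = np.ones((6, 6))
        f[2, 2] = np.nan
        g = cov.terrain_gradient(f, 4.0)
        assert np.isnan(g[2, 2])
        assert np.isfinite(g[2, 3])


class TestIDW:
    def test_exact_hit_returns_source_value(self):
        got = cov.idw_append([[1.0, 1.0], [5.0, 5.0]], [10.0, 99.0], [[1.0, 1.0]])
        assert got[0] == 10.0

    def test_equidistant_pair_averages(self):
        got = cov.idw_append([[0.0, 0.0], [2.0, 0.0]], [10.0, 20.0], [[1.0, 0.0]])
        assert got[0] == pytest.approx(15.0)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(4)
        src = rng.uniform(0, 10, size=(5, 2))
        val = rng.uniform(0, 100, size=5)
        q = rng.uniform(0, 10, size=(7, 2))
        got = cov.idw_append(src, val, q, power=2.0)
        for i, p in enumerate(q):
            w = np.array([np.hypot(*(p - s)) ** -2.0 for s in src])
            assert got[i] == pytest.approx(w @ val / w.sum(), abs=1e-12)

    def test_max_radius_gives_missing(self):
        got = cov.idw_append([[0.0, 0.0]], [1.0], [[50.0, 0.0]], max_radius=10.0)
        assert np.isnan(got[0])

    def test_no_sources_rejected(self):
        with pytest.raises(ValueError):
            cov.idw_append(np.empty((0, 2)), [], [[0.0, 0.0]])


class TestTemporal:
    @pytest.mark.parametrize("day,window", [(195, (193, 200)), (1, (1, 8)),
                                            (8, (1, 8)), (9, (9, 16))])
    def test_window_arithmetic(self, day, window):
        assert cov.composite_window(day) == window

    def test_enumeration_consistency(self):
        """Every day of the year falls in exactly its own 8-day window."""
        for day in range(1, 367):
            a, b = cov.composite_window(day)
            assert a <= day <= b
            assert (a - 1) % 8 == 0 and b - a == 7

    def test_uncovered_day_rejected(self):
        with pytest.raises(ValueError):
            cov.composite_window(0)
        with pytest.raises(KeyError):
            cov.temporal_match({1: np.zeros((2, 2))}, 100)

    def test_salinity_mean_of_constant_layers(self):
        layers = {d: np.full((3, 3), 35.0) for d in range(193, 201)}
        assert np.allclose(cov.eight_day_mean(layers, 195), 35.0)

    def test_salinity_missing_day_rejected(self):
        layers = {d: np.zeros((2, 2)) for d in range(193, 200)}  # 200 missing
        with pytest.raises(KeyError):
            cov.eight_day_mean(layers, 195)


class TestColonyScore:
    def test_open_sea_inverse_square(self):
        """100 pairs, 10 km of open sea: score = 100/10^2 = 1.0 pairs/km^2."""
        land = np.zeros((1, 5), dtype=bool)
        land[0, 0] = True
        g = build_grid((0, 25, 0, 5), 5.0)
        colonies = pd.DataFrame({"name": ["c"], "x": [2.5], "y": [2.5],
                                 "pairs": [100]})
        score = cov.colony_proximity_score(g, colonies, land)
        # snapped sea cell is (1, 0); cell (3, 0) is 10 km away
        assert score[0, 3] == pytest.approx(1.0, abs=1e-12)

    def test_colony_cell_clamped_to_half_cell(self):
        """d_min = cell_km/2 = 2 for 4 km cells: own cell gets pairs/4."""
        land = np.zeros((1, 4), dtype=bool)
        land[0, 0] = True
        g = build_grid((0, 16, 0, 4), 4.0)
        colonies = pd.DataFrame({"name": ["c"], "x": [2.0], "y": [2.0],
                                 "pairs": [100]})
        score = cov.colony_proximity_score(g, colonies, land)
        assert score[0, 1] == pytest.approx(100 / 4.0, abs=1e-12)

    def barrier_world(self):
        """20x20 grid, vertical land wall with a gap forcing a detour."""
        land = np.zeros((20, 20), dtype=bool)
        land[0:16, 10] = True
        land[5, 0] = True  # colony site
        return land, build_grid((0, 80, 0, 80), 4.0)

    def test_distances_match_networkx_dijkstra(self):
        networkx = pytest.importorskip("networkx")
        land, g = self.barrier_world()
        src = cov.snap_to_sea(land, g, (2.0, 22.0))
        got = cov.sea_distance(land, src, g.cell_km)
        # independent oracle: networkx shortest paths on the same 8-graph
        G = networkx.Graph()
        ny, nx = land.shape
        for iy in range(ny):
            for ix in range(nx):
                if land[iy, ix]:
                    continue
                for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
                    jy, jx = iy + dy, ix + dx
                    if 0 <= jy < ny and 0 <= jx < nx and not land[jy, jx]:
                        w = g.cell_km * (np.sqrt(2.0) if dx and dy else 1.0)
                        G.add_edge((ix, iy), (jx, jy), weight=w)
        want = networkx.single_source_dijkstra_path_length(G, src)
        for (ix, iy), d in want.items():
            assert got[iy, ix] == pytest.approx(d, abs=1e-9)

    def test_scores_match_sum_formula(self):
        land, g = self.barrier_world()
        colonies = pd.DataFrame({"name": ["a"], "x": [2.0], "y": [22.0],
                                 "pairs": [500]})
        score = cov.colony_proximity_score(g, colonies, land)
        src = cov.snap_to_sea(land, g, (2.0, 22.0))
        d = cov.sea_distance(land, src, g.cell_km)
        want = 500.0 / np.maximum(d, 2.0) ** 2
        sea = ~land
        assert np.allclose(score[sea], want[sea], atol=1e-12)

    def test_removing_barrier_never_increases_distance(self):
        land, g = self.barrier_world()
        src = cov.snap_to_sea(land, g, (2.0, 22.0))
        with_wall = cov.sea_distance(land, src, g.cell_km)
        open_land = np.zeros_like(land)
        open_land[5, 0] = True
        without = cov.sea_distance(open_land, src, g.cell_km)
        sea = ~land
        assert np.all(without[sea] <= with_wall[sea] + 1e-9)

    def test_additive_over_colonies_and_monotone(self):
        land, g = self.barrier_world()
        c1 = pd.DataFrame({"name": ["a"], "x": [2.0], "y": [22.0], "pairs": [100]})
        c2 = pd.DataFrame({"name": ["b"], "x": [2.0], "y": [22.0], "pairs": [250]})
        both = pd.concat([c1, c2], ignore_index=True)
        s1 = cov.colony_proximity_score(g, c1, land)
        s2 = cov.colony_proximity_score(g, c2, land)
        sb = cov.colony_proximity_score(g, both, land)
        sea = ~land
        assert np.allclose(sb[sea], s1[sea] + s2[sea], atol=1e-12)

    def test_unreachable_basin_contributes_zero(self):
        land = np.zeros((5, 7), dtype=bool)
        land[:, 3] = True           # full wall: right side unreachable
        land[2, 0] = True           # colony site on the left
        g = build_grid((0, 28, 0, 20), 4.0)
        colonies = pd.DataFrame({"name": ["c"], "x": [2.0], "y": [10.0],
                                 "pairs": [100]})
        with pytest.warns(RuntimeWarning):
            score = cov.colony_proximity_score(g, colonies, land)
        assert np.all(score[:, 4:][~land[:, 4:]] == 0.0)


class TestBoxCox:
    def test_linear_case(self):
        tr = cov.BoxCoxTransform(1.0, 0.0)
        assert tr.transform([5.0])[0] == pytest.approx(4.0)

    def test_log_case(self):
        tr = cov.BoxCoxTransform(0.0, 0.0)
        assert tr.transform([np.e])[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("lmbda", [-1.15, 0.0, 0.14, 0.5, 1.0])
    def test_roundtrip(self, lmbda):
        x = np.array([0.2, 1.0, 3.7, 12.0])
        tr = cov.BoxCoxTransform(lmbda, 0.0)
        assert np.allclose(tr.inverse(tr.transform(x)), x, atol=1e-10)

    def test_shift_applied_and_persisted(self):
        x = np.array([-2.0, 0.0, 3.0, 8.0])
        y, tr = cov.fit_boxcox(x)
        assert tr.shift == 3.0
        assert np.allclose(tr.inverse(y), x, atol=1e-9)

    def test_estimated_lambda_reduces_skewness(self):
        from scipy.stats import skew
        rng = np.random.default_rng(6)
        x = np.exp(rng.standard_normal(2000))
        y, tr = cov.fit_boxcox(x)
        assert abs(skew(y)) < abs(skew(x))
        assert abs(tr.lmbda) < 0.2  # log-normal: lambda near 0

    def test_estimated_lambda_matches_scipy(self):
        from scipy.stats import boxcox as scipy_boxcox
        rng = np.random.default_rng(7)
        x = rng.gamma(2.0, 3.0, size=500)
        _, tr = cov.fit_boxcox(x)
        _, lam = scipy_boxcox(x)
        assert tr.lmbda == pytest.approx(lam, abs=1e-3)

    def test_nonpositive_after_shift_rejected(self):
        tr = cov.BoxCoxTransform(0.5, 0.0)
        with pytest.raises(ValueError):
            tr.transform([-1.0])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(-1.5, 1.5), st.lists(st.floats(0.1, 100.0), min_size=2,
                                          max_size=20))
    def test_roundtrip_property(self, lmbda, xs):
        tr = cov.BoxCoxTransform(lmbda, 0.0)
        x = np.asarray(xs)
        assert np.allclose(tr.inverse(tr.transform(x)), x, rtol=1e-8, atol=1e-8)


class TestCovariateTable:
    def test_table_complete_on_sea_cells(self, small_world):
        env, colonies, _ = small_world
        t = cov.covariate_table(env.grid, env.land_mask, env.fields, colonies)
        assert len(t) == int((~env.land_mask).sum())
        for c in ("dist_coast", "depth", "slope", "chl_a", "sst", "sss",
                  "grad_chl", "grad_sst", "grad_sss", "colony_score"):
            assert np.isfinite(t[c]).all(), c
        assert (t["depth"] <= 0).all()
        assert (t["dist_coast"] >= 0).all()
        assert (t["colony_score"] >= 0).all()
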