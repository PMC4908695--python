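"""Resistance surfaces, least-cost paths, and distance-matrix models."""

import numpy as np
import pytest

from lekstruct.containers import BarrierSet, PairwiseLekMatrix, ResistanceRaster
from lekstruct.landscape import (
    apply_barriers,
    geographic_distances,
    invert_suitability,
    least_cost_distances,
    mantel_test,
    mrm,
)
from lekstruct.simulate import simulate_resistance_raster


def random_distance_matrix(rng, n, labels=None):
    pts = rng.standard_normal((n, 2))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return PairwiseLekMatrix(labels or [f"l{i}" for i in range(n)], d, "geographic")


class TestInvertSuitability:
    def test_constant_suitability_becomes_constant_one(self):
        s = ResistanceRaster(np.full((5, 5), 0.4))
        out = invert_suitability(s)
        assert np.allclose(out.values, 1.0)

    def test_monotone_decreasing_in_suitability(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0.05, 1.0, size=(8, 8))
        out = invert_suitability(ResistanceRaster(vals))
        order = np.argsort(vals.ravel())
        assert np.all(np.diff(out.values.ravel()[order]) <= 1e-12)

    def test_two_value_raster_maps_to_extremes(self):
        vals = np.array([[0.5, 1.0], [1.0, 0.5]])
        out = invert_suitability(ResistanceRaster(vals), r_max=100.0)
        assert out.values[0, 0] == pytest.approx(100.0)
        assert out.values[0, 1] == pytest.approx(1.0)

    def test_nonpositive_suitability_rejected(self):
        with pytest.raises(ValueError):
            invert_suitability(ResistanceRaster(np.array([[0.5, 1.5], [0.2, 0.9]])))

    def test_complement_mode_also_monotone(self):
        vals = np.array([[0.2, 0.9], [0.5, 0.7]])
        out = invert_suitability(ResistanceRaster(vals), mode="complement")
        assert out.values[0, 0] > out.values[1, 0] > out.values[1, 1] > out.values[0, 1]


class TestBarriers:
    def test_empty_barrier_set_is_identity(self):
        r = simulate_resistance_raster(10, 10, roughness=1.0, seed=2)
        out = apply_barriers(r, BarrierSet(np.empty((0, 4))))
        assert np.array_equal(out.values, r.values)

    def test_permeable_mode_never_lowers_any_cell(self):
        r = simulate_resistance_raster(20, 20, cell_size=100.0, roughness=2.0, seed=3)
        b = BarrierSet(np.array([[0.0, 0.0, 2000.0, 2000.0]]), buffer_radius=100.0)
        out = apply_barriers(r, b)
        assert np.all(out.values >= r.values - 1e-12)

    def test_low_permeable_is_exactly_four_orders_above_permeable(self):
        r = simulate_resistance_raster(15, 15, cell_size=100.0, roughness=2.0, seed=4)
        seg = np.array([[0.0, 750.0, 1500.0, 750.0]])
        perm = apply_barriers(r, BarrierSet(seg, 100.0, "permeable"))
        low = apply_barriers(r, BarrierSet(seg, 100.0, "low_permeable"))
        changed = perm.values != r.values
        assert changed.any()
        assert np.allclose(low.values[changed] / perm.values[changed], 1e4)


class TestLeastCost:
    def test_uniform_raster_straight_line(self):
        r = ResistanceRaster(np.ones((10, 10)), cell_size=5.0)
        pts = np.array([[2.5, 2.5], [42.5, 2.5]])  # 8 cells apart in one row
        d = least_cost_distances(r, pts, ["a", "b"])
        assert d.values[0, 1] == pytest.approx(40.0)

    def test_lower_bound_by_euclidean_times_min_resistance(self):
        rng = np.random.default_rng(5)
        for seed in range(5):
            r = simulate_resistance_raster(15, 15, cell_size=2.0, roughness=2.0, seed=seed)
            pts = rng.uniform(1, 29, size=(4, 2))
            d = least_cost_distances(r, pts, list("abcd"))
            for i in range(4):
                for j in range(i + 1, 4):
                    eucl = np.hypot(*(pts[i] - pts[j]))
                    # snapping moves endpoints by at most one cell diagonal
                    slack = 2 * np.sqrt(2) * r.cell_size * r.values.min()
                    assert d.values[i, j] >= eucl * r.values.min() - slack

    def test_matches_networkx_dijkstra_oracle(self):
        import networkx as nx

        for seed in range(3):
            r = simulate_resistance_raster(12, 12, cell_size=3.0, roughness=2.0, seed=seed)
            g = nx.Graph()
            vals = r.values
            for i in range(12):
                for j in range(12):
                    for di, dj in ((0, 1), (1, 0), (1, 1), (1, -1)):
                        ii, jj = i + di, j + dj
                        if 0 <= ii < 12 and 0 <= jj < 12:
                            mult = np.sqrt(2) if di and dj else 1.0
                            w = (vals[i, j] + vals[ii, jj]) / 2 * r.cell_size * mult
                            g.add_edge((i, j), (ii, jj), weight=w)
            pts = np.array([[1.5, 1.5], [34.5, 28.5], [16.5, 4.5]])
            d = least_cost_distances(r, pts, list("abc"))
            cells = [r.cell_of(x, y) for x, y in pts]
            for a in range(3):
                for b in range(a + 1, 3):
                    ref = nx.dijkstra_path_length(g, cells[a], cells[b])
                    assert d.values[a, b] == pytest.approx(ref, abs=1e-9)

    def test_raising_resistance_never_shortens_paths(self):
        r = simulate_resistance_raster(12, 12, cell_size=2.0, roughness=2.0, seed=7)
        pts = np.array([[2.0, 2.0], [20.0, 20.0], [4.0, 18.0]])
        base = least_cost_distances(r, pts, list("abc"))
        raised_vals = r.values.copy()
        raised_vals[4:8, 4:8] *= 5.0
        raised = least_cost_distances(
            ResistanceRaster(raised_vals, r.origin, r.cell_size), pts, list("abc")
        )
        assert np.all(raised.values >= base.values - 1e-9)

    def test_point_outside_raster_names_the_lek(self):
        r = ResistanceRaster(np.ones((5, 5)), cell_size=1.0)
        with pytest.raises(ValueError, match="far_lek"):
            least_cost_distances(r, np.array([[2.0, 2.0], [99.0, 2.0]]), ["ok", "far_lek"])

    def test_nodata_cell_rejected(self):
        vals = np.ones((5, 5))
        vals[2, 2] = -9999.0
        r = ResistanceRaster(vals, cell_size=1.0)
        with pytest.raises(ValueError, match="swamp"):
            least_cost_distances(r, np.array([[0.5, 0.5], [2.5, 2.5]]), ["ok", "swamp"])


class TestGeographicDistances:
    def test_right_triangle_hypotenuse(self):
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [3.0, 4.0]])
        d = geographic_distances(pts, list("abc"))
        assert d.values[0, 2] == pytest.approx(5.0)

    def test_identical_points_zero(self):
        d = geographic_distances(np.array([[1.0, 1.0], [1.0, 1.0]]), ["a", "b"])
        assert d.values[0, 1] == 0.0

    def test_one_degree_latitude_great_circle(self):
        d = geographic_distances(
            np.array([[39.0, -116.0], [40.0, -116.0]]), ["a", "b"], mode="latlon"
        )
        assert d.values[0, 1] == pytest.approx(111.2, abs=0.3)

    def test_missing_coordinates_rejected(self):
        with pytest.raises(ValueError):
            geographic_distances(np.array([[0.0, np.nan], [1.0, 1.0]]), ["a", "b"])


class TestMantel:
    def test_affine_dependence_gives_r_one_and_minimal_p(self):
        rng = np.random.default_rng(8)
        d1 = random_distance_matrix(rng, 10)
        d2 = PairwiseLekMatrix(d1.labels, 0.5 + 2.0 * d1.values, "geographic")
        r, r2, res = mantel_test(d1, d2, n_perm=999, seed=1)
        assert r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_matches_skbio_mantel_r(self):
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(9)
        d1 = random_distance_matrix(rng, 12)
        d2 = random_distance_matrix(rng, 12, labels=d1.labels)
        r, _, _ = mantel_test(d1, d2, n_perm=9, seed=0)
        ref_r, _, _ = skbio_mantel(d1.values, d2.values, permutations=0)
        assert r == pytest.approx(ref_r, abs=1e-10)

    def test_invariant_to_common_relabeling(self):
        rng = np.random.default_rng(10)
        d1 = random_distance_matrix(rng, 8)
        d2 = random_distance_matrix(rng, 8, labels=d1.labels)
        perm = rng.permutation(8)
        labels2 = [d1.labels[i] for i in perm]
        d1p = d1.reordered(labels2)
        d2p = d2.reordered(labels2)
        r1, _, _ = mantel_test(d1, d2, n_perm=9, seed=0)
        r2_, _, _ = mantel_test(d1p, d2p, n_perm=9, seed=0)
        assert r1 == pytest.approx(r2_, abs=1e-12)

    def test_zero_variance_matrix_rejected(self):
        flat = PairwiseLekMatrix(list("abc"), np.ones((3, 3)) - np.eye(3), "geographic")
        with pytest.raises(ValueError):
            mantel_test(flat, flat, 9, 0)


class TestMrm:
    def test_single_predictor_r2_equals_mantel_r_squared(self):
        rng = np.random.default_rng(11)
        d1 = random_distance_matrix(rng, 10)
        d2 = random_distance_matrix(rng, 10, labels=d1.labels)
        _, mantel_r2, _ = mantel_test(d1, d2, n_perm=9, seed=0)
        res = mrm(d1, [d2], n_perm=9, seed=0)
        assert res["r2"] == pytest.approx(mantel_r2, abs=1e-10)

    def test_adding_predictor_never_decreases_r2(self):
        rng = np.random.default_rng(12)
        y = random_distance_matrix(rng, 9)
        x1 = random_distance_matrix(rng, 9, labels=y.labels)
        x2 = random_distance_matrix(rng, 9, labels=y.labels)
        r2_one = mrm(y, [x1], n_perm=9, seed=0)["r2"]
        r2_two = mrm(y, [x1, x2], n_perm=9, seed=0)["r2"]
        assert r2_two >= r2_one - 1e-12

    def test_recovers_known_regression_slope(self):
        # response built as 0.142 * distance + 0.179 + noise
        rng = np.random.default_rng(13)
        slopes = []
        for _ in range(10):
            x = random_distance_matrix(rng, 10)
            noise = rng.normal(0, 0.05, size=x.values.shape)
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0)
            yv = 0.179 + 0.142 * x.values + noise
            np.fill_diagonal(yv, 0)
            y = PairwiseLekMatrix(x.labels, yv, "nei_d")
            res = mrm(y, [x], n_perm=9, seed=0)
            slopes.append(res["coefficients"][1])
        assert np.mean(slopes) == pytest.approx(0.142, abs=0.02)
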