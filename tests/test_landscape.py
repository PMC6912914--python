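"""Terrain ruggedness, transforms, and landscape distance oracles."""

import networkx as nx
import numpy as np
import pytest

import landgen as lg
from landgen.core import Raster, SiteSet
from landgen.landscape import euclidean_cell_distances

from _oracles import dense_effective_resistance


def flat_raster(nr, nc, value=0.0, cellsize=1.0):
    return Raster(values=np.full((nr, nc), value), cellsize=cellsize)


def sites_at(cells, raster):
    s = SiteSet(site_ids=[f"P{i}" for i in range(len(cells))],
                rowcol=np.array(cells))
    s.snap_to(raster)
    return s


class TestTRI:
    def test_flat_surface_zero_everywhere(self):
        tri = lg.terrain_ruggedness(flat_raster(6, 6, 3.0))
        assert np.allclose(tri.values, 0.0)

    def test_single_peak_hand_computation(self):
        v = np.zeros((7, 7))
        v[3, 3] = 8.0
        tri = lg.terrain_ruggedness(Raster(values=v, cellsize=1.0))
        assert tri.values[3, 3] == pytest.approx(8.0)
        assert tri.values[2, 2] == pytest.approx(1.0)  # one of 8 neighbours

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.random((9, 9))
        t0 = lg.terrain_ruggedness(Raster(values=v, cellsize=1.0))
        t1 = lg.terrain_ruggedness(Raster(values=v + 100.0, cellsize=1.0))
        assert np.allclose(t0.values, t1.values)

    def test_riley_variant_and_tiny_raster(self):
        v = np.array([[0.0, 3.0], [4.0, 0.0]])
        tri = lg.terrain_ruggedness(Raster(values=v, cellsize=1.0), method="riley")
        assert tri.values[0, 0] == pytest.approx(5.0)  # sqrt(9+16)
        with pytest.raises(ValueError):
            lg.terrain_ruggedness(Raster(values=np.zeros((1, 5)), cellsize=1.0))


class TestAggregate:
    def test_factor_one_identity(self):
        rng = np.random.default_rng(1)
        r = Raster(values=rng.random((6, 6)), cellsize=2.0)
        out = lg.aggregate(r, 2.0)
        assert np.allclose(out.values, r.values)

    def test_constant_block_mean(self):
        r = flat_raster(4, 4, 7.0, cellsize=1.0)
        out = lg.aggregate(r, 2.0)
        assert out.shape == (2, 2)
        assert np.allclose(out.values, 7.0)

    def test_checkerboard_averages_to_half(self):
        v = np.indices((8, 8)).sum(axis=0) % 2
        out = lg.aggregate(Raster(values=v.astype(float), cellsize=1.0), 2.0)
        assert np.allclose(out.values, 0.5)

    def test_majority_masked_block_becomes_nodata(self):
        v = np.ones((4, 4))
        mask = np.zeros((4, 4), dtype=bool)
        mask[:2, :2] = True
        mask[0, 2] = mask[1, 2] = mask[0, 3] = True
        r = Raster(values=v, cellsize=1.0, nodata_mask=mask)
        out = lg.aggregate(r, 2.0)
        assert out.nodata_mask[0, 0]       # 4/4 masked
        assert out.nodata_mask[0, 1]       # 3/4 masked
        assert not out.nodata_mask[1, 0]


class TestTransform:
    def test_monomolecular_endpoints(self):
        spec = lg.TransformSpec("monomolecular", shape=0.5, magnitude=40.0)
        out = spec.curve(np.array([0.0, 1.0]))
        assert out[0] == pytest.approx(1.0)
        assert out[1] == pytest.approx(40.0)

    def test_reverse_is_monomolecular_of_flipped_input(self):
        rng = np.random.default_rng(2)
        x = rng.random(50)
        a = lg.TransformSpec("reverse_monomolecular", 0.3, 20.0).curve(x)
        b = lg.TransformSpec("monomolecular", 0.3, 20.0).curve(1 - x)
        assert np.allclose(a, b)

    def test_inverse_reverse_resists_only_extreme_ruggedness(self):
        """Small shape: resistance stays near 1 over most of the range and
        rises only near the rugged end (lowlands cheap, mountains costly)."""
        spec = lg.TransformSpec("inverse_reverse_monomolecular", 0.05, 100.0)
        x = np.linspace(0, 1, 101)
        y = spec.curve(x)
        assert y[0] == pytest.approx(1.0)
        assert y[-1] == pytest.approx(100.0)
        assert (y[:85] < 10).all()          # cheap over most of the range
        assert np.all(np.diff(y) >= -1e-9)  # monotone

    def test_surface_output_bounded_and_rescaled(self):
        rng = np.random.default_rng(3)
        tri = Raster(values=rng.random((8, 8)) * 500, cellsize=1.0)
        out = lg.transform_surface(tri, lg.TransformSpec("monomolecular", 1.0, 10.0))
        assert out.values.min() == pytest.approx(1.0)
        assert out.values.max() == pytest.approx(10.0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            lg.TransformSpec("monomolecular", shape=0.0)
        with pytest.raises(ValueError):
            lg.TransformSpec("monomolecular", magnitude=0.5)
        with pytest.raises(ValueError):
            lg.TransformSpec("gaussian")


class TestLeastCost:
    def test_uniform_surface_distance_is_path_length(self):
        r = flat_raster(3, 8, 1.0, cellsize=2.5)
        s = sites_at([[1, 1], [1, 5]], r)
        d = lg.least_cost_distances(r, s)
        assert d.values[0, 1] == pytest.approx(4 * 2.5)

    def test_matches_networkx_dijkstra_on_random_surfaces(self):
        rng = np.random.default_rng(4)
        for rep in range(10):
            vals = 1 + 9 * rng.random((12, 12))
            r = Raster(values=vals, cellsize=1.0)
            s = sites_at([[0, 0], [11, 11], [5, 2], [2, 9]], r)
            d = lg.least_cost_distances(r, s)
            G = nx.Graph()
            for i in range(12):
                for j in range(12):
                    for di, dj in ((0, 1), (1, 0)):
                        if i + di < 12 and j + dj < 12:
                            w = (vals[i, j] + vals[i + di, j + dj]) / 2
                            G.add_edge((i, j), (i + di, j + dj), weight=w)
            for a in range(4):
                for b in range(a + 1, 4):
                    ref = nx.dijkstra_path_length(
                        G, tuple(s.snapped_cells[a]), tuple(s.snapped_cells[b]))
                    assert d.values[a, b] == pytest.approx(ref, abs=1e-9)

    def test_raising_resistance_on_optimal_path_increases_distance(self):
        vals = np.ones((5, 5))
        vals[1:, :] = 50.0  # unique cheap corridor along row 0
        r = Raster(values=vals, cellsize=1.0)
        s = sites_at([[0, 0], [0, 4]], r)
        d0 = lg.least_cost_distances(r, s).values[0, 1]
        vals2 = vals.copy()
        vals2[0, 1:4] += 1.0
        d1 = lg.least_cost_distances(Raster(values=vals2, cellsize=1.0), s).values[0, 1]
        assert d1 > d0

    def test_doubling_resistance_doubles_distances(self):
        rng = np.random.default_rng(5)
        vals = 1 + rng.random((8, 8))
        r1 = Raster(values=vals, cellsize=1.0)
        r2 = Raster(values=2 * vals, cellsize=1.0)
        s = sites_at([[0, 0], [7, 7], [3, 4]], r1)
        d1 = lg.least_cost_distances(r1, s).values
        d2 = lg.least_cost_distances(r2, s).values
        assert np.allclose(d2, 2 * d1)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(6)
        vals = 1 + 4 * rng.random((10, 10))
        r = Raster(values=vals, cellsize=1.0)
        s = sites_at([[0, 0], [9, 9], [0, 9], [5, 5]], r)
        d = lg.least_cost_distances(r, s).values
        for a in range(4):
            for b in range(4):
                for c in range(4):
                    assert d[a, b] <= d[a, c] + d[c, b] + 1e-9

    def test_disconnected_sites_error_names_pair(self):
        vals = np.ones((3, 5))
        mask = np.zeros((3, 5), dtype=bool)
        mask[:, 2] = True
        r = Raster(values=vals, cellsize=1.0, nodata_mask=mask)
        s = SiteSet(site_ids=["west", "east"], rowcol=np.array([[1, 0], [1, 4]]))
        s.snapped_cells = np.array([[1, 0], [1, 4]])
        with pytest.raises(ValueError, match="west"):
            lg.least_cost_distances(r, s)


class TestCommute:
    def test_two_node_closed_form(self):
        # single edge, resistance 1 on both cells, cellsize 1 -> conductance 1
        r = flat_raster(1, 2, 1.0)
        s = sites_at([[0, 0], [0, 1]], r)
        c = lg.commute_distances(r, s)
        assert c.values[0, 1] == pytest.approx(2.0)

    def test_path_graph_series_resistance(self):
        # 1 - 2 - 3 with unit conductances: vol = 4, R13 = 2, commute = 8
        r = flat_raster(1, 3, 1.0)
        s = sites_at([[0, 0], [0, 2]], r)
        c = lg.commute_distances(r, s)
        assert c.values[0, 1] == pytest.approx(8.0)

    def test_matches_dense_pseudoinverse_oracle(self):
        rng = np.random.default_rng(7)
        for rep in range(5):
            vals = 1 + 9 * rng.random((10, 10))
            r = Raster(values=vals, cellsize=1.0)
            s = sites_at([[0, 0], [9, 9], [4, 4], [2, 7]], r)
            c = lg.commute_distances(r, s)
            edges = []
            idx = np.arange(100).reshape(10, 10)
            for i in range(10):
                for j in range(10):
                    for di, dj in ((0, 1), (1, 0)):
                        if i + di < 10 and j + dj < 10:
                            cond = 2.0 / (vals[i, j] + vals[i + di, j + dj])
                            edges.append((idx[i, j], idx[i + di, j + dj], cond))
            reff = dense_effective_resistance(100, edges)
            vol = 2 * sum(c3 for _, _, c3 in edges)
            nodes = [idx[a, b] for a, b in s.snapped_cells]
            for a in range(4):
                for b in range(a + 1, 4):
                    assert c.values[a, b] == pytest.approx(
                        vol * reff[nodes[a], nodes[b]], abs=1e-8)

    def test_parallel_paths_cheaper_than_single_corridor(self):
        """On a ladder, commute/vol (= R_eff) is below the least-cost
        resistance of any single path (Rayleigh monotonicity)."""
        r = flat_raster(2, 6, 1.0)
        s = sites_at([[0, 0], [0, 5]], r)
        c = lg.commute_distances(r, s)
        vol = 2 * (2 * 5 + 6) * 1.0  # 16 unit-conductance edges
        reff = c.values[0, 1] / vol
        assert reff < 5.0  # single top-row path has resistance 5

    def test_corridor_grid_matches_least_cost(self):
        """On a 1-D corridor (series-only graph) R_eff equals the
        least-cost distance."""
        rng = np.random.default_rng(8)
        vals = (1 + 4 * rng.random((1, 7)))
        r = Raster(values=vals, cellsize=1.0)
        s = sites_at([[0, 0], [0, 6]], r)
        lcp = lg.least_cost_distances(r, s).values[0, 1]
        c = lg.commute_distances(r, s)
        # vol = 2 * sum of edge conductances
        conds = [2.0 / (vals[0, k] + vals[0, k + 1]) for k in range(6)]
        vol = 2 * sum(conds)
        assert c.values[0, 1] / vol == pytest.approx(lcp, abs=1e-9)

    def test_scaling_resistance_leaves_commute_unchanged(self):
        """Uniformly doubling resistance halves vol and doubles R_eff, so
        the commute distance (their product) is unchanged."""
        rng = np.random.default_rng(9)
        vals = 1 + rng.random((6, 6))
        s_cells = [[0, 0], [5, 5], [2, 3]]
        c1 = lg.commute_distances(Raster(values=vals, cellsize=1.0),
                                  sites_at(s_cells, Raster(values=vals, cellsize=1.0)))
        c2 = lg.commute_distances(Raster(values=2 * vals, cellsize=1.0),
                                  sites_at(s_cells, Raster(values=2 * vals, cellsize=1.0)))
        assert np.allclose(c1.values, c2.values)

    def test_commute_gram_form_is_psd(self):
        """Commute distance embeds as a squared Euclidean metric: the
        double-centered -D/2 matrix is PSD."""
        rng = np.random.default_rng(10)
        vals = 1 + 3 * rng.random((7, 7))
        r = Raster(values=vals, cellsize=1.0)
        s = sites_at([[0, 0], [6, 6], [0, 6], [6, 0], [3, 3]], r)
        D = lg.commute_distances(r, s).values
        n = D.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        G = -0.5 * J @ D @ J
        assert np.linalg.eigvalsh(G).min() > -1e-8


class TestGeographic:
    def test_identical_points_zero(self):
        s = SiteSet(site_ids=["a", "b"], lonlat=np.array([[147.0, -5.0],
                                                          [147.0, -5.0]]))
        assert lg.geographic_distances(s).values[0, 1] == 0.0

    def test_antipodal_half_circumference(self):
        s = SiteSet(site_ids=["a", "b"], lonlat=np.array([[0.0, 0.0],
                                                          [180.0, 0.0]]))
        d = lg.geographic_distances(s).values[0, 1]
        assert d == pytest.approx(np.pi * 6371.0088, rel=1e-6)

    def test_field_sites_match_independent_spherical_oracle(self):
        # site 1 (Papuan) and site 2 (Gulf) coordinates from the sampling table
        lonlat = np.array([[148.571044, -9.210437], [146.531037, -7.840529]])
        s = SiteSet(site_ids=["1", "2"], lonlat=lonlat)
        d = lg.geographic_distances(s).values[0, 1]
        # spherical law of cosines, written independently
        lam = np.radians(lonlat[:, 0])
        phi = np.radians(lonlat[:, 1])
        ref = 6371.0088 * np.arccos(
            np.sin(phi[0]) * np.sin(phi[1])
            + np.cos(phi[0]) * np.cos(phi[1]) * np.cos(lam[1] - lam[0]))
        assert d == pytest.approx(ref, rel=0.005)
        assert 250 < d < 300  # ~270 km apart

    def test_invalid_latitude_rejected(self):
        s = SiteSet(site_ids=["a", "b"], lonlat=np.array([[0.0, 95.0],
                                                          [10.0, 0.0]]))
        with pytest.raises(ValueError, match="coordinates"):
            lg.geographic_distances(s)

    def test_euclidean_fallback_for_grid_sites(self):
        r = flat_raster(5, 5, 1.0, cellsize=2.0)
        s = sites_at([[0, 0], [0, 3], [4, 0]], r)
        d = euclidean_cell_distances(r, s)
        assert d.values[0, 1] == pytest.approx(6.0)
        assert d.values[0, 2] == pytest.approx(8.0)


def test_asc_roundtrip(tmp_path):
    rng = np.random.default_rng(11)
    v = rng.random((6, 8)) * 100
    mask = np.zeros((6, 8), dtype=bool)
    mask[2, 3] = True
    r = Raster(values=v, cellsize=90.0, origin=(10.0, 5000.0), nodata_mask=mask)
    p = tmp_path / "r.asc"
    r.write_asc(str(p))
    r2 = Raster.read_asc(str(p))
    assert r2.cellsize == 90.0
    assert r2.nodata_mask[2, 3]
    assert np.allclose(r2.values[~mask], r.values[~mask], atol=1e-4)
    assert r2.origin == pytest.approx(r.origin)
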