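"""Mesh construction, discrete geometry, and remeshing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinesim import (
    ConfigurationError, GeometryError, MembraneMesh, ModelParams,
    compute_geometry, init_spine_mesh, remesh,
)
from .conftest import regular_polygon


class TestInitSpineMesh:
    def test_plateau_levels_follow_from_the_radii(self, params, spine_mesh):
        # the circle points where x = r_PSD (top) / x = r_neck (bottom)
        assert spine_mesh.h_PSD == pytest.approx(
            math.sqrt(params.r_s**2 - params.r_PSD**2))
        assert spine_mesh.h_PSD == pytest.approx(0.34997, abs=1e-5)
        assert spine_mesh.h_neck == pytest.approx(
            -math.sqrt(params.r_s**2 - params.r_neck**2))
        assert spine_mesh.h_neck == pytest.approx(-0.48999, abs=1e-5)

    def test_vertices_projected_onto_plateaus_and_fixed(self, spine_mesh):
        y = spine_mesh.positions[:, 1]
        assert np.all(y <= spine_mesh.h_PSD + 1e-12)
        assert np.all(y >= spine_mesh.h_neck - 1e-12)
        on_psd = np.isclose(y, spine_mesh.h_PSD)
        on_neck = np.isclose(y, spine_mesh.h_neck)
        assert np.array_equal(spine_mesh.fixed, on_psd | on_neck)
        assert on_psd.sum() >= 2 and on_neck.sum() >= 2

    def test_vertex_count_matches_target_edge_length(self, params, spine_mesh):
        expected = round(2 * math.pi * params.r_s / params.delta_s)
        assert spine_mesh.n_vertices == expected

    def test_counterclockwise_simple_polygon(self, spine_mesh):
        assert compute_geometry(spine_mesh).area_enclosed > 0

    def test_degenerate_radii_give_plain_circle(self):
        p = ModelParams().replace(r_PSD=1e-9, r_neck=1e-9)
        mesh = init_spine_mesh(p)
        # constraints are vacuous except possibly at the exact poles
        assert mesh.fixed.sum() <= 2
        r = np.linalg.norm(mesh.positions[~mesh.fixed], axis=1)
        assert np.allclose(r, p.r_s)

    def test_invalid_radii_raise(self):
        with pytest.raises(ConfigurationError):
            init_spine_mesh(ModelParams().replace(r_PSD=0.5))


class TestComputeGeometry:
    def test_unit_square(self, unit_square):
        geo = compute_geometry(unit_square)
        assert geo.area_enclosed == pytest.approx(1.0)
        assert geo.boundary_length == pytest.approx(4.0)

    def test_regular_polygon_area_and_curvature(self, circle_100):
        geo = compute_geometry(circle_100)
        n, r = 100, 0.5
        assert geo.area_enclosed == pytest.approx(
            (n / 2) * r**2 * math.sin(2 * math.pi / n))
        assert geo.area_enclosed == pytest.approx(0.784882, abs=1e-6)
        # all vertices lie on a circle of radius r: circumradius is exact
        assert np.allclose(geo.curvature, 1.0 / r, rtol=1e-6)

    def test_fine_polygon_curvature_converges_to_circle(self):
        geo = compute_geometry(regular_polygon(4000, r=0.25))
        assert np.allclose(geo.curvature, 4.0, rtol=1e-6)

    def test_arc_weights_sum_to_boundary_length(self, pentagon):
        geo = compute_geometry(pentagon)
        assert geo.ds.sum() == pytest.approx(geo.boundary_length)
        assert geo.edge_lengths.sum() == pytest.approx(geo.boundary_length)

    def test_collinear_triple_has_zero_curvature(self):
        pos = np.array([[0.0, 0.0], [0.5, 0.0], [1.0, 0.0], [0.5, 1.0]])
        mesh = MembraneMesh(pos, np.zeros(4, bool), np.nan, np.nan, 0.03)
        geo = compute_geometry(mesh)
        assert geo.curvature[1] == 0.0

    def test_duplicate_consecutive_vertices_raise(self):
        pos = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0], [0.5, 1.0]])
        mesh = MembraneMesh(pos, np.zeros(4, bool), np.nan, np.nan, 0.03)
        with pytest.raises(GeometryError):
            compute_geometry(mesh)

    def test_convex_ccw_polygon_has_positive_curvature(self, pentagon):
        assert np.all(compute_geometry(pentagon).curvature > 0)


class TestRemesh:
    def test_long_edge_is_split_at_midpoint(self):
        p = ModelParams()
        pos = np.array([[0.0, 0.0], [0.05, 0.0], [0.05, 0.05], [0.0, 0.05]])
        mesh = MembraneMesh(pos, np.zeros(4, bool), np.nan, np.nan, p.delta_s)
        out = remesh(mesh, p)
        assert out.n_vertices > 4
        # the midpoint of the first edge (length 0.05 > d_max = 0.04) appears
        assert any(np.allclose(v, [0.025, 0.0]) for v in out.positions)

    def test_short_free_edge_loses_one_vertex(self):
        p = ModelParams()
        # octagon-ish ring with one deliberately short edge
        theta = 2 * np.pi * np.arange(12) / 12
        pos = 0.05 * np.column_stack([np.cos(theta), np.sin(theta)])
        pos = np.vstack([pos, [pos[-1] + [0.001, 0.0005]]])  # short edge
        mesh = MembraneMesh(pos, np.zeros(len(pos), bool), np.nan, np.nan,
                            p.delta_s)
        out = remesh(mesh, p)
        lengths = np.linalg.norm(
            np.roll(out.positions, -1, axis=0) - out.positions, axis=1)
        assert np.all(lengths >= p.d_min)

    def test_in_bounds_mesh_is_untouched(self, params, resting):
        mesh = resting[0]
        out = remesh(mesh, params)
        assert np.array_equal(out.positions, mesh.positions)

    def test_idempotent(self, params, spine_mesh):
        once = remesh(spine_mesh, params)
        twice = remesh(once, params)
        assert np.array_equal(once.positions, twice.positions)
        assert np.array_equal(once.fixed, twice.fixed)

    def test_fixed_vertices_survive_bitwise(self, params, spine_mesh):
        before = spine_mesh.positions[spine_mesh.fixed]
        out = remesh(spine_mesh, params)
        after = out.positions[out.fixed]
        # every original fixed vertex is still present, bit-for-bit
        for v in before:
            assert any((after == v).all(axis=1))

    def test_free_adjacent_edges_within_bounds(self, params):
        rng = np.random.default_rng(5)
        theta = np.sort(rng.uniform(0, 2 * np.pi, 40))
        r = rng.uniform(0.3, 0.6, 40)
        pos = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        mesh = MembraneMesh(pos, np.zeros(40, bool), np.nan, np.nan,
                            params.delta_s)
        out = remesh(mesh, params)
        lengths = np.linalg.norm(
            np.roll(out.positions, -1, axis=0) - out.positions, axis=1)
        assert np.all(lengths <= params.d_max + 1e-12)
        assert np.all(lengths >= params.d_min - 1e-12)

    def test_midpoint_between_fixed_vertices_is_fixed(self):
        p = ModelParams()
        pos = np.array([[0.0, 0.1], [0.0, 0.0], [0.06, 0.0], [0.06, 0.1]])
        fixed = np.array([False, True, True, False])
        mesh = MembraneMesh(pos, fixed, 0.0, np.nan, p.delta_s)
        out = remesh(mesh, p)
        mid = np.flatnonzero(np.all(np.isclose(out.positions, [0.03, 0.0]),
                                    axis=1))
        assert len(mid) == 1 and out.fixed[mid[0]]

    def test_area_change_is_second_order(self, params, spine_mesh):
        # splitting/collapsing edges perturbs the shoelace area only by
        # O(d_max^2) per modified edge
        before = compute_geometry(spine_mesh).area_enclosed
        out = remesh(spine_mesh, params)
        after = compute_geometry(out).area_enclosed
        assert abs(after - before) < 1e-3

    def test_collapse_below_triangle_raises(self):
        p = ModelParams()
        pos = 0.001 * np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 1.0]])
        mesh = MembraneMesh(pos, np.zeros(3, bool), np.nan, np.nan, p.delta_s)
        with pytest.raises(GeometryError):
            remesh(mesh, p)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(8, 60), st.floats(0.1, 0.8))
def test_remesh_idempotence_property(n, r):
    """Remeshing any regular polygon is idempotent and bound-respecting."""
    params = ModelParams()
    mesh = regular_polygon(n, r=r)
    out = remesh(mesh, params)
    again = remesh(out, params)
    assert np.array_equal(out.positions, again.positions)
    lengths = np.linalg.norm(
        np.roll(out.positions, -1, axis=0) - out.positions, axis=1)
    assert np.all(lengths <= params.d_max + 1e-12)
    assert np.all(lengths >= params.d_min - 1e-12)
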