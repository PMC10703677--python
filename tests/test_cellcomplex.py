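"""Foam geometry: areas, volumes, junction angles, gradients, curvature."""

import numpy as np
import pytest

from foaminfer import cellcomplex as cx
from foaminfer.delwatershed import MultimaterialMesh

TWO_PI = 2 * np.pi


class TestSphereGeometry:
    def test_volume_area_curvature(self, sphere_mesh):
        cc = cx.build_cell_complex(sphere_mesh)
        assert cc.cells[1].volume == pytest.approx(4 * np.pi / 3, rel=5e-3)
        itf = cc.interfaces[(0, 1)]
        assert itf.area == pytest.approx(4 * np.pi, rel=5e-3)
        assert itf.H_plain == pytest.approx(2.0, rel=0.01)
        assert itf.H_var == pytest.approx(2.0, rel=0.01)
        assert np.allclose(cc.cells[1].centroid, 0.0, atol=1e-9)

    def test_scaling_laws(self, sphere_mesh):
        s = 2.5
        scaled = MultimaterialMesh(sphere_mesh.vertices * s,
                                   sphere_mesh.triangles,
                                   sphere_mesh.materials)
        a = cx.build_cell_complex(sphere_mesh)
        b = cx.build_cell_complex(scaled)
        assert b.cells[1].volume == pytest.approx(s ** 3 * a.cells[1].volume)
        assert b.interfaces[(0, 1)].area == pytest.approx(
            s ** 2 * a.interfaces[(0, 1)].area)
        assert b.interfaces[(0, 1)].H_var == pytest.approx(
            a.interfaces[(0, 1)].H_var / s, rel=1e-9)

    def test_rigid_motion_invariance(self, sphere_mesh):
        rng = np.random.default_rng(4)
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = MultimaterialMesh(sphere_mesh.vertices @ q.T + [3.0, -1.0, 2.0],
                                  sphere_mesh.triangles, sphere_mesh.materials)
        a = cx.build_cell_complex(sphere_mesh)
        b = cx.build_cell_complex(moved)
        assert b.cells[1].volume == pytest.approx(a.cells[1].volume, rel=1e-9)
        assert b.interfaces[(0, 1)].H_var == pytest.approx(
            a.interfaces[(0, 1)].H_var, rel=1e-6)


class TestVertexGradients:
    def test_volume_gradient_translation_invariance(self, sphere_mesh):
        g = cx.vertex_gradients(sphere_mesh)
        assert np.abs(g.volume_grad(1).sum(axis=0)).max() < 1e-12

    def test_area_gradient_matches_finite_differences(self, sphere_mesh):
        g = cx.vertex_gradients(sphere_mesh)
        gA = g.area_grad((0, 1))
        rng = np.random.default_rng(0)
        h = 1e-6
        for v in rng.choice(sphere_mesh.n_vertices, 20, replace=False):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            vp = sphere_mesh.vertices.copy()
            vm = sphere_mesh.vertices.copy()
            vp[v] += h * d
            vm[v] -= h * d
            ap = MultimaterialMesh(vp, sphere_mesh.triangles,
                                   sphere_mesh.materials).triangle_areas().sum()
            am = MultimaterialMesh(vm, sphere_mesh.triangles,
                                   sphere_mesh.materials).triangle_areas().sum()
            fd = (ap - am) / (2 * h)
            assert np.dot(gA[v], d) == pytest.approx(fd, rel=1e-4, abs=1e-9)

    def test_volume_gradient_matches_finite_differences(self, sphere_mesh):
        g = cx.vertex_gradients(sphere_mesh)
        gV = g.volume_grad(1)
        rng = np.random.default_rng(1)
        h = 1e-6
        for v in rng.choice(sphere_mesh.n_vertices, 10, replace=False):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            vp = sphere_mesh.vertices.copy()
            vm = sphere_mesh.vertices.copy()
            vp[v] += h * d
            vm[v] -= h * d
            fp = MultimaterialMesh(vp, sphere_mesh.triangles,
                                   sphere_mesh.materials).enclosed_volume(1)
            fm = MultimaterialMesh(vm, sphere_mesh.triangles,
                                   sphere_mesh.materials).enclosed_volume(1)
            fd = (fp - fm) / (2 * h)
            assert np.dot(gV[v], d) == pytest.approx(fd, rel=1e-4, abs=1e-12)

    def test_single_triangle_area_gradient_is_in_plane(self):
        mesh = MultimaterialMesh(np.array([[0., 0, 0], [1, 0, 0], [0, 1, 0]]),
                                 np.array([[0, 1, 2]]), np.array([[0, 1]]))
        g = cx.vertex_gradients(mesh)
        gA = g.area_grad((0, 1))
        assert np.allclose(gA[:, 2], 0.0)

    def test_sphere_volume_gradient_is_area_weighted_normal(self, sphere_mesh):
        g = cx.vertex_gradients(sphere_mesh)
        gV = g.volume_grad(1)
        n_hat = sphere_mesh.vertices / np.linalg.norm(sphere_mesh.vertices,
                                                      axis=1, keepdims=True)
        total = np.einsum("ij,ij->i", gV, n_hat).sum()
        area = sphere_mesh.triangle_areas().sum()
        assert total == pytest.approx(area, rel=0.01)


class TestJunctionAngles:
    def test_tripod_gives_exact_120_degrees(self, tripod_mesh):
        cc = cx.build_cell_complex(tripod_mesh, validate=False,
                                   compute_curvature=False)
        assert cc.n_j == 1
        jn = next(iter(cc.junctions.values()))
        for ang in jn.angles.values():
            assert ang == pytest.approx(TWO_PI / 3, abs=1e-9)

    def test_angle_sum_is_exactly_two_pi(self, tripod_mesh):
        cc = cx.build_cell_complex(tripod_mesh, validate=False,
                                   compute_curvature=False)
        jn = next(iter(cc.junctions.values()))
        assert sum(jn.angles.values()) == pytest.approx(TWO_PI, abs=1e-9)

    def test_secant_and_fit_agree_on_flat_interfaces(self, tripod_mesh):
        a = cx.build_cell_complex(tripod_mesh, validate=False,
                                  compute_curvature=False,
                                  angle_method="secant")
        b = cx.build_cell_complex(tripod_mesh, validate=False,
                                  compute_curvature=False,
                                  angle_method="cmc_fit")
        ja = next(iter(a.junctions.values()))
        jb = next(iter(b.junctions.values()))
        for p in ja.angles:
            assert ja.angles[p] == pytest.approx(jb.angles[p], abs=1e-6)


class TestCurvature:
    def test_flat_interface_curvature_is_zero(self, relaxed_doublet):
        # equal target volumes and equal tensions: the contact disc is flat
        _, state = relaxed_doublet
        cc = cx.build_cell_complex(state.mesh)
        itf = cc.interfaces[(1, 2)]
        # |H| well below the cell-medium curvature scale (~2/R ~ 0.13)
        assert abs(itf.H_var) < 0.01

    def test_doublet_junction_circle_length(self, relaxed_doublet):
        scenario, state = relaxed_doublet
        cc = cx.build_cell_complex(state.mesh)
        assert cc.n_j == 1
        jn = next(iter(cc.junctions.values()))
        pts = state.mesh.vertices[np.unique(jn.edges)]
        center = pts.mean(axis=0)
        radius = np.linalg.norm(pts - center, axis=1).mean()
        assert jn.length == pytest.approx(TWO_PI * radius, rel=0.02)

    def test_curvature_times_tension_matches_pressure(self, relaxed_doublet):
        scenario, state = relaxed_doublet
        cc = cx.build_cell_complex(state.mesh)
        for pair in ((0, 1), (0, 2)):
            cell = pair[1]
            itf = cc.interfaces[pair]
            expected = state.pressures[cell]
            assert itf.H_var * scenario.tension(*pair) == pytest.approx(
                expected, rel=0.04)


class TestComplexBookkeeping:
    def test_doublet_counts(self, relaxed_doublet):
        _, state = relaxed_doublet
        cc = cx.build_cell_complex(state.mesh)
        assert cc.n_c == 2
        assert sorted(cc.interfaces) == [(0, 1), (0, 2), (1, 2)]
        assert cc.n_j == 1

    def test_csv_export(self, tmp_path, relaxed_doublet):
        _, state = relaxed_doublet
        cc = cx.build_cell_complex(state.mesh)
        out = cc.to_csv(tmp_path)
        import pandas as pd
        interfaces = pd.read_csv(out / "interfaces.csv")
        assert set(interfaces.columns) >= {"i", "j", "area", "H_var"}
        assert len(interfaces) == 3
        cells = pd.read_csv(out / "cells.csv")
        assert len(cells) == 2

    def test_label_permutation_equivariance(self, relaxed_doublet):
        _, state = relaxed_doublet
        mesh = state.mesh
        permuted = mesh.permute_labels({1: 2, 2: 1})
        a = cx.build_cell_complex(mesh)
        b = cx.build_cell_complex(permuted)
        assert a.cells[1].volume == pytest.approx(b.cells[2].volume)
        assert a.interfaces[(0, 1)].area == pytest.approx(
            b.interfaces[(0, 2)].area)
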