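"""Delaunay-watershed meshing: sampling, dual graph, watershed, extraction."""

import numpy as np
import pytest

from foaminfer.segio import DistanceMap, LabelImage, boundary_edt
from foaminfer import delwatershed as dw


class TestSampling:
    def test_planar_case_covers_membrane_and_interiors(self, half_space_image):
        dmap = boundary_edt(half_space_image)
        pts = dw.sample_seed_points(dmap, 5)
        # membrane points near the separating plane z in {17, 18}
        near_plane = np.abs(pts[:, 2] - 17.5) <= 1.0
        assert near_plane.sum() >= 10
        # interior maxima on both sides
        assert np.any(pts[:, 2] < 12) and np.any(pts[:, 2] > 23)
        # the 8 corners are present
        for corner in [(0, 0, 0), (39, 39, 39), (0, 39, 0)]:
            assert np.any(np.all(pts == corner, axis=1))

    def test_constant_map_rejected(self):
        with pytest.raises(dw.DegeneratePointSetError):
            dw.sample_seed_points(DistanceMap(np.ones((16, 16, 16))), 5)

    def test_even_pool_size_rejected(self, half_space_image):
        dmap = boundary_edt(half_space_image)
        with pytest.raises(ValueError):
            dw.sample_seed_points(dmap, 4)

    def test_cube_cell_single_interior_maximum(self, cube_cell_image):
        dmap = boundary_edt(cube_cell_image)
        pts = dw.sample_seed_points(dmap, 13)
        # pool window larger than the 12-voxel cube: one interior max
        inside = cube_cell_image.voxels[
            tuple(pts.astype(int).T)] == 1
        deep = dmap.values[tuple(pts.astype(int).T)] > 2
        assert np.count_nonzero(inside & deep) == 1


class TestDualGraph:
    def test_two_tetrahedra_share_one_facet(self):
        pts = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10],
                        [10, 10, 10]], dtype=float)
        dmap = DistanceMap(np.zeros((12, 12, 12)))
        g = dw.delaunay_dual_graph(pts, dmap)
        assert g.n_nodes == 2
        assert len(g.edges) == 1

    def test_constant_field_gives_constant_weight(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(1, 14, size=(30, 3))
        dmap = DistanceMap(np.full((16, 16, 16), 3.7))
        g = dw.delaunay_dual_graph(pts, dmap)
        assert np.allclose(g.weights, 3.7)

    def test_membrane_facets_weigh_less_than_interior(self, half_space_image):
        dmap = boundary_edt(half_space_image)
        pts = dw.sample_seed_points(dmap, 5)
        g = dw.delaunay_dual_graph(pts, dmap)
        centers = g.tessellation.points[g.facet_vertices].mean(axis=1)
        on_plane = np.abs(centers[:, 2] - 17.5) < 1.5
        interior = np.abs(centers[:, 2] - 10.0) < 2.0
        assert g.weights[on_plane].mean() < g.weights[interior].mean()


class TestWatershed:
    def _path_graph(self, weights):
        n = len(weights) + 1
        g = dw.DualGraph(tessellation=None,
                         barycenters=np.zeros((n, 3)),
                         edges=np.array([[i, i + 1] for i in range(n - 1)]),
                         facet_vertices=np.zeros((n - 1, 3), dtype=int),
                         weights=np.array(weights, dtype=float))
        return g

    def test_cut_falls_in_the_valley(self):
        g = self._path_graph([5.0, 1.0])
        labels = dw.watershed_partition(g, {1: 0, 2: 2})
        assert labels.tolist() == [1, 1, 2]

    def test_equal_weight_tie_break_is_lowest_edge_index(self):
        # a-b-c with equal weights; b must join through edge 0 (a-b)
        g = self._path_graph([2.0, 2.0])
        labels = dw.watershed_partition(g, {1: 0, 2: 2})
        assert labels.tolist() == [1, 1, 2]

    def test_partition_independent_of_input_edge_order(self, half_space_image):
        dmap = boundary_edt(half_space_image)
        pts = dw.sample_seed_points(dmap, 5)
        g = dw.delaunay_dual_graph(pts, dmap)
        seeds = dw.seed_graph(g, half_space_image)
        ref = dw.watershed_partition(g, seeds)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(g.weights))
        g2 = dw.DualGraph(g.tessellation, g.barycenters, g.edges[perm],
                          g.facet_vertices[perm], g.weights[perm],
                          hull_facets=g.hull_facets)
        # shuffling storage order must not change the cut: the tie-break is
        # on the weight-sorted order of the *original* indices, so apply the
        # same lexsort contract to the shuffled copy
        out = dw.watershed_partition(g2, seeds)
        assert np.array_equal(ref, out)

    def test_disconnected_node_raises(self):
        g = self._path_graph([1.0])
        g2 = dw.DualGraph(None, np.zeros((3, 3)), g.edges,
                          g.facet_vertices, g.weights)
        # node 2 unreachable with a single 0-1 edge
        with pytest.raises(dw.OrphanNodeError):
            dw.watershed_partition(g2, {1: 0, 2: 1})
        with pytest.raises(ValueError):
            dw.watershed_partition(g2, {1: 0})   # fewer than 2 seeds

    def test_cut_facets_lie_near_true_plane(self, half_space_image):
        dmap = boundary_edt(half_space_image)
        pts = dw.sample_seed_points(dmap, 5)
        g = dw.delaunay_dual_graph(pts, dmap)
        seeds = dw.seed_graph(g, half_space_image)
        labels = dw.watershed_partition(g, seeds)
        la, lb = labels[g.edges[:, 0]], labels[g.edges[:, 1]]
        cut = (la != lb) & (la != 0) & (lb != 0)   # the 1|2 interface
        centers = g.tessellation.points[g.facet_vertices[cut]].mean(axis=1)
        # away from the outer triple line (where the 1|2 membrane meets the
        # medium and the EDT valley widens) the cut tracks the true plane
        interior = np.all((centers[:, :2] > 9) & (centers[:, :2] < 31), axis=1)
        assert interior.sum() >= 20
        assert np.all(np.abs(centers[interior, 2] - 17.5) <= 1.6)


class TestSeeding:
    def test_two_half_spaces_two_seeds(self, half_space_image):
        dmap = boundary_edt(half_space_image)
        pts = dw.sample_seed_points(dmap, 5)
        g = dw.delaunay_dual_graph(pts, dmap)
        seeds = dw.seed_graph(g, half_space_image)
        assert set(seeds) == {0, 1, 2}
        assert len(set(seeds.values())) == 3

    def test_unseedable_tiny_cell_raises(self):
        v = np.zeros((16, 16, 16), dtype=np.int32)
        v[4:12, 4:12, 4:12] = 1
        v[8, 8, 8] = 2     # single-voxel cell, no barycenter falls inside
        img = LabelImage(v)
        dmap = boundary_edt(img)
        pts = dw.sample_seed_points(dmap, 7)
        g = dw.delaunay_dual_graph(pts, dmap)
        with pytest.raises(dw.UnseededRegionError):
            dw.seed_graph(g, img)


class TestMeshExtraction:
    def test_half_space_mesh_pairs_and_closure(self, half_space_image):
        mesh = dw.generate_mesh(half_space_image)
        assert sorted(tuple(map(int, p)) for p in mesh.interface_pairs()) == \
            [(0, 1), (0, 2), (1, 2)]
        assert mesh.check_closed() == {}

    def test_oriented_area_vectors_sum_to_zero(self, half_space_image):
        mesh = dw.generate_mesh(half_space_image)
        cross = mesh.triangle_cross()
        for mat in (0, 1, 2):
            idx, sign = mesh.cell_triangle_orientation(mat)
            net = np.linalg.norm((0.5 * cross[idx] * sign[:, None]).sum(0))
            total = mesh.triangle_areas()[idx].sum()
            assert net <= 1e-9 * total

    def test_volumes_match_voxel_counts(self, half_space_image):
        mesh = dw.generate_mesh(half_space_image)
        vols = mesh.cell_volumes()
        for lab in (1, 2):
            vox = float((half_space_image.voxels == lab).sum())
            assert vols[lab] == pytest.approx(vox, rel=0.10)

    def test_label_permutation_equivariance(self, half_space_image):
        mesh = dw.generate_mesh(half_space_image)
        v = half_space_image.voxels
        swapped = np.select([v == 1, v == 2], [2, 1],
                            default=0).astype(v.dtype)
        mesh2 = dw.generate_mesh(LabelImage(swapped))
        expected = mesh.permute_labels({1: 2, 2: 1})

        # same interface pairs and (nearly) the same per-pair area
        def areas(m):
            out = {}
            ar = m.triangle_areas()
            for p in m.interface_pairs():
                sel = (m.materials[:, 0] == p[0]) & (m.materials[:, 1] == p[1])
                out[tuple(map(int, p))] = ar[sel].sum()
            return out
        a1 = areas(expected)
        a2 = areas(mesh2)
        assert set(a1) == set(a2)
        for p in a1:
            assert a1[p] == pytest.approx(a2[p], rel=1e-6)

    def test_generation_is_deterministic(self, half_space_image):
        m1 = dw.generate_mesh(half_space_image)
        m2 = dw.generate_mesh(half_space_image)
        assert np.array_equal(m1.vertices, m2.vertices)
        assert np.array_equal(m1.triangles, m2.triangles)
        assert np.array_equal(m1.materials, m2.materials)

    def test_voxel_size_scales_vertices(self, half_space_image):
        img = LabelImage(half_space_image.voxels.copy(),
                         voxel_size=(2.0, 2.0, 2.0))
        m1 = dw.generate_mesh(half_space_image)
        m2 = dw.generate_mesh(img)
        assert np.allclose(m2.vertices, 2.0 * m1.vertices)

    def test_interface_completeness(self, half_space_image):
        """Every voxel adjacency between labels appears as a material pair."""
        mesh = dw.generate_mesh(half_space_image)
        pairs = {tuple(map(int, p)) for p in mesh.interface_pairs()}
        v = half_space_image.voxels
        adj = set()
        for ax in range(3):
            a = np.moveaxis(v, ax, 0)[:-1].ravel()
            b = np.moveaxis(v, ax, 0)[1:].ravel()
            for x, y in zip(a[a != b], b[a != b]):
                adj.add((min(int(x), int(y)), max(int(x), int(y))))
        assert adj <= pairs


class TestPlyVtk:
    def test_ply_round_trip(self, tmp_path, half_space_image):
        mesh = dw.generate_mesh(half_space_image)
        path = mesh.to_ply(tmp_path / "m.ply")
        back = dw.MultimaterialMesh.from_ply(path)
        assert np.allclose(back.vertices, mesh.vertices)
        assert np.array_equal(back.triangles, mesh.triangles)
        assert np.array_equal(back.materials, mesh.materials)

    def test_vtk_export_contains_material_data(self, tmp_path,
                                               half_space_image):
        mesh = dw.generate_mesh(half_space_image)
        path = mesh.to_vtk(tmp_path / "m.vtk",
                           cell_data={"gamma": np.ones(mesh.n_triangles)})
        text = open(path).read()
        assert "SCALARS m1 int" in text and "SCALARS gamma double" in text
        assert f"POINTS {mesh.n_vertices} double" in text
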