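"""Foam simulator: scenarios, initialization, constrained relaxation."""

import numpy as np
import pytest

from foaminfer import cellcomplex as cx
from foaminfer import foamsim as fs


class TestScenarios:
    def test_zero_spread_gives_unit_tensions(self):
        sc = fs.sample_scenario(4, spread=0.0, seed=0)
        off = sc.gamma[~np.eye(5, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_fixed_seed_reproducible(self):
        a = fs.sample_scenario(6, spread=0.4, seed=42)
        b = fs.sample_scenario(6, spread=0.4, seed=42)
        assert np.array_equal(a.gamma, b.gamma)
        assert np.array_equal(a.volume_fractions, b.volume_fractions)

    def test_all_potential_triples_satisfy_triangle_inequality(self):
        sc = fs.sample_scenario(6, spread=0.4, seed=7)
        n = sc.n_c + 1
        for a in range(n):
            for b in range(a + 1, n):
                for c in range(b + 1, n):
                    g = sorted([sc.gamma[a, b], sc.gamma[b, c],
                                sc.gamma[a, c]])
                    assert g[2] <= g[0] + g[1]

    def test_excessive_spread_rejected(self):
        with pytest.raises(ValueError):
            fs.sample_scenario(3, spread=1.0, seed=0)

    def test_volume_fractions_in_range(self):
        sc = fs.sample_scenario(8, spread=0.4, seed=3)
        assert np.all((sc.volume_fractions >= 0.7)
                      & (sc.volume_fractions <= 1.3))


class TestInitAggregate:
    def test_single_cell_is_one_closed_surface(self):
        sc = fs.sample_scenario(1, spread=0.0, seed=2)
        mesh = fs.init_aggregate(sc, resolution=48)
        assert sorted(tuple(map(int, p)) for p in mesh.interface_pairs()) \
            == [(0, 1)]
        assert mesh.check_closed() == {}

    def test_two_cells_have_three_interfaces_one_junction(self):
        sc = fs.sample_scenario(2, spread=0.0, seed=1)
        mesh = fs.init_aggregate(sc, resolution=48)
        cc = cx.build_cell_complex(mesh, compute_curvature=False)
        assert sorted(cc.interfaces) == [(0, 1), (0, 2), (1, 2)]
        assert cc.n_j == 1

    def test_six_cells_genus_zero(self):
        sc = fs.sample_scenario(6, spread=0.4, seed=11)
        mesh = fs.init_aggregate(sc, resolution=64)
        # every cell surface must be a closed genus-0 surface:
        # V - E + F = 2 for its triangle subset
        for cell in range(1, 7):
            idx, _ = mesh.cell_triangle_orientation(cell)
            tris = mesh.triangles[idx]
            verts = np.unique(tris)
            edges = np.unique(np.sort(np.concatenate(
                [tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]]),
                axis=1), axis=0)
            chi = len(verts) - len(edges) + len(tris)
            assert chi == 2, f"cell {cell}: Euler characteristic {chi}"


class TestRelaxation:
    def test_single_cell_relaxes_to_laplace_sphere(self, relaxed_sphere):
        scenario, state = relaxed_sphere
        cc = cx.build_cell_complex(state.mesh)
        V = cc.cells[1].volume
        R = (3 * V / (4 * np.pi)) ** (1 / 3)
        assert cc.interfaces[(0, 1)].area == pytest.approx(
            4 * np.pi * R ** 2, rel=0.02)
        assert state.pressures[1] == pytest.approx(2.0 / R, rel=0.02)

    def test_doublet_contact_angles_near_120(self, relaxed_doublet):
        _, state = relaxed_doublet
        cc = cx.build_cell_complex(state.mesh)
        jn = next(iter(cc.junctions.values()))
        for ang in jn.angles.values():
            assert np.degrees(ang) == pytest.approx(120.0, abs=4.0)

    def test_volumes_conserved(self, relaxed_triplet):
        _, state = relaxed_triplet
        assert state.volume_error <= 1e-3

    def test_energy_decreases_across_rounds(self, relaxed_triplet):
        _, state = relaxed_triplet
        assert state.energy_trace[-1] < state.energy_trace[0]

    def test_equilibrium_residual_reporting(self, relaxed_doublet):
        _, state = relaxed_doublet
        assert fs.equilibrium_residual(state) == state.residual
        assert state.residual >= 0.0

    def test_multiplier_pressures_match_curvature_times_tension(
            self, relaxed_triplet):
        scenario, state = relaxed_triplet
        cc = cx.build_cell_complex(state.mesh)
        checked = 0
        for pair, itf in cc.interfaces.items():
            if 0 not in pair or itf.H_var is None or itf.area < 100:
                continue
            cell = pair[1]
            gH = scenario.tension(*pair) * itf.H_var
            assert gH == pytest.approx(state.pressures[cell], rel=0.08)
            checked += 1
        assert checked >= 2


class TestConfinement:
    def test_confined_cellmedium_curvature_becomes_heterogeneous(self):
        """A rigid shell flattens cell-medium interfaces locally: the
        pointwise mean curvature spreads far beyond its unconfined range,
        the regime where the uniform-curvature Laplace inversion breaks."""
        free = fs.sample_scenario(4, spread=0.2, seed=21)
        confined = fs.FoamScenario(4, free.gamma, free.volume_fractions,
                                   seed=21, confinement=(0.95, 0.75, 0.65))
        out = {}
        for tag, sc in (("free", free), ("confined", confined)):
            state = fs.simulate(sc, resolution=56,
                                params=fs.RelaxParams(outer_rounds=6),
                                topology_refresh=False)
            grads = cx.vertex_gradients(state.mesh)
            spreads = []
            for pair in state.mesh.interface_pairs():
                if 0 not in pair:
                    continue
                _, H = cx.pointwise_mean_curvature(state.mesh, pair, grads)
                if len(H) >= 10:
                    lo, hi = np.percentile(H, [20, 80])
                    spreads.append(hi - lo)
            assert spreads, f"{tag}: no interface with enough interior vertices"
            out[tag] = np.median(spreads)
        assert out["confined"] > 1.5 * out["free"]
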