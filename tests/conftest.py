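"""Shared fixtures: analytic meshes, tiny label images, relaxed foams.

Everything is generated programmatically; the expensive relaxed-foam
fixtures are session-scoped so the whole suite pays for them once.
"""

import numpy as np
import pytest

from foaminfer import (FoamScenario, LabelImage, RelaxParams, sample_scenario,
                       simulate)
from foaminfer._primitives import icosphere
from foaminfer.delwatershed import MultimaterialMesh


@pytest.fixture(scope="session")
def half_space_image():
    """Two half-space cells in a box surrounded by medium."""
    v = np.zeros((40, 40, 40), dtype=np.int32)
    v[5:35, 5:35, 5:18] = 1
    v[5:35, 5:35, 18:35] = 2
    return LabelImage(v)


@pytest.fixture(scope="session")
def cube_cell_image():
    """A single cubic cell centered in a large box of medium."""
    v = np.zeros((32, 32, 32), dtype=np.int32)
    v[10:22, 10:22, 10:22] = 1
    return LabelImage(v)


@pytest.fixture(scope="session")
def sphere_mesh():
    """Unit icosphere at refinement 4 (pair (0, 1))."""
    return icosphere(1.0, 4)


@pytest.fixture(scope="session")
def tripod_mesh():
    """Three half-plane interfaces meeting at exactly 120 degrees along the
    z-axis: regions 1, 2, 3 fill the three wedges (open surfaces; for angle
    tests only)."""
    n_z, n_r = 8, 6
    z = np.linspace(0.0, 4.0, n_z)
    r = np.linspace(0.0, 3.0, n_r)
    dirs = {k: np.array([np.cos(a), np.sin(a), 0.0])
            for k, a in enumerate([0.0, 2 * np.pi / 3, 4 * np.pi / 3])}
    # interface k separates the two regions flanking direction k
    region_pairs = [(1, 2), (2, 3), (1, 3)]
    verts, tris, mats = [], [], []
    axis_idx = {}

    def vid(k, i, j):
        # axis vertices (j == 0) are shared between the three sheets
        if j == 0:
            key = ("axis", i)
        else:
            key = (k, i, j)
        if key not in axis_idx:
            axis_idx[key] = len(verts)
            verts.append(dirs[k] * r[j] + np.array([0.0, 0.0, z[i]]))
        return axis_idx[key]

    for k, pair in enumerate(region_pairs):
        for i in range(n_z - 1):
            for j in range(n_r - 1):
                a = vid(k, i, j)
                b = vid(k, i + 1, j)
                c = vid(k, i + 1, j + 1)
                d = vid(k, i, j + 1)
                tris += [[a, b, c], [a, c, d]]
                mats += [list(pair), list(pair)]
    return MultimaterialMesh(np.array(verts), np.array(tris), np.array(mats))


@pytest.fixture(scope="session")
def relaxed_doublet():
    """Equal-tension two-cell foam at equilibrium (contact angles 120)."""
    scenario = FoamScenario(2, np.full((3, 3), 1.0),
                            np.array([1.0, 1.0]), seed=1)
    state = simulate(scenario, resolution=56,
                     params=RelaxParams(outer_rounds=8))
    return scenario, state


@pytest.fixture(scope="session")
def relaxed_triplet():
    """Heterogeneous three-cell foam (spread 0.4) at equilibrium."""
    scenario = sample_scenario(3, spread=0.4, seed=5)
    state = simulate(scenario, resolution=64,
                     params=RelaxParams(outer_rounds=9))
    return scenario, state


@pytest.fixture(scope="session")
def relaxed_sphere():
    """Single cell relaxed to a sphere under a volume constraint."""
    scenario = FoamScenario(1, np.full((2, 2), 1.0), np.array([1.0]), seed=3)
    state = simulate(scenario, resolution=48,
                     params=RelaxParams(outer_rounds=6),
                     topology_refresh=False)
    return scenario, state
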