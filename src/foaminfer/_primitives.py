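"""Small analytic mesh primitives used by the simulator and the test suite."""

from __future__ import annotations

import numpy as np

from .delwatershed import MultimaterialMesh

_PHI = (1.0 + np.sqrt(5.0)) / 2.0

_ICO_VERTS = np.array([
    [-1, _PHI, 0], [1, _PHI, 0], [-1, -_PHI, 0], [1, -_PHI, 0],
    [0, -1, _PHI], [0, 1, _PHI], [0, -1, -_PHI], [0, 1, -_PHI],
    [_PHI, 0, -1], [_PHI, 0, 1], [-_PHI, 0, -1], [-_PHI, 0, 1],
], dtype=float)

_ICO_FACES = np.array([
    [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
    [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
    [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
    [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
])


def icosphere(radius: float = 1.0, subdivisions: int = 3,
              center=(0.0, 0.0, 0.0), cell: int = 1) -> MultimaterialMesh:
    """Subdivided icosahedron projected onto a sphere.

    The triangles carry pair (0, cell) with outward-pointing... the stored
    orientation follows the multimaterial convention (normal from 0 into the
    cell, i.e. inward), so the enclosed volume of ``cell`` is positive.
    """
    verts = _ICO_VERTS / np.linalg.norm(_ICO_VERTS[0])
    faces = _ICO_FACES
    for _ in range(subdivisions):
        edge_mid: dict[tuple[int, int], int] = {}
        new_faces = []
        verts_list = list(verts)

        def midpoint(a, b):
            key = (min(a, b), max(a, b))
            if key not in edge_mid:
                m = verts_list[a] + verts_list[b]
                m /= np.linalg.norm(m)
                edge_mid[key] = len(verts_list)
                verts_list.append(m)
            return edge_mid[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
        verts = np.array(verts_list)
        faces = np.array(new_faces)
    # _ICO_FACES wind outward; multimaterial convention for pair (0, cell)
    # needs the normal pointing from material 0 into the cell (inward)
    faces = faces[:, ::-1]
    verts = verts * radius + np.asarray(center, dtype=float)
    mats = np.column_stack([np.zeros(len(faces), dtype=int),
                            np.full(len(faces), cell, dtype=int)])
    return MultimaterialMesh(verts, faces, mats)
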