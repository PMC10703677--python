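"""Foam geometry measured on a multimaterial mesh.

From a triangle mesh with material pairs we extract the quantities that the
force balances consume:

* interfaces (i, j): total area ``A_ij`` and signed mean curvature ``H_ij``
  (sum of the two principal curvatures; a sphere of radius R gives 2/R);
* tricellular junctions (i, j, k): polylines where exactly three interfaces
  meet, with total length ``L_ijk`` and the three in-plane opening angles
  ``alpha_ij, alpha_jk, alpha_ki`` (the wedge opposite each interface; they
  sum to 2 pi);
* cells i: enclosed volume ``V_i`` and centroid.

Curvature is computed variationally from the exact area and volume gradients
of the piecewise-linear surface: at an interface-interior vertex,
``H_v = (dA . n) / (dV . n)`` with ``n`` the unit volume-gradient direction.
This is the discrete counterpart of the identity dA/dV = H for a surface
displaced along its normal, and is calibrated by the sphere (H -> 2/R).

Sign conventions (used consistently by the pressure solver):

* the reference region of interface (i, j) is i if i != 0 else j
  (cell-medium interfaces are referenced to the cell);
* H_ij > 0 when the interface bows away from the reference region
  (a lone cell against the medium has H = +2/R);
* Young-Laplace then reads p_ref - p_other = gamma_ij * H_ij.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .delwatershed import MultimaterialMesh

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi


def reference_region(pair: tuple[int, int]) -> int:
    """The region whose outward normal defines the sign of H for this pair."""
    i, j = pair
    return i if i != 0 else j


def other_region(pair: tuple[int, int]) -> int:
    i, j = pair
    return j if i != 0 else i


@dataclass
class Interface:
    pair: tuple[int, int]
    area: float
    triangle_ids: np.ndarray
    H_plain: float | None = None
    H_var: float | None = None
    n_interior_vertices: int = 0


@dataclass
class Junction:
    triple: tuple[int, int, int]
    length: float
    edges: np.ndarray            # (n_e, 2) vertex indices
    edge_lengths: np.ndarray
    # opening angle opposite each interface pair, radians
    angles: dict[tuple[int, int], float] = field(default_factory=dict)


@dataclass
class CellGeom:
    label: int
    volume: float
    centroid: np.ndarray


@dataclass
class CellComplex:
    mesh: MultimaterialMesh
    interfaces: dict[tuple[int, int], Interface]
    junctions: dict[tuple[int, int, int], Junction]
    cells: dict[int, CellGeom]

    @property
    def n_c(self) -> int:
        return len(self.cells)

    @property
    def n_m(self) -> int:
        return len(self.interfaces)

    @property
    def n_j(self) -> int:
        return len(self.junctions)

    def interface_table(self) -> pd.DataFrame:
        rows = [{"i": p[0], "j": p[1], "area": itf.area,
                 "H_plain": itf.H_plain, "H_var": itf.H_var}
                for p, itf in sorted(self.interfaces.items())]
        return pd.DataFrame(rows)

    def junction_table(self) -> pd.DataFrame:
        rows = []
        for tr, j in sorted(self.junctions.items()):
            row = {"i": tr[0], "j": tr[1], "k": tr[2], "length": j.length}
            for pair, ang in j.angles.items():
                row[f"alpha_{pair[0]}_{pair[1]}"] = ang
            rows.append(row)
        return pd.DataFrame(rows)

    def cell_table(self) -> pd.DataFrame:
        rows = [{"cell": c.label, "volume": c.volume,
                 "cx": c.centroid[0], "cy": c.centroid[1], "cz": c.centroid[2]}
                for c in sorted(self.cells.values(), key=lambda c: c.label)]
        return pd.DataFrame(rows)

    def to_csv(self, directory):
        """Write interfaces.csv, junctions.csv, cells.csv under ``directory``."""
        from pathlib import Path
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.interface_table().to_csv(d / "interfaces.csv", index=False)
        self.junction_table().to_csv(d / "junctions.csv", index=False)
        self.cell_table().to_csv(d / "cells.csv", index=False)
        return d


# ---------------------------------------------------------------------------
# exact gradients of areas and volumes w.r.t. vertex positions
# ---------------------------------------------------------------------------

class VertexGradients:
    """Exact per-vertex gradients of interface areas and cell volumes.

    For the piecewise-linear surface these are closed forms, not
    approximations: for a triangle (a, b, c) with unit normal n,
    dArea/da = 0.5 * n x (c - b); for the divergence-theorem volume,
    dVol/da = (b x c) / 6 summed over the oriented boundary triangles.
    """

    def __init__(self, mesh: MultimaterialMesh):
        self.mesh = mesh
        self._area_grads: dict[tuple[int, int], np.ndarray] = {}
        self._vol_grads: dict[int, np.ndarray] = {}
        # per-corner area gradient, reused by every interface
        a, b, c = mesh.triangle_corners()
        cr = np.cross(b - a, c - a)
        nrm = np.linalg.norm(cr, axis=1)
        nrm[nrm == 0] = 1.0
        n_hat = cr / nrm[:, None]
        self._corner_area_grad = np.stack([
            0.5 * np.cross(n_hat, c - b),
            0.5 * np.cross(n_hat, a - c),
            0.5 * np.cross(n_hat, b - a),
        ], axis=1)                                    # (m, 3 corners, 3)

    def area_grad(self, pair: tuple[int, int]) -> np.ndarray:
        """(n_vertices, 3) gradient of A_ij w.r.t. every vertex position."""
        pair = tuple(int(x) for x in pair)
        if pair not in self._area_grads:
            mesh = self.mesh
            sel = np.nonzero((mesh.materials[:, 0] == pair[0])
                             & (mesh.materials[:, 1] == pair[1]))[0]
            g = np.zeros((mesh.n_vertices, 3))
            for corner in range(3):
                np.add.at(g, mesh.triangles[sel, corner],
                          self._corner_area_grad[sel, corner])
            self._area_grads[pair] = g
        return self._area_grads[pair]

    def volume_grad(self, cell: int) -> np.ndarray:
        """(n_vertices, 3) gradient of the signed enclosed volume of ``cell``."""
        cell = int(cell)
        if cell not in self._vol_grads:
            mesh = self.mesh
            idx, sign = mesh.cell_triangle_orientation(cell)
            a = mesh.vertices[mesh.triangles[idx, 0]]
            b = mesh.vertices[mesh.triangles[idx, 1]]
            c = mesh.vertices[mesh.triangles[idx, 2]]
            g = np.zeros((mesh.n_vertices, 3))
            s = sign[:, None] / 6.0
            np.add.at(g, mesh.triangles[idx, 0], s * np.cross(b, c))
            np.add.at(g, mesh.triangles[idx, 1], s * np.cross(c, a))
            np.add.at(g, mesh.triangles[idx, 2], s * np.cross(a, b))
            self._vol_grads[cell] = g
        return self._vol_grads[cell]


def vertex_gradients(mesh: MultimaterialMesh) -> VertexGradients:
    return VertexGradients(mesh)


# ---------------------------------------------------------------------------
# complex construction
# ---------------------------------------------------------------------------

def _edge_incidence(mesh: MultimaterialMesh):
    """Undirected edge -> list of incident triangle indices."""
    m = mesh.n_triangles
    tri = mesh.triangles
    e = np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
    t_of = np.tile(np.arange(m), 3)
    e = np.sort(e, axis=1)
    key = e[:, 0] * np.int64(mesh.n_vertices + 1) + e[:, 1]
    order = np.argsort(key, kind="stable")
    key_s = key[order]
    starts = np.r_[0, np.nonzero(np.diff(key_s))[0] + 1, len(key_s)]
    edges = e[order[starts[:-1]]]
    groups = [t_of[order[starts[i]:starts[i + 1]]] for i in range(len(starts) - 1)]
    return edges, groups


def build_cell_complex(mesh: MultimaterialMesh,
                       compute_angles: bool = True,
                       compute_curvature: bool = True,
                       angle_method: str = "cmc_fit",
                       validate: bool = True) -> CellComplex:
    """Measure interfaces, junctions and cells of a multimaterial mesh.

    ``validate=False`` skips the closed-surface check (volumes are then
    meaningless); useful for open analytic fixtures.
    """
    if validate:
        mesh.check_closed()
    areas = mesh.triangle_areas()
    mats = mesh.materials

    interfaces: dict[tuple[int, int], Interface] = {}
    pair_keys = mats[:, 0] * np.int64(mats.max() + 1) + mats[:, 1]
    for key in np.unique(pair_keys):
        sel = np.nonzero(pair_keys == key)[0]
        pair = (int(mats[sel[0], 0]), int(mats[sel[0], 1]))
        interfaces[pair] = Interface(pair, float(areas[sel].sum()), sel)

    cells: dict[int, CellGeom] = {}
    for lab in mesh.material_labels():
        lab = int(lab)
        if lab == 0:
            continue
        idx, sign = mesh.cell_triangle_orientation(lab)
        a = mesh.vertices[mesh.triangles[idx, 0]]
        b = mesh.vertices[mesh.triangles[idx, 1]]
        c = mesh.vertices[mesh.triangles[idx, 2]]
        det = np.einsum("ij,ij->i", a, np.cross(b, c))
        vol = float(np.sum(sign * det / 6.0))
        # centroid of the enclosed solid via the divergence theorem
        cen = (sign[:, None] * det[:, None] * (a + b + c) / 24.0).sum(0)
        cells[lab] = CellGeom(lab, vol, cen / vol if vol != 0 else cen)
        if vol <= 0:
            warnings.warn(f"cell {lab} has nonpositive volume {vol}", stacklevel=2)

    # junction polylines: edges where exactly 3 distinct pairs / materials meet
    edges, groups = _edge_incidence(mesh)
    vtx = mesh.vertices
    junctions: dict[tuple[int, int, int], Junction] = {}
    jn_edges: dict[tuple[int, int, int], list[int]] = {}
    n_skipped = 0
    for eid, tids in enumerate(groups):
        if len(tids) < 3:
            continue
        pairs = {tuple(mats[t]) for t in tids}
        mat_set = set()
        for p in pairs:
            mat_set.update(p)
        if len(tids) == 3 and len(pairs) == 3 and len(mat_set) == 3:
            triple = tuple(sorted(mat_set))
            jn_edges.setdefault(triple, []).append(eid)
        else:
            n_skipped += 1
    if n_skipped:
        warnings.warn(f"{n_skipped} degenerate (>3-material or pinched) edges "
                      "excluded from junctions", stacklevel=2)

    for triple, eids in jn_edges.items():
        e = edges[np.array(eids)]
        el = np.linalg.norm(vtx[e[:, 1]] - vtx[e[:, 0]], axis=1)
        junctions[triple] = Junction(triple, float(el.sum()), e, el)

    complex_ = CellComplex(mesh, interfaces, junctions, cells)

    if compute_angles and junctions:
        junction_angles(complex_, mesh,
                        edge_groups=(edges, groups, jn_edges),
                        method=angle_method)
    if compute_curvature:
        grads = VertexGradients(mesh)
        interface_mean_curvature(complex_, grads)
    return complex_


# ---------------------------------------------------------------------------
# junction opening angles
# ---------------------------------------------------------------------------

def _fit_cmc_surfaces(mesh: MultimaterialMesh) -> dict:
    """Per interface, a constant-curvature proxy: an algebraic sphere fit
    (center, radius) to the interface's vertices, or a plane (point, normal)
    when the patch is flat or the fit unstable. Used for bias-free junction
    tangents."""
    fits = {}
    mats = mesh.materials
    pair_keys = {}
    for t in range(mesh.n_triangles):
        pair_keys.setdefault((int(mats[t, 0]), int(mats[t, 1])), []).append(t)
    for pair, tids in pair_keys.items():
        pts = mesh.vertices[np.unique(mesh.triangles[tids])]
        mean = pts.mean(0)
        centered = pts - mean
        scale = np.linalg.norm(centered, axis=1).max() or 1.0
        # plane fit (total least squares)
        _, sv, vt = np.linalg.svd(centered, full_matrices=False)
        plane_rms = float(sv[2] / np.sqrt(len(pts))) if len(pts) >= 3 else np.inf
        fit = ("plane", mean, vt[2]) if len(pts) >= 3 else None
        # sphere fit: algebraic initialization (noise-biased toward small
        # radii) refined by damped Gauss-Newton on the geometric residual
        # |p - c| - r; kept only when it fits at least as well as the plane
        # and its radius is sane (a flat patch makes the fitted center
        # direction arbitrary)
        if len(pts) >= 6:
            A = np.c_[2 * centered, np.ones(len(pts))]
            b = (centered ** 2).sum(1)
            sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
            if rank == 4:
                c = sol[:3]
                r2 = sol[3] + c @ c
                if r2 > 0:
                    r = float(np.sqrt(r2))
                    for _ in range(10):
                        d = centered - c
                        dist = np.linalg.norm(d, axis=1)
                        dist[dist == 0] = 1e-12
                        f = dist - r
                        J = np.c_[-d / dist[:, None], -np.ones(len(pts))]
                        try:
                            step, *_ = np.linalg.lstsq(J, -f, rcond=None)
                        except np.linalg.LinAlgError:
                            break
                        c = c + step[:3]
                        r = r + float(step[3])
                        if np.linalg.norm(step) < 1e-9 * max(r, 1.0):
                            break
                    rms = float(np.std(np.linalg.norm(centered - c, axis=1) - r))
                    # the sphere generalizes the plane: a plane fitted to a
                    # weakly curved patch tilts junction tangents by
                    # ~extent/(2R)
                    if (np.isfinite(r) and 0 < r < 100.0 * scale
                            and rms <= 1.02 * plane_rms):
                        fit = ("sphere", c + mean, r)
        if fit is None:
            continue
        fits[pair] = fit
    return fits


def junction_angles(complex_: CellComplex, mesh: MultimaterialMesh,
                    edge_groups=None, method: str = "cmc_fit") -> dict:
    """In-plane opening angles at every tricellular junction.

    Per junction edge, each incident interface contributes a unit tangent
    perpendicular to the edge, pointing away from the junction into the
    interface. Projected into the plane orthogonal to the edge, the three
    tangents split the circle into three wedges summing to exactly 2 pi; the
    wedge *opposite* interface ab (between the tangents of the other two
    interfaces) is the opening angle alpha_ab.

    Tangent estimation (``method``):

    * ``"cmc_fit"`` (default) -- the tangent of a constant-curvature
      (sphere or plane) fit of the whole interface, evaluated at the edge
      midpoint. A first-ring secant tilts systematically by ~ h H / 2 on a
      curved interface (h the local edge length); the fitted tangent removes
      that bias, at the price of assuming interfaces are close to constant
      mean curvature -- the premise of the foam model itself.
    * ``"secant"`` -- the classical first-ring estimate: the in-plane
      direction toward the adjacent triangle's opposite vertex.

    Junction-level angles are length-weighted circular means of the per-edge
    wedges (mean cosine and sine, combined with atan2), then rescaled by the
    common factor that restores the exact 2-pi sum.
    """
    if edge_groups is None:
        all_edges, all_groups = _edge_incidence(mesh)
    else:
        all_edges, all_groups, _ = edge_groups
    # map sorted edge -> triangle list for lookup
    key_of = {(int(a), int(b)): g for (a, b), g in zip(all_edges, all_groups)}
    fits = _fit_cmc_surfaces(mesh) if method == "cmc_fit" else {}

    vtx = mesh.vertices
    tri = mesh.triangles
    mats = mesh.materials
    out = {}
    for triple, jn in complex_.junctions.items():
        pairs = [(triple[0], triple[1]), (triple[1], triple[2]),
                 (triple[0], triple[2])]
        cos_acc = {p: 0.0 for p in pairs}
        sin_acc = {p: 0.0 for p in pairs}
        w_acc = 0.0
        for (a, b), el in zip(jn.edges, jn.edge_lengths):
            tids = key_of[(int(a), int(b))]
            mid = 0.5 * (vtx[a] + vtx[b])
            raw_edge = vtx[b] - vtx[a]
            e_dir = raw_edge / np.linalg.norm(raw_edge)
            if fits:
                # a jagged polyline makes the raw edge direction a noisy
                # frame; the junction curve is the intersection of the
                # fitted surfaces, so the cross product of two fitted
                # normals gives a smooth tangent
                normals = []
                for t in tids:
                    fp = fits.get((int(mats[t, 0]), int(mats[t, 1])))
                    if fp is None:
                        continue
                    if fp[0] == "sphere":
                        d = mid - fp[1]
                        nn = np.linalg.norm(d)
                        if nn > 0:
                            normals.append(d / nn)
                    else:
                        normals.append(fp[2])
                best = None
                best_norm = 0.1
                for ii in range(len(normals)):
                    for jj in range(ii + 1, len(normals)):
                        cr = np.cross(normals[ii], normals[jj])
                        ncr = np.linalg.norm(cr)
                        if ncr > best_norm:
                            best, best_norm = cr / ncr, ncr
                if best is not None:
                    e_dir = best if best @ e_dir >= 0 else -best
                    # a zigzag polyline inflates raw edge lengths; the
                    # projection onto the smooth junction direction is the
                    # unbiased arclength contribution of this edge
                    el = abs(raw_edge @ e_dir)
            # orthonormal basis of the plane perpendicular to the edge
            u = np.cross(e_dir, [1.0, 0.0, 0.0])
            if np.linalg.norm(u) < 1e-8:
                u = np.cross(e_dir, [0.0, 1.0, 0.0])
            u /= np.linalg.norm(u)
            w = np.cross(e_dir, u)
            theta = {}
            degenerate = False
            for t in tids:
                pair = (int(mats[t, 0]), int(mats[t, 1]))
                corners = set(int(x) for x in tri[t])
                opp = (corners - {int(a), int(b)}).pop()
                tangent = vtx[opp] - mid
                tangent = tangent - np.dot(tangent, e_dir) * e_dir
                nt = np.linalg.norm(tangent)
                if nt < 1e-12:
                    degenerate = True
                    break
                tangent /= nt
                fit = fits.get(pair)
                if fit is not None:
                    if fit[0] == "sphere":
                        n_s = mid - fit[1]
                        nn = np.linalg.norm(n_s)
                        n_s = n_s / nn if nn > 0 else None
                    else:
                        n_s = fit[2]
                    if n_s is not None:
                        n_p = n_s - np.dot(n_s, e_dir) * e_dir
                        npn = np.linalg.norm(n_p)
                        if npn > 0.2:
                            tc = np.cross(e_dir, n_p / npn)
                            if np.dot(tc, tangent) < 0:
                                tc = -tc
                            tangent = tc
                theta[pair] = np.arctan2(np.dot(tangent, w), np.dot(tangent, u))
            if degenerate or len(theta) != 3:
                warnings.warn("degenerate junction-edge tangent skipped",
                              stacklevel=2)
                continue
            # wedge between the other two interfaces = opening angle of pair;
            # of the two arcs between them, take the one NOT containing the
            # pair's own tangent
            for p in pairs:
                others = [q for q in theta if q != p]
                d = (theta[others[1]] - theta[others[0]]) % TWO_PI
                third = (theta[p] - theta[others[0]]) % TWO_PI
                wedge = TWO_PI - d if third < d else d
                cos_acc[p] += el * np.cos(wedge)
                sin_acc[p] += el * np.sin(wedge)
            w_acc += el
        if w_acc == 0:
            warnings.warn(f"junction {triple}: no usable edges", stacklevel=2)
            continue
        raw = {p: float(np.arctan2(sin_acc[p], cos_acc[p]) % TWO_PI)
               for p in pairs}
        total = sum(raw.values())
        jn.angles = {p: v * TWO_PI / total for p, v in raw.items()}
        out[triple] = jn.angles
    return out


# ---------------------------------------------------------------------------
# interface mean curvature
# ---------------------------------------------------------------------------

def interface_mean_curvature(complex_: CellComplex,
                             grads: VertexGradients) -> dict:
    """Signed mean curvature per interface, from area/volume gradients.

    Only interface-interior vertices are used (vertices all of whose incident
    triangles belong to the interface); junction vertices mix the gradients
    of several interfaces. Two estimates are stored:

    * ``H_plain`` -- unweighted mean of the pointwise ratio
      (dA . n)/(dV . n);
    * ``H_var``  -- ratio of sums (sum dA . n)/(sum dV . n), the exact
      discrete counterpart of the variational Laplace balance.
    """
    mesh = complex_.mesh
    # vertices incident to a single material pair = interface interior
    mats = mesh.materials
    vert_pairs: dict[int, set] = {}
    for t in range(mesh.n_triangles):
        p = (int(mats[t, 0]), int(mats[t, 1]))
        for v in mesh.triangles[t]:
            vert_pairs.setdefault(int(v), set()).add(p)

    out = {}
    for pair, itf in complex_.interfaces.items():
        ref = reference_region(pair)
        tri_ids = itf.triangle_ids
        verts = np.unique(mesh.triangles[tri_ids])
        interior = np.array([v for v in verts if vert_pairs[int(v)] == {pair}],
                            dtype=np.int64)
        itf.n_interior_vertices = len(interior)
        if len(interior) == 0:
            itf.H_plain = None
            itf.H_var = None
            logger.info("interface %s has no interior vertex; H undefined", pair)
            continue
        gA = grads.area_grad(pair)[interior]
        gV = grads.volume_grad(ref)[interior]
        gv_norm = np.linalg.norm(gV, axis=1)
        # a vertex ringed by slivers has a vanishing volume gradient and an
        # unbounded pointwise ratio; exclude it from the plain mean
        ok = gv_norm > 0.05 * np.median(gv_norm)
        n_hat = np.zeros_like(gV)
        n_hat[ok] = gV[ok] / gv_norm[ok, None]
        num = np.einsum("ij,ij->i", gA, n_hat)
        den = np.einsum("ij,ij->i", gV, n_hat)
        ptwise = num[ok] / den[ok]
        itf.H_plain = float(np.mean(ptwise)) if ok.any() else None
        denom = float(den[ok].sum())
        itf.H_var = float(num[ok].sum() / denom) if abs(denom) > 1e-14 else None
        out[pair] = (itf.H_plain, itf.H_var)
    return out


def pointwise_mean_curvature(mesh: MultimaterialMesh, pair: tuple[int, int],
                             grads: VertexGradients | None = None):
    """Pointwise H at interface-interior vertices (vertex ids, H values)."""
    grads = grads or VertexGradients(mesh)
    cc = build_cell_complex(mesh, compute_angles=False, compute_curvature=False)
    itf = cc.interfaces[tuple(int(x) for x in pair)]
    mats = mesh.materials
    vert_pairs: dict[int, set] = {}
    for t in range(mesh.n_triangles):
        p = (int(mats[t, 0]), int(mats[t, 1]))
        for v in mesh.triangles[t]:
            vert_pairs.setdefault(int(v), set()).add(p)
    verts = np.unique(mesh.triangles[itf.triangle_ids])
    interior = np.array([v for v in verts if vert_pairs[int(v)] == {tuple(pair)}],
                        dtype=np.int64)
    ref = reference_region(tuple(pair))
    gA = grads.area_grad(tuple(pair))[interior]
    gV = grads.volume_grad(ref)[interior]
    n_hat = gV / np.linalg.norm(gV, axis=1)[:, None]
    H = np.einsum("ij,ij->i", gA, n_hat) / np.einsum("ij,ij->i", gV, n_hat)
    return interior, H
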