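"""Heterogeneous foam simulator: ground-truth equilibria for validation.

A foam scenario assigns a tension to every interface class and a target
volume to every cell. The simulator minimizes total surface energy
``E = sum gamma_ij A_ij`` under the volume constraints on a multimaterial
mesh with an augmented-Lagrangian scheme:

* outer rounds alternate remeshing with an L-BFGS solve of
  ``E - sum p_i (V_i - V_i*) + mu_i/2 (V_i - V_i*)^2``;
* the multiplier update ``p_i <- p_i - mu_i (V_i - V_i*)`` converges to
  the cells' hydrostatic pressures, the ground-truth oracle for pressure
  inference; volumes are restored exactly by Newton projection along the
  volume gradients after every round;
* remeshing (conforming edge splits, collapses and quality flips inside
  interfaces, tangential smoothing) keeps triangle quality; junction
  edges are split but never collapsed.

An optional rigid ellipsoidal shell confines the aggregate: vertices
leaving the shell are projected back, which makes cell-medium curvatures
inhomogeneous and breaks the Young-Laplace relation — the regime where
two-step (tension-only) inference is still valid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .delwatershed import MeshParams, MultimaterialMesh, generate_mesh
from .segio import LabelImage

logger = logging.getLogger(__name__)


class RelaxationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

@dataclass
class FoamScenario:
    """Ground truth driving one simulation.

    gamma : (n_c+1, n_c+1) symmetric array of interface tensions (row/col 0
        is the medium); entries for non-adjacent pairs are simply unused.
    volume_fractions : per-cell target volume relative to the mean cell
        volume of the initial aggregate.
    confinement : None or ellipsoid semi-axes (in units of the initial
        aggregate's bounding-ball radius).
    """

    n_c: int
    gamma: np.ndarray
    volume_fractions: np.ndarray
    seed: int = 0
    confinement: tuple[float, float, float] | None = None

    def tension(self, i: int, j: int) -> float:
        return float(self.gamma[i, j])

    def tension_map(self) -> dict[tuple[int, int], float]:
        out = {}
        for i in range(self.n_c + 1):
            for j in range(i + 1, self.n_c + 1):
                out[(i, j)] = float(self.gamma[i, j])
        return out


def _violates_triangle(gamma: np.ndarray) -> bool:
    """Any potential junction triple (a, b, c) violating the triangle
    inequalities of its three pairwise tensions?"""
    n = gamma.shape[0]
    for a in range(n):
        for b in range(a + 1, n):
            for c in range(b + 1, n):
                g = np.array([gamma[a, b], gamma[b, c], gamma[a, c]])
                if np.any(2.0 * g > g.sum()):
                    return True
    return False


def sample_scenario(n_c: int, spread: float = 0.4, seed: int = 0,
                    confinement=None, max_tries: int = 1000) -> FoamScenario:
    """Random tensions uniform in [1-spread, 1+spread] per interface pair and
    volumes uniform in [0.7, 1.3] x mean; scenarios whose tension table
    could produce an unstable junction are rejected and resampled."""
    if not 0 <= spread < 1:
        raise ValueError("spread must be in [0, 1): tensions must stay positive")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        g = rng.uniform(1.0 - spread, 1.0 + spread, size=(n_c + 1, n_c + 1))
        gamma = np.triu(g, 1)
        gamma = gamma + gamma.T
        if not _violates_triangle(gamma):
            break
    else:
        raise RelaxationError("could not sample a stable tension table; "
                              "reduce spread")
    fractions = rng.uniform(0.7, 1.3, size=n_c)
    return FoamScenario(n_c, gamma, fractions, seed=seed, confinement=confinement)


# ---------------------------------------------------------------------------
# initial aggregate
# ---------------------------------------------------------------------------

def init_aggregate(scenario: FoamScenario, resolution: int = 72,
                   pool_size: int = 5) -> MultimaterialMesh:
    """Initial partition: Voronoi diagram of seeded points inside a ball,
    rasterized to a label lattice and meshed with Delaunay-watershed."""
    rng = np.random.default_rng(scenario.seed + 1)
    L = resolution
    center = (L - 1) / 2.0
    R = 0.36 * L
    # well-separated seed points in the ball
    min_d = 1.1 * R * scenario.n_c ** (-1 / 3)
    seeds = []
    for _ in range(20000):
        p = rng.uniform(-1, 1, 3)
        if np.linalg.norm(p) > 0.85:
            continue
        q = center + R * p
        if all(np.linalg.norm(q - s) >= min_d for s in seeds):
            seeds.append(q)
        if len(seeds) == scenario.n_c:
            break
    if len(seeds) < scenario.n_c:
        raise RelaxationError(f"could not place {scenario.n_c} seeds")
    seeds = np.array(seeds)
    zz, yy, xx = np.meshgrid(*[np.arange(L)] * 3, indexing="ij")
    coords = np.stack([zz, yy, xx], axis=-1).astype(float)
    inside = np.linalg.norm(coords - center, axis=-1) <= R
    d2 = ((coords[..., None, :] - seeds[None, None, None]) ** 2).sum(-1)
    labels = np.where(inside, np.argmin(d2, axis=-1) + 1, 0).astype(np.int32)
    img = LabelImage(labels)
    return generate_mesh(img, MeshParams(pool_size=pool_size,
                                         seed=scenario.seed))


# ---------------------------------------------------------------------------
# relaxation
# ---------------------------------------------------------------------------

@dataclass
class RelaxParams:
    outer_rounds: int = 8        # remesh + multiplier updates between solves
    inner_iter: int = 600        # L-BFGS iterations per round
    tol: float = 5e-2            # max vertex force / (mean gamma * mean edge)
    mu_factor: float = 5.0       # volume penalty in units of the Laplace
    #                              pressure scale per unit target volume
    target_edge: float | None = None   # defaults to initial mean edge length
    refine: tuple[float, ...] = (1.0, 1.5, 2.0)   # edge-length divisors per
    #                              phase: coarse rounds converge the shape,
    #                              finer rounds sharpen junction geometry
    smooth_lambda: float = 0.4
    volume_tol: float = 1e-3
    verbose: bool = False


@dataclass
class RelaxState:
    mesh: MultimaterialMesh
    pressures: dict[int, float]        # volume-constraint multipliers
    energy: float
    residual: float                    # normalized max vertex force
    volume_error: float
    energy_trace: list = field(default_factory=list)
    residual_trace: list = field(default_factory=list)
    converged: bool = False


class _Relaxer:
    def __init__(self, mesh: MultimaterialMesh, scenario: FoamScenario,
                 params: RelaxParams,
                 v_target: dict[int, float] | None = None):
        self.scenario = scenario
        self.params = params
        self.cells = [c for c in mesh.material_labels() if c != 0]
        self.V = mesh.vertices.copy()
        self.T = mesh.triangles.copy()
        self.P = mesh.materials.copy()
        self._sync()
        if v_target is not None:
            self.v_target = {int(c): float(v) for c, v in v_target.items()}
        else:
            vols = self._volumes()
            mean_v = np.mean([vols[c] for c in self.cells])
            self.v_target = {c: float(scenario.volume_fractions[c - 1] * mean_v)
                             for c in self.cells}
        self.gamma_mean = float(np.mean([scenario.tension(*p)
                                         for p in mesh.interface_pairs()]))
        if scenario.confinement is not None:
            self.conf_center = self.V.mean(axis=0)
            r0 = np.linalg.norm(self.V - self.conf_center, axis=1).max()
            self.conf_axes = np.asarray(scenario.confinement, dtype=float) * r0
        else:
            self.conf_axes = None

    # -- bookkeeping --------------------------------------------------------
    def _sync(self):
        """Recompute per-triangle tensions and cell orientation signs."""
        self.tri_gamma = np.array([self.scenario.tension(int(a), int(b))
                                   for a, b in self.P])
        self.cell_tris = {}
        for c in self.cells:
            touches = (self.P[:, 0] == c) | (self.P[:, 1] == c)
            idx = np.nonzero(touches)[0]
            sign = np.where(self.P[idx, 0] == c, 1.0, -1.0)
            self.cell_tris[c] = (idx, sign)

    def mesh(self) -> MultimaterialMesh:
        return MultimaterialMesh(self.V.copy(), self.T.copy(), self.P.copy())

    def mean_edge(self, V=None) -> float:
        V = self.V if V is None else V
        a, b, c = V[self.T[:, 0]], V[self.T[:, 1]], V[self.T[:, 2]]
        return float((np.linalg.norm(b - a, axis=1) + np.linalg.norm(c - b, axis=1)
                      + np.linalg.norm(a - c, axis=1)).mean() / 3.0)

    # -- geometry -----------------------------------------------------------
    def _volumes(self, V=None):
        V = self.V if V is None else V
        out = {}
        for c in self.cells:
            idx, sign = self.cell_tris[c]
            a, b, cc = V[self.T[idx, 0]], V[self.T[idx, 1]], V[self.T[idx, 2]]
            out[c] = float(np.sum(sign * np.einsum("ij,ij->i", a,
                                                   np.cross(b, cc)) / 6.0))
        return out

    def _energy(self, V=None):
        V = self.V if V is None else V
        a, b, c = V[self.T[:, 0]], V[self.T[:, 1]], V[self.T[:, 2]]
        areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
        return float(np.sum(self.tri_gamma * areas))

    def _energy_grad(self, V=None):
        """d(sum gamma A)/dv, (n, 3)."""
        V = self.V if V is None else V
        a, b, c = V[self.T[:, 0]], V[self.T[:, 1]], V[self.T[:, 2]]
        cr = np.cross(b - a, c - a)
        nrm = np.linalg.norm(cr, axis=1)
        nrm[nrm == 0] = 1.0
        n_hat = cr / nrm[:, None]
        w = self.tri_gamma[:, None]
        g = np.zeros_like(V)
        np.add.at(g, self.T[:, 0], w * 0.5 * np.cross(n_hat, c - b))
        np.add.at(g, self.T[:, 1], w * 0.5 * np.cross(n_hat, a - c))
        np.add.at(g, self.T[:, 2], w * 0.5 * np.cross(n_hat, b - a))
        return g

    def _volume_grads(self, V=None):
        V = self.V if V is None else V
        out = {}
        for c in self.cells:
            idx, sign = self.cell_tris[c]
            a, b, cc = V[self.T[idx, 0]], V[self.T[idx, 1]], V[self.T[idx, 2]]
            g = np.zeros_like(V)
            s = sign[:, None] / 6.0
            np.add.at(g, self.T[idx, 0], s * np.cross(b, cc))
            np.add.at(g, self.T[idx, 1], s * np.cross(cc, a))
            np.add.at(g, self.T[idx, 2], s * np.cross(a, b))
            out[c] = g
        return out

    # -- multipliers and forces --------------------------------------------
    def _multipliers(self, gradE, gV):
        k = len(self.cells)
        M = np.empty((k, k))
        b = np.empty(k)
        for i, ci in enumerate(self.cells):
            b[i] = np.sum(gV[ci] * gradE)
            for j, cj in enumerate(self.cells):
                if j < i:
                    M[i, j] = M[j, i]
                else:
                    M[i, j] = np.sum(gV[ci] * gV[cj])
        try:
            p = np.linalg.solve(M, b)
        except np.linalg.LinAlgError:
            p = np.linalg.lstsq(M, b, rcond=None)[0]
        return {c: float(p[i]) for i, c in enumerate(self.cells)}, M

    def _force(self, V=None):
        gradE = self._energy_grad(V)
        gV = self._volume_grads(V)
        p, M = self._multipliers(gradE, gV)
        F = -gradE
        for c in self.cells:
            F += p[c] * gV[c]
        return F, p, gV, M

    def robust_multipliers(self):
        """Volume-constraint multipliers fitted on the converged part of
        the state: the top 2% of vertices by residual force (mesh defects,
        frustrated junction endpoints) violate the stationarity that makes
        the multipliers pressures, so they are excluded from the fit."""
        gradE = self._energy_grad()
        gV = self._volume_grads()
        F = -gradE
        p0, _ = self._multipliers(gradE, gV)
        for c in self.cells:
            F += p0[c] * gV[c]
        fn = np.linalg.norm(F, axis=1)
        mask = fn <= np.percentile(fn, 98)
        k = len(self.cells)
        M = np.empty((k, k))
        b = np.empty(k)
        for i, ci in enumerate(self.cells):
            b[i] = np.sum(gV[ci][mask] * gradE[mask])
            for j, cj in enumerate(self.cells):
                M[i, j] = (np.sum(gV[ci][mask] * gV[cj][mask])
                           if j >= i else M[j, i])
        try:
            p = np.linalg.solve(M, b)
        except np.linalg.LinAlgError:
            p = np.linalg.lstsq(M, b, rcond=None)[0]
        return {c: float(p[i]) for i, c in enumerate(self.cells)}

    def _project_volumes(self, V, n_iter=2):
        for _ in range(n_iter):
            vols = self._volumes(V)
            err = np.array([self.v_target[c] - vols[c] for c in self.cells])
            if np.max(np.abs(err)) < 1e-12:
                break
            gV = self._volume_grads(V)
            k = len(self.cells)
            M = np.empty((k, k))
            for i, ci in enumerate(self.cells):
                for j, cj in enumerate(self.cells):
                    M[i, j] = np.sum(gV[ci] * gV[cj]) if j >= i else M[j, i]
            try:
                coef = np.linalg.solve(M, err)
            except np.linalg.LinAlgError:
                coef = np.linalg.lstsq(M, err, rcond=None)[0]
            for i, c in enumerate(self.cells):
                V = V + coef[i] * gV[c]
        return V

    def _confine(self, V):
        if self.conf_axes is None:
            return V
        rel = (V - self.conf_center) / self.conf_axes
        rho = np.linalg.norm(rel, axis=1)
        out = rho > 1.0
        if np.any(out):
            V = V.copy()
            V[out] = self.conf_center + (rel[out] / rho[out, None]) * self.conf_axes
        return V

    def volume_error(self):
        vols = self._volumes()
        return max(abs(vols[c] - self.v_target[c]) / self.v_target[c]
                   for c in self.cells)

    # -- remeshing ----------------------------------------------------------
    def _vertex_pairs(self):
        vp: dict[int, set] = {}
        for t in range(len(self.T)):
            pair = (int(self.P[t, 0]), int(self.P[t, 1]))
            for v in self.T[t]:
                vp.setdefault(int(v), set()).add(pair)
        return vp

    def _edges(self):
        e = np.concatenate([self.T[:, [0, 1]], self.T[:, [1, 2]],
                            self.T[:, [2, 0]]])
        e = np.sort(e, axis=1)
        t_of = np.tile(np.arange(len(self.T)), 3)
        key = e[:, 0] * np.int64(len(self.V) + 1) + e[:, 1]
        order = np.argsort(key, kind="stable")
        key_s = key[order]
        starts = np.r_[0, np.nonzero(np.diff(key_s))[0] + 1, len(key_s)]
        edges = e[order[starts[:-1]]]
        groups = [t_of[order[starts[i]:starts[i + 1]]]
                  for i in range(len(starts) - 1)]
        return edges, groups

    def _split_long_edges(self, threshold):
        """Conforming subdivision: every edge longer than threshold gets a
        midpoint; triangles split by 1-, 2- or 3-edge patterns."""
        for _ in range(4):
            lengths = np.linalg.norm(self.V[self.T[:, [1, 2, 0]]]
                                     - self.V[self.T[:, [0, 1, 2]]], axis=2)
            if not np.any(lengths.max(axis=1) > threshold):
                return
            long_mid: dict[tuple[int, int], int] = {}
            new_verts = list(self.V)

            def mid(a, b):
                key = (min(a, b), max(a, b))
                if key not in long_mid:
                    long_mid[key] = len(new_verts)
                    new_verts.append(0.5 * (self.V[a] + self.V[b]))
                return long_mid[key]

            # mark long edges globally for conformity
            e_all = np.concatenate([self.T[:, [0, 1]], self.T[:, [1, 2]],
                                    self.T[:, [2, 0]]])
            l_all = np.linalg.norm(self.V[e_all[:, 0]] - self.V[e_all[:, 1]],
                                   axis=1)
            long_set = {tuple(sorted(map(int, e))) for e, l in
                        zip(e_all, l_all) if l > threshold}
            new_T, new_P = [], []
            for t in range(len(self.T)):
                a, b, c = (int(x) for x in self.T[t])
                pair = self.P[t]
                sab = (min(a, b), max(a, b)) in long_set
                sbc = (min(b, c), max(b, c)) in long_set
                sca = (min(c, a), max(c, a)) in long_set
                n_split = sab + sbc + sca
                if n_split == 0:
                    new_T.append([a, b, c])
                    new_P.append(pair)
                    continue
                if n_split == 3:
                    mab, mbc, mca = mid(a, b), mid(b, c), mid(c, a)
                    tris = [[a, mab, mca], [mab, b, mbc], [mca, mbc, c],
                            [mab, mbc, mca]]
                elif n_split == 2:
                    # rotate so the un-split edge is (c, a)
                    while not ((min(a, b), max(a, b)) in long_set
                               and (min(b, c), max(b, c)) in long_set):
                        a, b, c = b, c, a
                    mab, mbc = mid(a, b), mid(b, c)
                    tris = [[a, mab, c], [mab, b, mbc], [mab, mbc, c]]
                else:
                    while not (min(a, b), max(a, b)) in long_set:
                        a, b, c = b, c, a
                    mab = mid(a, b)
                    tris = [[a, mab, c], [mab, b, c]]
                new_T.extend(tris)
                new_P.extend([pair] * len(tris))
            self.V = np.array(new_verts)
            self.T = np.array(new_T, dtype=np.int64)
            self.P = np.array(new_P, dtype=np.int64)
            self._sync()

    def _collapse_short_edges(self, threshold):
        """Collapse interface-interior edges shorter than threshold; junction
        and mixed-material edges are never collapsed."""
        edges, groups = self._edges()
        vp = self._vertex_pairs()
        lengths = np.linalg.norm(self.V[edges[:, 0]] - self.V[edges[:, 1]],
                                 axis=1)
        order = np.argsort(lengths)
        merged = np.arange(len(self.V))
        touched = set()
        n_collapsed = 0
        for ei in order:
            if lengths[ei] >= threshold:
                break
            a, b = int(edges[ei, 0]), int(edges[ei, 1])
            if a in touched or b in touched:
                continue
            if len(groups[ei]) != 2:
                continue
            pa, pb = vp.get(a), vp.get(b)
            if pa is None or pb is None or len(pa) != 1 or pa != pb:
                continue
            mid_pt = 0.5 * (self.V[a] + self.V[b])
            self.V[a] = mid_pt
            merged[b] = a
            touched.update((a, b))
            n_collapsed += 1
        if n_collapsed == 0:
            return
        T = merged[self.T]
        keep = ~((T[:, 0] == T[:, 1]) | (T[:, 1] == T[:, 2])
                 | (T[:, 2] == T[:, 0]))
        self.T = T[keep]
        self.P = self.P[keep]
        # drop unused vertices
        used = np.unique(self.T)
        remap = np.full(len(self.V), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        self.V = self.V[used]
        self.T = remap[self.T]
        self._sync()

    def _flip_edges(self, n_passes=2):
        """Quality-improving edge flips inside interfaces (manifold edges
        with two same-pair triangles only). Removes cap-shaped slivers that
        neither splits nor collapses can reach."""

        def tri_quality(a, b, c):
            ab, bc, ca = b - a, c - b, a - c
            area2 = np.linalg.norm(np.cross(ab, -ca))
            denom = ab @ ab + bc @ bc + ca @ ca
            return 2.0 * np.sqrt(3.0) * 0.5 * area2 / denom if denom > 0 else 0.0

        for _ in range(n_passes):
            edges, groups = self._edges()
            existing = {(int(a), int(b)) for a, b in edges}
            modified = np.zeros(len(self.T), dtype=bool)
            n_flips = 0
            for (va, vb), g in zip(edges, groups):
                if len(g) != 2:
                    continue
                t1, t2 = int(g[0]), int(g[1])
                if modified[t1] or modified[t2]:
                    continue
                if not np.array_equal(self.P[t1], self.P[t2]):
                    continue
                # rotate tri1 to (a, b, c) with {a, b} the shared edge; tri2
                # then holds the directed edge (b, a)
                va, vb = int(va), int(vb)
                l1 = [int(x) for x in self.T[t1]]
                a = b = c = None
                for i in range(3):
                    p_, q_ = l1[i], l1[(i + 1) % 3]
                    if {p_, q_} == {va, vb}:
                        a, b, c = p_, q_, l1[(i + 2) % 3]
                        break
                if a is None:
                    continue
                l2 = [int(x) for x in self.T[t2]]
                d = [x for x in l2 if x not in (a, b)][0]
                q_old = min(tri_quality(self.V[a], self.V[b], self.V[c]),
                            tri_quality(self.V[b], self.V[a], self.V[d]))
                q_new = min(tri_quality(self.V[a], self.V[d], self.V[c]),
                            tri_quality(self.V[d], self.V[b], self.V[c]))
                if q_new <= 1.05 * q_old:
                    continue
                key = (min(c, d), max(c, d))
                if key in existing:
                    continue
                # fold guard: new normals must not oppose the old mean normal
                n_old = np.cross(self.V[b] - self.V[a], self.V[c] - self.V[a]) \
                    + np.cross(self.V[a] - self.V[b], self.V[d] - self.V[b])
                n1 = np.cross(self.V[d] - self.V[a], self.V[c] - self.V[a])
                n2 = np.cross(self.V[b] - self.V[d], self.V[c] - self.V[d])
                if n1 @ n_old <= 0 or n2 @ n_old <= 0:
                    continue
                self.T[t1] = [a, d, c]
                self.T[t2] = [d, b, c]
                modified[t1] = modified[t2] = True
                existing.add(key)
                n_flips += 1
            if n_flips == 0:
                break
        self._sync()

    def _smooth(self, lam):
        """Tangential smoothing: interface-interior vertices relax toward
        their neighborhood centroid within the tangent plane; junction
        vertices redistribute along the junction polyline only."""
        edges, groups = self._edges()
        vp = self._vertex_pairs()
        n = len(self.V)
        nbr_sum = np.zeros((n, 3))
        nbr_cnt = np.zeros(n)
        jn_nbrs: dict[int, list[int]] = {}
        for (a, b), g in zip(edges, groups):
            a, b = int(a), int(b)
            nbr_sum[a] += self.V[b]
            nbr_sum[b] += self.V[a]
            nbr_cnt[a] += 1
            nbr_cnt[b] += 1
            if len(g) >= 3:
                jn_nbrs.setdefault(a, []).append(b)
                jn_nbrs.setdefault(b, []).append(a)
        gV = self._volume_grads()
        normals = np.zeros((n, 3))
        for c in self.cells:
            nz = np.linalg.norm(gV[c], axis=1) > 0
            normals[nz] = gV[c][nz]
        nn = np.linalg.norm(normals, axis=1)
        nn[nn == 0] = 1.0
        normals /= nn[:, None]
        newV = self.V.copy()
        for v in range(n):
            if nbr_cnt[v] == 0:
                continue
            if v in jn_nbrs:
                nbrs = jn_nbrs[v]
                if len(nbrs) != 2:
                    continue          # junction endpoint / quadruple point
                t = self.V[nbrs[0]] - self.V[nbrs[1]]
                tn = np.linalg.norm(t)
                if tn < 1e-12:
                    continue
                t /= tn
                d = 0.5 * (self.V[nbrs[0]] + self.V[nbrs[1]]) - self.V[v]
                newV[v] = self.V[v] + lam * np.dot(d, t) * t
            elif len(vp.get(v, ())) == 1:
                d = nbr_sum[v] / nbr_cnt[v] - self.V[v]
                d = d - np.dot(d, normals[v]) * normals[v]
                newV[v] = self.V[v] + lam * d
        self.V = newV

    def remesh(self, target_edge):
        n0 = len(self.T)
        self._split_long_edges(1.5 * target_edge)
        self._collapse_short_edges(0.5 * target_edge)
        self._flip_edges()
        self._smooth(self.params.smooth_lambda)
        self.V = self._project_volumes(self.V, n_iter=3)
        if self.conf_axes is not None:
            self.V = self._confine(self.V)
        logger.debug("remesh: %d -> %d triangles", n0, len(self.T))

    # -- main loop ----------------------------------------------------------
    def run(self) -> RelaxState:
        """Augmented-Lagrangian minimization of the surface energy.

        Outer rounds alternate remeshing with an L-BFGS solve of
        ``E - sum p_i (V_i - V_t) + mu_i/2 (V_i - V_t)^2``; the multiplier
        update ``p_i <- p_i - mu_i (V_i - V_t)`` converges to the cell
        pressures. Volumes are restored exactly by Newton projection after
        every round.
        """
        from scipy.optimize import minimize

        params = self.params
        base_edge = params.target_edge or self.mean_edge()
        target_edge = base_edge / params.refine[0]
        self.remesh(target_edge)
        scale = self.gamma_mean * target_edge
        mean_v = np.mean([self.v_target[c] for c in self.cells])
        r_cell = (3.0 * mean_v / (4.0 * np.pi)) ** (1.0 / 3.0)
        p0 = 2.0 * self.gamma_mean / r_cell
        mu = {c: params.mu_factor * p0 / self.v_target[c] for c in self.cells}
        p = {c: 0.0 for c in self.cells}
        n_outer = max(2, params.outer_rounds)
        inner_iter = params.inner_iter

        def objective(x):
            V = x.reshape(-1, 3)
            vols = self._volumes(V)
            E = self._energy(V)
            g = self._energy_grad(V)
            gV = self._volume_grads(V)
            phi = E
            for c in self.cells:
                dv = vols[c] - self.v_target[c]
                phi += -p[c] * dv + 0.5 * mu[c] * dv * dv
                g += (-p[c] + mu[c] * dv) * gV[c]
            if self.conf_axes is not None:
                # quadratic wall outside the ellipsoid
                rel = (V - self.conf_center) / self.conf_axes
                rho2 = np.einsum("ij,ij->i", rel, rel)
                out = rho2 > 1.0
                if np.any(out):
                    k_wall = 10.0 * self.gamma_mean
                    phi += 0.5 * k_wall * np.sum((rho2[out] - 1.0) ** 2)
                    gw = (2.0 * k_wall * (rho2[out] - 1.0))[:, None] \
                        * rel[out] / self.conf_axes
                    g[out] += gw
            return phi, g.ravel()

        e_trace = [self._energy()]
        r_trace: list[float] = []
        converged = False
        for outer in range(n_outer):
            res = minimize(objective, self.V.ravel(), jac=True,
                           method="L-BFGS-B",
                           options={"maxiter": inner_iter, "maxcor": 20,
                                    "ftol": 1e-14, "gtol": 1e-10})
            self.V = res.x.reshape(-1, 3)
            vols = self._volumes()
            for c in self.cells:
                p[c] = p[c] - mu[c] * (vols[c] - self.v_target[c])
            self.V = self._project_volumes(self.V, n_iter=3)
            if self.conf_axes is not None:
                self.V = self._confine(self.V)
                self.V = self._project_volumes(self.V, n_iter=2)
            F, p_exact, gV, _ = self._force()
            resid = float(np.linalg.norm(F, axis=1).max() / scale)
            r_trace.append(resid)
            e_trace.append(self._energy())
            if params.verbose:
                logger.info("outer %d: E=%.6f resid=%.3e tris=%d",
                            outer, e_trace[-1], resid, len(self.T))
            phase = min(len(params.refine) - 1,
                        (outer + 1) * len(params.refine) // n_outer)
            target_edge = base_edge / params.refine[phase]
            scale = self.gamma_mean * target_edge
            if resid < params.tol and self.volume_error() < params.volume_tol \
                    and phase == len(params.refine) - 1:
                converged = True
                break
            if outer < n_outer - 1:
                self.remesh(target_edge)
        vols_err = self.volume_error()
        if vols_err > params.volume_tol:
            self.V = self._project_volumes(self.V, n_iter=5)
            vols_err = self.volume_error()
        F, p_exact, gV, _ = self._force()
        resid = float(np.linalg.norm(F, axis=1).max() / scale)
        # report the robust least-squares multipliers of the final geometry:
        # they equal the AL multipliers at convergence and are the
        # ground-truth pressures of the relaxed state
        state = RelaxState(self.mesh(), {0: 0.0, **self.robust_multipliers()},
                           self._energy(), resid, vols_err, e_trace, r_trace,
                           converged)
        if not converged:
            logger.info("relaxation stopped after %d rounds with residual "
                        "%.2e", n_outer, resid)
        return state


def relax(mesh: MultimaterialMesh, scenario: FoamScenario,
          params: RelaxParams | None = None,
          v_target: dict[int, float] | None = None) -> RelaxState:
    """Relax a multimaterial mesh to the scenario's foam equilibrium."""
    return _Relaxer(mesh, scenario, params or RelaxParams(), v_target).run()


def equilibrium_residual(state: RelaxState) -> float:
    """Max vertex net force, normalized by mean tension x mean edge length."""
    return state.residual


def simulate(scenario: FoamScenario, resolution: int = 72,
             params: RelaxParams | None = None,
             topology_refresh: bool = True,
             refresh_resolution: int = 96) -> RelaxState:
    """Scenario -> initial Voronoi aggregate -> relaxed foam equilibrium.

    The rasterized Voronoi initialization carries topological debris
    (sub-voxel interfaces, quadruple lines) that a fixed-connectivity
    relaxation cannot remove and that obstructs convergence. With
    ``topology_refresh`` the aggregate is therefore relaxed in two stages:
    a short coarse relaxation, then a re-voxelization of the relaxed shape
    and a fresh Delaunay-watershed meshing (which drops vanishing
    interfaces), then the full relaxation on the cleaned topology.
    """
    from dataclasses import replace

    params = params or RelaxParams()
    mesh = init_aggregate(scenario, resolution=resolution)
    v_target = None
    if topology_refresh:
        from .synthimg import mesh_to_labels

        pre = replace(params, outer_rounds=4, refine=(1.0, 1.25))
        relaxer = _Relaxer(mesh, scenario, pre)
        st1 = relaxer.run()
        v_target = dict(relaxer.v_target)
        img = mesh_to_labels(st1.mesh, (refresh_resolution,) * 3)
        mesh = generate_mesh(img, MeshParams(seed=scenario.seed))
        missing = set(range(1, scenario.n_c + 1)) - {
            int(c) for c in mesh.material_labels() if c != 0}
        if missing:
            raise RelaxationError(f"cells {sorted(missing)} vanished during "
                                  "topology refresh")
    return relax(mesh, scenario, params, v_target=v_target)
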