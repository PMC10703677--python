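"""Tension and pressure inference by inverting foam force balances.

At mechanical equilibrium a cell aggregate behaves as a heterogeneous foam:

* at each tricellular junction the three vector tensions sum to zero
  (Young-Dupre), which constrains the tension magnitudes through the
  junction's opening angles;
* across each interface the pressure jump equals tension times mean
  curvature (Young-Laplace).

Both balances are assembled into overdetermined linear systems and solved
by weighted ordinary least squares: one tension row block per junction
(weighted by junction length), one pressure row per interface (weighted by
interface area). Tensions are determined up to a global factor, removed by
the mean-tension-one constraint; pressures up to a constant, removed by
pinning the exterior medium to zero.

Six tension-row variants are provided (scalar Young-Dupre cosine rows, its
cosine+sine projection, Lami sine ratios, inverse Lami, log-Lami, and a
variational form built from discrete area gradients), plus two pressure
variants (pointwise Laplace and the variational ratio-of-sums form).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cellcomplex import CellComplex, VertexGradients, other_region, reference_region

logger = logging.getLogger(__name__)

TENSION_VARIANTS = ("yd", "yd_projection", "lami", "lami_inverse", "lami_log",
                    "variational")
PRESSURE_VARIANTS = ("laplace", "variational_laplace")

_SIN_FLOOR = 1e-6


@dataclass
class TensionSystem:
    variant: str
    matrix: np.ndarray            # ((n_rows + 1), n_m), weighted, incl. constraint
    rhs: np.ndarray
    pairs: list[tuple[int, int]]  # column -> interface
    junction_rows: dict[tuple[int, int, int], list[int]]
    log_space: bool = False

    @property
    def n_m(self) -> int:
        return len(self.pairs)


@dataclass
class PressureSystem:
    variant: str
    matrix: np.ndarray
    rhs: np.ndarray
    cells: list[int]              # column -> cell label
    row_pairs: list[tuple[int, int]]


@dataclass
class ForceAtlas:
    """Inferred mechanics of one aggregate."""

    tensions: dict[tuple[int, int], float]
    pressures: dict[int, float]
    tension_variant: str = "yd"
    pressure_variant: str = "variational_laplace"
    residuals: dict[tuple[int, int, int], float] = field(default_factory=dict)
    stable: dict[tuple[int, int, int], bool] = field(default_factory=dict)
    stress: dict[int, np.ndarray] = field(default_factory=dict)
    compaction: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def tension_table(self) -> pd.DataFrame:
        return pd.DataFrame([{"i": p[0], "j": p[1], "gamma": g}
                             for p, g in sorted(self.tensions.items())])

    def pressure_table(self) -> pd.DataFrame:
        return pd.DataFrame([{"cell": c, "p": v}
                             for c, v in sorted(self.pressures.items())])


# ---------------------------------------------------------------------------
# tension system assembly
# ---------------------------------------------------------------------------

def _junction_pairs(triple):
    i, j, k = triple
    return [(i, j), (j, k), (i, k)]


def assemble_tension_system(complex_: CellComplex, variant: str = "yd",
                            grads: VertexGradients | None = None) -> TensionSystem:
    """Build the weighted linear system A_Gamma x Gamma = c_Gamma.

    Rows are per tricellular junction, scaled by its length over the mean
    junction length; the final row is the mean-tension-one constraint
    (all ones, right-hand side n_m; for ``lami_log`` the unknowns are
    log-tensions and the constraint is sum log gamma = 0).
    """
    if variant not in TENSION_VARIANTS:
        raise ValueError(f"unknown tension variant {variant!r}")
    if not complex_.junctions:
        raise ValueError("no tricellular junction: tensions are unconstrained")
    pairs = sorted(complex_.interfaces)
    col = {p: k for k, p in enumerate(pairs)}
    n_m = len(pairs)
    mean_len = np.mean([j.length for j in complex_.junctions.values()])
    # interfaces far below the geometric resolution carry meaningless
    # angles; they and their junctions are excluded (tension reported nan)
    med_area = np.median([i.area for i in complex_.interfaces.values()])
    tiny = {p for p, i in complex_.interfaces.items()
            if i.area < 0.01 * med_area}
    if tiny:
        warnings.warn(f"interfaces {sorted(tiny)} are below the geometric "
                      "resolution; excluded from tension inference",
                      stacklevel=2)

    rows: list[np.ndarray] = []
    rhs: list[float] = []
    junction_rows: dict = {}

    if variant == "variational":
        grads = grads or VertexGradients(complex_.mesh)

    for triple, jn in sorted(complex_.junctions.items()):
        jpairs = _junction_pairs(triple)
        if any(p in tiny for p in jpairs):
            continue
        if any(p not in jn.angles for p in jpairs):
            warnings.warn(f"junction {triple} lacks angles; skipped", stacklevel=2)
            continue
        w = jn.length / mean_len
        if w < 0.01:
            # numerical debris: a vanishing junction constrains nothing but
            # can still hijack the least-squares solution
            logger.info("junction %s has negligible length; skipped", triple)
            continue
        a = {p: jn.angles[p] for p in jpairs}
        start = len(rows)
        p_ij, p_jk, p_ki = jpairs
        if variant == "yd":
            # gamma_ab + gamma_cd cos(alpha_ef) + gamma_ef cos(alpha_cd) = 0
            for own, o1, o2 in ((p_ij, p_jk, p_ki), (p_jk, p_ki, p_ij),
                                (p_ki, p_ij, p_jk)):
                r = np.zeros(n_m)
                r[col[own]] = 1.0
                r[col[o1]] = np.cos(a[o2])
                r[col[o2]] = np.cos(a[o1])
                rows.append(w * r)
                rhs.append(0.0)
        elif variant == "yd_projection":
            r = np.zeros(n_m)
            r[col[p_ij]] = 1.0
            r[col[p_jk]] = np.cos(a[p_ki])
            r[col[p_ki]] = np.cos(a[p_jk])
            rows.append(w * r)
            rhs.append(0.0)
            r = np.zeros(n_m)
            r[col[p_jk]] = np.sin(a[p_ki])
            r[col[p_ki]] = -np.sin(a[p_jk])
            rows.append(w * r)
            rhs.append(0.0)
        elif variant == "lami":
            # gamma_ab / sin(alpha_ab) equal across the three pairs;
            # two independent ratio rows, chosen cyclically
            sins = {p: np.sin(a[p]) for p in jpairs}
            if min(abs(s) for s in sins.values()) < _SIN_FLOOR:
                warnings.warn(f"junction {triple}: near-zero sine, lami rows "
                              "dropped", stacklevel=2)
                continue
            for pa, pb in ((p_ij, p_jk), (p_jk, p_ki)):
                r = np.zeros(n_m)
                r[col[pa]] = 1.0 / sins[pa]
                r[col[pb]] = -1.0 / sins[pb]
                rows.append(w * r)
                rhs.append(0.0)
        elif variant == "lami_inverse":
            for pa, pb in ((p_ij, p_jk), (p_jk, p_ki)):
                r = np.zeros(n_m)
                r[col[pa]] = np.sin(a[pb])
                r[col[pb]] = -np.sin(a[pa])
                rows.append(w * r)
                rhs.append(0.0)
        elif variant == "lami_log":
            sins = {p: np.sin(a[p]) for p in jpairs}
            if min(abs(s) for s in sins.values()) < _SIN_FLOOR:
                warnings.warn(f"junction {triple}: near-zero sine, lami_log "
                              "rows dropped", stacklevel=2)
                continue
            for pa, pb in ((p_ij, p_jk), (p_jk, p_ki)):
                r = np.zeros(n_m)
                r[col[pa]] = 1.0
                r[col[pb]] = -1.0
                rows.append(w * r)
                rhs.append(w * float(np.log(abs(sins[pa])) - np.log(abs(sins[pb]))))
        elif variant == "variational":
            # net junction pull of each interface: sum over junction vertices
            # of its area gradient, projected off the mean junction tangent
            verts = np.unique(jn.edges)
            tangents = (complex_.mesh.vertices[jn.edges[:, 1]]
                        - complex_.mesh.vertices[jn.edges[:, 0]])
            # orient tangents consistently before averaging
            ref_t = tangents[np.argmax(np.linalg.norm(tangents, axis=1))]
            sgn = np.sign(tangents @ ref_t)
            sgn[sgn == 0] = 1.0
            mean_t = (tangents * sgn[:, None]).sum(0)
            nt = np.linalg.norm(mean_t)
            if nt < 1e-12:
                warnings.warn(f"junction {triple}: degenerate tangent", stacklevel=2)
                continue
            mean_t /= nt
            u = np.cross(mean_t, [1.0, 0.0, 0.0])
            if np.linalg.norm(u) < 1e-8:
                u = np.cross(mean_t, [0.0, 1.0, 0.0])
            u /= np.linalg.norm(u)
            vv = np.cross(mean_t, u)
            coeff = np.zeros((2, n_m))
            for p in jpairs:
                g = grads.area_grad(p)[verts].sum(0)
                coeff[0, col[p]] = np.dot(g, u)
                coeff[1, col[p]] = np.dot(g, vv)
            scale = np.linalg.norm(coeff)
            if scale > 0:
                coeff = coeff / scale
            rows.append(w * coeff[0])
            rhs.append(0.0)
            rows.append(w * coeff[1])
            rhs.append(0.0)
        junction_rows[triple] = list(range(start, len(rows)))

    if not rows:
        raise ValueError("no usable junction rows")
    A = np.array(rows)
    # an interface touched by no junction row is unconstrained: with a
    # homogeneous system it would soak up the whole mean-one constraint
    # (gamma = n_m there, 0 elsewhere); excise it and report it undetermined
    col_norm = np.linalg.norm(A, axis=0)
    covered = col_norm > 0.05 * np.median(col_norm)
    if not covered.all():
        dropped = [p for p, c in zip(pairs, covered) if not c]
        warnings.warn(f"interfaces {dropped} appear in no junction row; "
                      "their tension is undetermined (nan)", stacklevel=2)
        A = A[:, covered]
        pairs = [p for p, c in zip(pairs, covered) if c]
        n_m = len(pairs)
    if variant == "lami_log":
        A = np.vstack([A, np.ones(n_m)])
        rhs.append(0.0)            # sum of log-tensions = 0
    else:
        A = np.vstack([A, np.ones(n_m)])
        rhs.append(float(n_m))     # mean tension = 1
    return TensionSystem(variant, A, np.array(rhs), pairs,
                         junction_rows, log_space=(variant == "lami_log"))


def solve_tensions(system: TensionSystem) -> tuple[dict, dict]:
    """Weighted OLS solve, then exact rescale to mean tension one.

    Returns (tensions, diagnostics). Diagnostics carry the singular values,
    condition number, rank and total residual of the solve.
    """
    A, b = system.matrix, system.rhs
    n_rows = A.shape[0] - 1
    if n_rows < system.n_m - 1:
        warnings.warn(f"underdetermined tension system: {n_rows} physical rows "
                      f"for {system.n_m} tensions", stacklevel=2)
    sol, res, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < system.n_m:
        warnings.warn(f"rank-deficient tension system (rank {rank} < "
                      f"{system.n_m}); pseudo-inverse solution", stacklevel=2)
    gamma = np.exp(sol) if system.log_space else sol
    mean = gamma.mean()
    if mean <= 0:
        warnings.warn("nonpositive mean tension; rescaling by |mean|", stacklevel=2)
        mean = abs(mean) or 1.0
    gamma = gamma / mean
    diag = {
        "condition_number": float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf,
        "singular_values": sv,
        "rank": int(rank),
        "residual": float(np.linalg.norm(A[:-1] @ (sol if not system.log_space
                                                   else sol) - b[:-1])),
    }
    tensions = {p: float(g) for p, g in zip(system.pairs, gamma)}
    return tensions, diag


# ---------------------------------------------------------------------------
# pressure system
# ---------------------------------------------------------------------------

def assemble_pressure_system(complex_: CellComplex, tensions: dict,
                             variant: str = "variational_laplace",
                             grads: VertexGradients | None = None) -> PressureSystem:
    """One Young-Laplace row per interface with defined curvature.

    Row for interface with reference region r and other region s:
    ``p_r - p_s = gamma * H`` with the exterior pressure eliminated
    (p_0 = 0). ``laplace`` uses the pointwise-mean curvature ``H_plain``;
    ``variational_laplace`` uses the ratio-of-sums estimate ``H_var``.
    Rows are weighted by interface area over the mean area.
    """
    if variant not in PRESSURE_VARIANTS:
        raise ValueError(f"unknown pressure variant {variant!r}")
    cells = sorted(complex_.cells)
    col = {c: k for k, c in enumerate(cells)}
    areas = [itf.area for itf in complex_.interfaces.values()]
    mean_area = float(np.mean(areas))
    rows, rhs, row_pairs = [], [], []
    for pair, itf in sorted(complex_.interfaces.items()):
        H = itf.H_plain if variant == "laplace" else itf.H_var
        if H is None:
            logger.info("interface %s: undefined curvature, pressure row "
                        "skipped", pair)
            continue
        gam = tensions.get(pair)
        if gam is None or not np.isfinite(gam):
            logger.info("interface %s: no solved tension, pressure row "
                        "skipped", pair)
            continue
        w = itf.area / mean_area
        r = np.zeros(len(cells))
        ref = reference_region(pair)
        oth = other_region(pair)
        rhs_val = gam * H
        r[col[ref]] = 1.0
        if oth != 0:
            r[col[oth]] = -1.0
        rows.append(w * r)
        rhs.append(w * rhs_val)
        row_pairs.append(pair)
    if not rows:
        raise ValueError("no interface with defined curvature")
    return PressureSystem(variant, np.array(rows), np.array(rhs), cells, row_pairs)


def solve_pressures(system: PressureSystem) -> tuple[dict, dict]:
    """Weighted OLS pressures relative to the exterior (p_0 = 0)."""
    covered = np.any(system.matrix != 0, axis=0)
    if not covered.all():
        missing = [c for c, cov in zip(system.cells, covered) if not cov]
        warnings.warn(f"cells {missing} have no pressure row; pressure "
                      "undefined (set to nan)", stacklevel=2)
    sol, _, rank, sv = np.linalg.lstsq(system.matrix, system.rhs, rcond=None)
    sol = np.where(covered, sol, np.nan)
    pressures = {0: 0.0}
    pressures.update({c: float(p) for c, p in zip(system.cells, sol)})
    resid = float(np.linalg.norm(system.matrix @ np.where(covered, sol, 0.0)
                                 - system.rhs))
    return pressures, {"rank": int(rank), "singular_values": sv,
                       "residual": resid}


# ---------------------------------------------------------------------------
# residuals, stability, stress, compaction
# ---------------------------------------------------------------------------

def junction_residuals(complex_: CellComplex, tensions: dict,
                       weighted: bool = True) -> dict:
    """Squared Young-Dupre residual of the inferred tensions per junction.

    Rows are the three scalar cosine equations; with ``weighted`` they are
    normalized by junction length (the rows are evaluated unit-weight, so
    residuals are comparable across junctions)."""
    out = {}
    for triple, jn in sorted(complex_.junctions.items()):
        jpairs = _junction_pairs(triple)
        if any(p not in jn.angles for p in jpairs):
            continue
        if any(p not in tensions or not np.isfinite(tensions[p])
               for p in jpairs):
            continue
        a = {p: jn.angles[p] for p in jpairs}
        g = {p: tensions[p] for p in jpairs}
        p_ij, p_jk, p_ki = jpairs
        res = 0.0
        for own, o1, o2 in ((p_ij, p_jk, p_ki), (p_jk, p_ki, p_ij),
                            (p_ki, p_ij, p_jk)):
            res += (g[own] + g[o1] * np.cos(a[o2]) + g[o2] * np.cos(a[o1])) ** 2
        if not weighted:
            mean_len = np.mean([j.length for j in complex_.junctions.values()])
            res *= (jn.length / mean_len) ** 2
        out[triple] = float(res)
    return out


def detect_unstable_junctions(junction_tensions: dict) -> tuple[dict, dict]:
    """Triangle-inequality stability test per junction.

    ``junction_tensions`` maps a junction triple to its three tensions (in
    any order). A junction is unstable iff one tension exceeds the sum of
    the other two, the signature of an impending T1 neighbor exchange.
    Returns (flags, summary) where summary holds the unstable percentage
    and, when lengths are supplied as (tensions, length) tuples, the
    unstable length percentage.
    """
    flags = {}
    lengths = {}
    for key, val in junction_tensions.items():
        if isinstance(val, tuple) and len(val) == 2 and np.ndim(val[0]) == 1:
            gam, ln = np.asarray(val[0], dtype=float), float(val[1])
        else:
            gam, ln = np.asarray(val, dtype=float), 1.0
        if gam.shape != (3,):
            raise ValueError(f"junction {key}: need exactly 3 tensions")
        s = gam.sum()
        flags[key] = bool(np.all(2.0 * gam <= s))  # each gamma <= sum of others
        lengths[key] = ln
    n = len(flags)
    unstable = [k for k, ok in flags.items() if not ok]
    tot_len = sum(lengths.values())
    summary = {
        "n_junctions": n,
        "n_unstable": len(unstable),
        "pct_unstable": 100.0 * len(unstable) / n if n else 0.0,
        "pct_unstable_length": (100.0 * sum(lengths[k] for k in unstable)
                                / tot_len if tot_len else 0.0),
    }
    stable = {k: bool(v) for k, v in flags.items()}
    return stable, summary


def stability_report(complex_: CellComplex, tensions: dict) -> tuple[dict, dict]:
    """Stability flags + summary for every junction of a complex."""
    jt = {triple: (np.array([tensions[p] for p in _junction_pairs(triple)]),
                   jn.length)
          for triple, jn in complex_.junctions.items()
          if all(p in tensions and np.isfinite(tensions[p])
                 for p in _junction_pairs(triple))}
    return detect_unstable_junctions(jt)


def cell_stress_tensors(complex_: CellComplex, atlas: ForceAtlas) -> dict:
    """Batchelor coarse-grained stress tensor per cell.

    sigma_c = -p_c I + (1/V_c) * sum over boundary triangles of
    gamma_t * a_t * (I - n n^T), with n the outward unit normal. At Laplace
    equilibrium of an isolated sphere the two terms cancel and sigma = 0.
    """
    mesh = complex_.mesh
    cross = mesh.triangle_cross()
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    out = {}
    for lab, cell in complex_.cells.items():
        idx, sign = mesh.cell_triangle_orientation(lab)
        n_hat = cross[idx] * (sign / np.linalg.norm(cross[idx], axis=1))[:, None]
        gam = np.array([atlas.tensions.get((int(mesh.materials[t, 0]),
                                            int(mesh.materials[t, 1])), 0.0)
                        for t in idx])
        gam = np.nan_to_num(gam)
        a_t = areas[idx]
        surf = np.einsum("t,tij->ij", gam * a_t,
                         np.eye(3)[None] - np.einsum("ti,tj->tij", n_hat, n_hat))
        sigma = -atlas.pressures[lab] * np.eye(3) + surf / cell.volume
        out[lab] = 0.5 * (sigma + sigma.T)
    atlas.stress = out
    return out


def stress_eigensystem(stress: dict) -> dict:
    return {c: np.linalg.eigh(s) for c, s in stress.items()}


def compaction_parameter(complex_: CellComplex | None = None,
                         tensions: dict | None = None) -> dict:
    """Compaction parameter alpha = gamma_cc / (2 gamma_cm).

    Two estimates are returned: from mean inferred tensions of the two
    interface classes, and from geometry as cos(theta / 2) with theta the
    mean cell-medium contact angle at junctions involving the medium (the
    wedge opposite the cell-cell interface). alpha = 1 means no compaction
    (180-degree... vanishing external contact); equal tensions give
    alpha = 0.5 and theta = 120 degrees.
    """
    out = {}
    if tensions:
        cm = [g for p, g in tensions.items() if 0 in p]
        cc = [g for p, g in tensions.items() if 0 not in p]
        if cm and cc:
            out["alpha_tension"] = float(np.mean(cc) / (2.0 * np.mean(cm)))
    if complex_ is not None:
        thetas, weights = [], []
        for triple, jn in complex_.junctions.items():
            if triple[0] != 0 or not jn.angles:
                continue
            # wedge opposite the cell-cell interface = external contact angle
            cc_pair = (triple[1], triple[2])
            if cc_pair in jn.angles:
                thetas.append(jn.angles[cc_pair])
                weights.append(jn.length)
        if thetas:
            theta = float(np.average(thetas, weights=weights))
            out["theta_cm"] = theta
            out["alpha_geometry"] = float(np.cos(theta / 2.0))
    return out


# ---------------------------------------------------------------------------
# one-call inference
# ---------------------------------------------------------------------------

def infer_atlas(complex_: CellComplex, tension_variant: str = "yd",
                pressure_variant: str = "variational_laplace") -> ForceAtlas:
    """Tensions, pressures, residuals, stability, stress and compaction."""
    tsys = assemble_tension_system(complex_, tension_variant)
    tensions, tdiag = solve_tensions(tsys)
    psys = assemble_pressure_system(complex_, tensions, pressure_variant)
    pressures, pdiag = solve_pressures(psys)
    atlas = ForceAtlas(tensions, pressures, tension_variant, pressure_variant,
                       diagnostics={"tension": tdiag, "pressure": pdiag})
    atlas.residuals = junction_residuals(complex_, tensions)
    atlas.stable, summary = stability_report(complex_, tensions)
    atlas.diagnostics["stability"] = summary
    cell_stress_tensors(complex_, atlas)
    comp = compaction_parameter(complex_, tensions)
    atlas.compaction = comp.get("alpha_tension")
    atlas.diagnostics["compaction"] = comp
    return atlas
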