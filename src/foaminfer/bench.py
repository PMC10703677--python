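"""Validation studies: vertex-noise sensitivity and end-to-end pipeline error.

Two benchmarks mirror the package's validation logic:

* sensitivity -- relaxed simulation meshes are perturbed by uniform random
  vertex displacements of increasing amplitude; tensions and pressures are
  re-inferred with every formula variant and compared to the simulation's
  ground truth;
* end-to-end -- simulated foams are voxelized, turned into synthetic
  membrane images, re-segmented, re-meshed and re-inferred: the error of
  the full pipeline against ground truth with no real-data confounders.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cellcomplex as _cx
from . import forces as _forces
from . import foamsim as _sim
from . import synthimg as _img
from .delwatershed import MeshParams, MultimaterialMesh, generate_mesh

logger = logging.getLogger(__name__)


@dataclass
class BenchResult:
    """Tidy benchmark table plus the configuration that produced it."""

    table: pd.DataFrame
    config: dict = field(default_factory=dict)

    def to_csv(self, path):
        self.table.to_csv(path, index=False)
        return path


# ---------------------------------------------------------------------------
# perturbation and error metrics
# ---------------------------------------------------------------------------

def perturb_mesh(mesh: MultimaterialMesh, amplitude: float,
                 seed: int = 0) -> MultimaterialMesh:
    """Displace every vertex by an independent uniform vector in [-a, a]^3
    with a = amplitude x mean edge length; topology is unchanged."""
    a = amplitude * mesh.mean_edge_length()
    rng = np.random.default_rng(seed)
    disp = rng.uniform(-a, a, size=mesh.vertices.shape)
    return MultimaterialMesh(mesh.vertices + disp, mesh.triangles.copy(),
                             mesh.materials.copy())


def tension_error(estimated: dict, truth: dict) -> dict:
    """MSE and mean relative error between tension sets, both normalized to
    mean one over their common interfaces."""
    common = [p for p in estimated
              if p in truth and np.isfinite(estimated[p])]
    if not common:
        return {"mse": np.nan, "mean_relative": np.nan, "n": 0}
    est = np.array([estimated[p] for p in common], dtype=float)
    tru = np.array([truth[p] for p in common], dtype=float)
    est = est / est.mean()
    tru = tru / tru.mean()
    return {"mse": float(np.mean((est - tru) ** 2)),
            "mean_relative": float(np.mean(np.abs(est - tru) / tru)),
            "n": len(common)}


def pressure_error(estimated: dict, truth: dict, eps: float = 1e-9) -> dict:
    """Mean absolute and mean relative pressure error, both referenced to
    the exterior medium (pressure zero)."""
    common = [c for c in estimated
              if c != 0 and c in truth and np.isfinite(estimated[c])]
    if not common:
        return {"absolute": np.nan, "relative": np.nan, "n": 0}
    est = np.array([estimated[c] for c in common], dtype=float)
    tru = np.array([truth[c] for c in common], dtype=float)
    big = np.abs(tru) > eps
    return {"absolute": float(np.mean(np.abs(est - tru))),
            "relative": (float(np.mean(np.abs(est - tru)[big]
                                       / np.abs(tru)[big]))
                         if big.any() else np.nan),
            "n": len(common)}


# ---------------------------------------------------------------------------
# benchmark drivers
# ---------------------------------------------------------------------------

def _infer_errors(mesh, scenario, pressures_true, variants, pressure_variants,
                  angle_method="cmc_fit"):
    rows = []
    cc = _cx.build_cell_complex(mesh, angle_method=angle_method)
    truth = scenario.tension_map()
    # inferred tensions are normalized to mean one over the resolved
    # interfaces; ground-truth pressures correspond to the unnormalized
    # tension table, so they are rescaled into the same units
    present = [p for p in cc.interfaces if p in truth]
    scale = float(np.mean([truth[p] for p in present])) if present else 1.0
    pressures_true = {c: v / scale for c, v in pressures_true.items()}
    gamma_yd = None
    for var in variants:
        try:
            sol, diag = _forces.solve_tensions(
                _forces.assemble_tension_system(cc, var))
        except ValueError as exc:
            logger.warning("variant %s failed: %s", var, exc)
            continue
        err = tension_error(sol, truth)
        rows.append({"kind": "tension", "variant": var, **err})
        if var == "yd":
            gamma_yd = sol
    if gamma_yd is None and variants:
        gamma_yd, _ = _forces.solve_tensions(
            _forces.assemble_tension_system(cc, variants[0]))
    for pvar in pressure_variants:
        try:
            p, _ = _forces.solve_pressures(
                _forces.assemble_pressure_system(cc, gamma_yd, pvar))
        except ValueError as exc:
            logger.warning("pressure variant %s failed: %s", pvar, exc)
            continue
        err = pressure_error(p, pressures_true)
        rows.append({"kind": "pressure", "variant": pvar, **err})
    return rows


def run_sensitivity(scenario_seeds=(1, 2, 3, 4, 5), n_cells=(2, 3, 4, 5, 6),
                    amplitudes=(0.0, 0.1, 0.2, 0.4, 0.6),
                    variants=_forces.TENSION_VARIANTS,
                    pressure_variants=_forces.PRESSURE_VARIANTS,
                    spread: float = 0.4, noise_seed: int = 0,
                    resolution: int = 64,
                    relax_params=None) -> BenchResult:
    """Vertex-noise sensitivity study.

    For every scenario the foam is relaxed once; each amplitude then
    perturbs the relaxed mesh (uniform vertex displacement in units of the
    mean edge length), the geometry is re-measured and every inference
    variant re-run. All amplitudes (including zero) use the first-ring
    (secant) tangent estimator: on smooth simulation meshes it is the more
    accurate one, and a single estimator keeps the error-versus-noise
    curves comparable across amplitudes.
    """
    rows = []
    for k, seed in enumerate(scenario_seeds):
        n_c = n_cells[k % len(n_cells)]
        scenario = _sim.sample_scenario(n_c, spread=spread, seed=seed)
        state = _sim.simulate(scenario, resolution=resolution,
                              params=relax_params)
        for amp in amplitudes:
            mesh = (state.mesh if amp == 0.0 else
                    perturb_mesh(state.mesh, amp, seed=noise_seed + 7919 * k))
            for row in _infer_errors(mesh, scenario, state.pressures,
                                     variants, pressure_variants,
                                     angle_method="secant"):
                rows.append({"scenario": seed, "n_cells": n_c,
                             "amplitude": amp, **row})
    table = pd.DataFrame(rows)
    return BenchResult(table, {"scenario_seeds": list(scenario_seeds),
                               "amplitudes": list(amplitudes),
                               "spread": spread, "noise_seed": noise_seed,
                               "resolution": resolution})


def run_end_to_end(scenario_seeds=(1, 2, 3, 4, 5), n_cells=(3, 4, 5, 6, 8),
                   imaging=None, spread: float = 0.4,
                   variants=("yd",),
                   pressure_variants=("variational_laplace",),
                   resolution: int = 64,
                   relax_params=None,
                   mesh_params=None,
                   refresh_resolution: int = 96) -> BenchResult:
    """Full-pipeline error: simulate -> voxelize -> image -> segment ->
    mesh -> infer, scored against the scenario ground truth."""
    imaging = imaging or _img.ImagingConfig()
    rows = []
    for k, seed in enumerate(scenario_seeds):
        n_c = n_cells[k % len(n_cells)]
        t0 = time.perf_counter()
        scenario = _sim.sample_scenario(n_c, spread=spread, seed=seed)
        state = _sim.simulate(scenario, resolution=resolution,
                              params=relax_params,
                              refresh_resolution=refresh_resolution)
        labels = _img.mesh_to_labels(state.mesh, imaging.shape)
        image = _img.labels_to_image(labels, imaging)
        seg = _img.fallback_segmentation(image, imaging,
                                         expected_cells=scenario.n_c)
        if seg.n_cells == 0:
            logger.warning("scenario %d: segmentation found no cell", seed)
            continue
        seg.voxel_size = labels.voxel_size        # restore physical scale
        mesh = generate_mesh(seg, mesh_params
                             or MeshParams(seed=seed))
        # match segmented labels to simulation labels by mask overlap
        mapping = _match_labels(seg, labels)
        mesh = mesh.permute_labels(mapping)
        for row in _infer_errors(mesh, scenario, state.pressures,
                                 variants, pressure_variants):
            rows.append({"scenario": seed, "n_cells": n_c,
                         "runtime_s": time.perf_counter() - t0, **row})
    table = pd.DataFrame(rows)
    return BenchResult(table, {"scenario_seeds": list(scenario_seeds),
                               "n_cells": list(n_cells), "spread": spread,
                               "shape": imaging.shape,
                               "resolution": resolution})


def _match_labels(seg, truth) -> dict[int, int]:
    """Greedy best-overlap map from segmented labels to true labels."""
    mapping = {0: 0}
    for lab in range(1, seg.n_cells + 1):
        mask = seg.voxels == lab
        cand, counts = np.unique(truth.voxels[mask], return_counts=True)
        mapping[lab] = int(cand[np.argmax(counts)])
    return mapping


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def plot_sensitivity(result: BenchResult, path):
    """Tension MSE and pressure error vs noise amplitude, per variant."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.table
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for kind, metric, ax in (("tension", "mse", axes[0]),
                             ("pressure", "absolute", axes[1])):
        sub = t[t["kind"] == kind]
        for var, g in sub.groupby("variant"):
            agg = g.groupby("amplitude")[metric].agg(["mean", "std"])
            ax.errorbar(agg.index, agg["mean"], yerr=agg["std"],
                        marker="o", capsize=2, label=var)
        ax.set_xlabel("noise amplitude (mean edge lengths)")
        ax.set_ylabel(f"{kind} {metric}")
        ax.set_yscale("log")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_end_to_end(result: BenchResult, path):
    """Box plot of per-scenario relative errors for the full pipeline."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.table
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for kind, metric, ax in (("tension", "mean_relative", axes[0]),
                             ("pressure", "relative", axes[1])):
        sub = t[t["kind"] == kind]
        data = [g[metric].dropna().values for _, g in sub.groupby("variant")]
        names = [v for v, _ in sub.groupby("variant")]
        if data:
            ax.boxplot(data, tick_labels=names)
        ax.set_ylabel(f"{kind} {metric}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
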