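"""Artificial microscopy: mesh -> label masks -> membrane images -> masks.

Closes the validation loop: a simulated foam mesh is voxelized into a
segmentation-style label image, turned into a synthetic confocal
membrane-channel image (membrane indicator, PSF blur, noise), and
re-segmented with a classical seeded watershed. Running the mesh generator
on the result exercises the full pipeline with known ground truth and no
external data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .delwatershed import MultimaterialMesh
from .segio import LabelImage

logger = logging.getLogger(__name__)


@dataclass
class ImagingConfig:
    """Synthetic membrane-channel image parameters.

    shape : lattice size (isotropic cube by default, 200^3).
    membrane_half_thickness : voxels within this distance of an inter-label
        boundary light up (voxels).
    psf_sigma : Gaussian blur sigma emulating the point-spread function
        (voxels).
    snr : peak signal over additive Gaussian noise sigma.
    poisson : add shot noise before the Gaussian read noise.
    h_seed : depth parameter of the h-maxima seed detector used by the
        fallback segmentation (voxels of distance).
    """

    shape: tuple[int, int, int] = (200, 200, 200)
    membrane_half_thickness: float = 1.0
    psf_sigma: float = 1.5
    snr: float = 10.0
    poisson: bool = False
    seed: int = 0
    smooth_sigma: float = 1.0
    h_seed: float = 2.0

    def __post_init__(self):
        if min(self.shape) < 64:
            raise ValueError("image shape must be at least 64^3")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")


# ---------------------------------------------------------------------------
# mesh -> labels
# ---------------------------------------------------------------------------

def _rasterize_cell_axis(verts, tris, shape, axis):
    """Parity crossings of one closed surface along ``axis``.

    Returns a boolean (shape) array: voxel centers with an odd number of
    surface crossings below them along the axis.
    """
    ax_u, ax_v = [a for a in range(3) if a != axis]
    inside = np.zeros(shape, dtype=bool)
    a = verts[tris[:, 0]]
    b = verts[tris[:, 1]]
    c = verts[tris[:, 2]]
    # 2D projections
    pu = np.stack([a[:, ax_u], b[:, ax_u], c[:, ax_u]], axis=1)
    pv = np.stack([a[:, ax_v], b[:, ax_v], c[:, ax_v]], axis=1)
    pw = np.stack([a[:, axis], b[:, axis], c[:, axis]], axis=1)
    n_u, n_v, n_w = shape[ax_u], shape[ax_v], shape[axis]
    for t in range(len(tris)):
        u0, u1, u2 = pu[t]
        v0, v1, v2 = pv[t]
        det = (u1 - u0) * (v2 - v0) - (u2 - u0) * (v1 - v0)
        if abs(det) < 1e-12:
            continue
        lo_u = max(0, int(np.ceil(min(u0, u1, u2))))
        hi_u = min(n_u - 1, int(np.floor(max(u0, u1, u2))))
        lo_v = max(0, int(np.ceil(min(v0, v1, v2))))
        hi_v = min(n_v - 1, int(np.floor(max(v0, v1, v2))))
        if lo_u > hi_u or lo_v > hi_v:
            continue
        gu, gv = np.meshgrid(np.arange(lo_u, hi_u + 1),
                             np.arange(lo_v, hi_v + 1), indexing="ij")
        du = gu - u0
        dv = gv - v0
        l1 = ((v2 - v0) * du - (u2 - u0) * dv) / det
        l2 = (-(v1 - v0) * du + (u1 - u0) * dv) / det
        hit = (l1 >= 0) & (l2 >= 0) & (l1 + l2 <= 1)
        if not hit.any():
            continue
        w = pw[t, 0] + l1[hit] * (pw[t, 1] - pw[t, 0]) + l2[hit] * (pw[t, 2] - pw[t, 0])
        uu = gu[hit]
        vv = gv[hit]
        # voxels with center coordinate > crossing flip parity
        start = np.maximum(np.ceil(w + 1e-12).astype(int), 0)
        for s, iu, iv in zip(start, uu, vv):
            if s >= n_w:
                continue
            sl = [slice(None)] * 3
            sl[ax_u] = iu
            sl[ax_v] = iv
            sl[axis] = slice(s, None)
            inside[tuple(sl)] ^= True
    return inside


def mesh_to_labels(mesh: MultimaterialMesh, shape=(200, 200, 200),
                   margin: float = 0.06) -> LabelImage:
    """Voxelize a multimaterial mesh into a label image.

    The mesh is scaled and translated to fit ``shape`` with a relative
    ``margin``; each voxel center is assigned to the cell whose closed
    surface contains it by axis-parity ray casting, with a majority vote
    over the three axes for robustness at shared faces. The returned
    image's ``voxel_size`` is the inverse scale, so meshing it again
    reproduces the original physical units.
    """
    mesh.check_closed()
    shape = tuple(int(s) for s in shape)
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    extent = (hi - lo).max()
    scale = (min(shape) - 1) * (1.0 - 2.0 * margin) / extent
    offset = margin * (min(shape) - 1) - lo * scale
    verts = mesh.vertices * scale + offset

    cells = [int(c) for c in mesh.material_labels() if c != 0]
    votes = np.zeros((len(cells),) + shape, dtype=np.int8)
    for ci, cell in enumerate(cells):
        idx, sign = mesh.cell_triangle_orientation(cell)
        tris = mesh.triangles[idx].copy()
        flip = sign < 0
        tris[flip] = tris[flip][:, ::-1]
        for axis in range(3):
            votes[ci] += _rasterize_cell_axis(verts, tris, shape, axis)

    best = votes.argmax(axis=0)
    nvotes = votes.max(axis=0)
    labels = np.where(nvotes >= 2, np.asarray(cells, dtype=np.int32)[best], 0)
    multi = (votes >= 2).sum(axis=0) > 1
    if multi.any():
        warnings.warn(f"{int(multi.sum())} voxels claimed by several cells; "
                      "assigned to the first by vote order", stacklevel=2)
    img = LabelImage(labels.astype(np.int32),
                     voxel_size=(1.0 / scale,) * 3)
    # densify in case a cell vanished at this resolution
    labs = np.unique(labels)
    if len(labs) != len(cells) + 1:
        lut = np.zeros(labels.max() + 1, dtype=np.int32)
        lut[labs] = np.arange(len(labs))
        img = LabelImage(lut[labels].astype(np.int32), img.voxel_size,
                         {int(l): int(i) for i, l in enumerate(labs)})
        warnings.warn("some cells vanished during voxelization", stacklevel=2)
    return img


# ---------------------------------------------------------------------------
# labels -> image
# ---------------------------------------------------------------------------

def labels_to_image(image: LabelImage, config: ImagingConfig | None = None
                    ) -> np.ndarray:
    """Synthetic membrane-channel image: indicator -> PSF blur -> noise.

    Voxels within the membrane half-thickness of an inter-label boundary
    (excluding the lattice border) emit; a Gaussian PSF blurs the
    indicator; seeded Gaussian (optionally Poisson) noise is added; the
    result is normalized to [0, 1].
    """
    config = config or ImagingConfig(shape=image.voxels.shape)
    v = image.voxels
    mask = np.zeros(v.shape, dtype=bool)
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        diff = v[tuple(sl_a)] != v[tuple(sl_b)]
        mask[tuple(sl_a)] |= diff
        mask[tuple(sl_b)] |= diff
    if config.membrane_half_thickness > 0:
        dist = ndimage.distance_transform_edt(~mask)
        membrane = dist <= config.membrane_half_thickness
    else:
        membrane = mask
    img = membrane.astype(np.float64)
    if config.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, config.psf_sigma)
    rng = np.random.default_rng(config.seed)
    peak = img.max() or 1.0
    if config.poisson:
        photons = 50.0
        img = rng.poisson(np.clip(img, 0, None) / peak * photons) / photons * peak
    if np.isfinite(config.snr):
        img = img + rng.normal(0.0, peak / config.snr, size=img.shape)
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)


# ---------------------------------------------------------------------------
# classical fallback segmentation
# ---------------------------------------------------------------------------

def fallback_segmentation(image: np.ndarray,
                          config: ImagingConfig | None = None,
                          expected_cells: int | None = None) -> LabelImage:
    """Classical 3D seeded watershed of a membrane image.

    smooth -> Otsu membrane threshold -> distance transform of the
    non-membrane space -> h-maxima seeds -> watershed on the inverted
    distance. Regions touching the lattice border become the exterior
    medium (label 0); the rest are relabeled 1..n_c.
    """
    config = config or ImagingConfig(shape=image.shape)
    img = ndimage.gaussian_filter(np.asarray(image, dtype=np.float64),
                                  config.smooth_sigma)
    try:
        thr = threshold_otsu(img)
    except ValueError:
        warnings.warn("degenerate image histogram; single region",
                      stacklevel=2)
        return LabelImage(np.zeros(image.shape, dtype=np.int32))
    membrane = img > thr
    free = ~membrane
    dist = ndimage.distance_transform_edt(free)
    peaks = h_maxima(dist, config.h_seed)
    markers, n_seeds = ndimage.label(peaks)
    if n_seeds < 2:
        warnings.warn(f"only {n_seeds} watershed seed(s) found", stacklevel=2)
        return LabelImage(np.zeros(image.shape, dtype=np.int32))
    if expected_cells is not None and n_seeds < expected_cells + 1:
        warnings.warn(f"{n_seeds} seeds for {expected_cells} expected cells "
                      "+ medium", stacklevel=2)
    labels = watershed(-dist, markers)
    # regions touching the border form the exterior medium
    border = np.unique(np.concatenate([
        labels[0].ravel(), labels[-1].ravel(),
        labels[:, 0].ravel(), labels[:, -1].ravel(),
        labels[:, :, 0].ravel(), labels[:, :, -1].ravel()]))
    out = labels.copy()
    for lab in border:
        out[labels == lab] = 0
    labs = np.unique(out)
    lut = np.zeros(out.max() + 1, dtype=np.int32)
    lut[labs] = np.arange(len(labs))
    result = LabelImage(lut[out].astype(np.int32))
    logger.info("fallback segmentation: %d seeds -> %d cells",
                n_seeds, result.n_cells)
    return result


def segmentation_jaccard(a: LabelImage, b: LabelImage) -> dict[int, float]:
    """Per-cell Jaccard index between two label images after greedy
    best-overlap matching of b's labels onto a's."""
    out = {}
    for lab in range(1, a.n_cells + 1):
        mask = a.voxels == lab
        cand, counts = np.unique(b.voxels[mask], return_counts=True)
        nz = cand != 0
        if not nz.any():
            out[lab] = 0.0
            continue
        match = cand[nz][np.argmax(counts[nz])]
        other = b.voxels == match
        out[lab] = float((mask & other).sum() / (mask | other).sum())
    return out
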