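"""Label-image input/output and the boundary distance transform.

A segmented aggregate is a 3D lattice of integer cell identities: label 0 is
the exterior medium that surrounds the aggregate, labels 1..n_c are cells.
The Euclidean distance transform (EDT) of the inter-label boundary is the
topographic map that drives mesh generation: it is maximal deep inside cells
and vanishes on membranes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage


class SegmentationError(ValueError):
    """Base class for invalid segmentation inputs."""


class NonIntegerLabelsError(SegmentationError):
    """Raised when a label stack does not hold integer voxels."""


class EmptyImageError(SegmentationError):
    """Raised when a label stack has no voxels."""


class NoMediumError(SegmentationError):
    """Raised when label 0 (exterior medium) is absent."""


class EmptyAggregateError(SegmentationError):
    """Raised when an image contains no cell, only medium."""


@dataclass
class LabelImage:
    """3D integer lattice of cell identities.

    Attributes
    ----------
    voxels : ndarray of int, shape (nz, ny, nx)
        0 = exterior medium, 1..n_c = cells (dense label range).
    voxel_size : tuple of float
        Physical edge length of a voxel per axis (z, y, x).
    relabel_map : dict
        Original label -> dense label, recorded when the input was relabeled.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    relabel_map: dict[int, int] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return int(self.voxels.max())

    def labels(self) -> np.ndarray:
        return np.unique(self.voxels)

    def validate(self) -> None:
        """Check the structural invariants; warn on non-fatal defects."""
        v = self.voxels
        if v.size == 0:
            raise EmptyImageError("empty image")
        if not np.issubdtype(v.dtype, np.integer):
            raise NonIntegerLabelsError(f"label voxels must be integer, got {v.dtype}")
        if v.ndim != 3:
            raise SegmentationError(f"expected a 3D stack, got ndim={v.ndim}")
        labs = np.unique(v)
        if labs[0] != 0:
            raise NoMediumError("no exterior medium: label 0 absent")
        expected = np.arange(labs[-1] + 1)
        if not np.array_equal(labs, expected):
            raise SegmentationError(
                f"label set is not dense 0..n_c: {labs.tolist()}; use read/relabel first"
            )
        border = np.concatenate(
            [v[0].ravel(), v[-1].ravel(), v[:, 0].ravel(), v[:, -1].ravel(),
             v[:, :, 0].ravel(), v[:, :, -1].ravel()]
        )
        if not np.any(border == 0):
            warnings.warn("label 0 does not touch the lattice border; the medium "
                          "should surround the aggregate", stacklevel=2)
        # each cell should be one 6-connected piece
        structure = ndimage.generate_binary_structure(3, 1)
        for lab in labs[1:]:
            _, n_comp = ndimage.label(v == lab, structure=structure)
            if n_comp != 1:
                warnings.warn(f"label {lab} splits into {n_comp} 6-connected "
                              "components", stacklevel=2)


@dataclass
class DistanceMap:
    """Euclidean distance (voxel units) to the nearest inter-label boundary."""

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)


def _relabel_dense(voxels: np.ndarray) -> tuple[np.ndarray, dict[int, int]]:
    labs = np.unique(voxels)
    mapping = {int(old): new for new, old in enumerate(labs)}
    if labs[0] != 0:
        raise NoMediumError("no exterior medium: label 0 absent")
    lut = np.zeros(int(labs[-1]) + 1, dtype=np.int32)
    lut[labs] = np.arange(len(labs))
    return lut[voxels], mapping


def read_label_stack(path, voxel_size=None) -> LabelImage:
    """Read a (multi-page) TIFF of integer labels and validate it.

    Labels are densified to 0..n_c preserving order; the mapping is recorded
    on the returned image. ``voxel_size`` overrides any value stored in the
    TIFF description.
    """
    arr = tifffile.imread(str(path))
    if arr.size == 0:
        raise EmptyImageError(f"{path}: empty image")
    if not np.issubdtype(arr.dtype, np.integer):
        raise NonIntegerLabelsError(f"{path}: voxel type {arr.dtype} is not integer")
    if arr.ndim == 2:
        arr = arr[None]
    if voxel_size is None:
        voxel_size = (1.0, 1.0, 1.0)
        with tifffile.TiffFile(str(path)) as tf:
            desc = tf.pages[0].description
        if desc:
            try:
                meta = json.loads(desc)
                voxel_size = tuple(float(s) for s in meta["voxel_size"])
            except (json.JSONDecodeError, KeyError, TypeError):
                pass
    dense, mapping = _relabel_dense(arr.astype(np.int64))
    img = LabelImage(dense.astype(np.int32), tuple(voxel_size), mapping)
    img.validate()
    return img


def write_label_stack(image: LabelImage, path):
    """Write a LabelImage as a TIFF stack, voxel size in the description tag."""
    image.validate()
    if image.n_cells == 0:
        raise EmptyAggregateError("empty aggregate: image is all medium")
    desc = json.dumps({"voxel_size": list(image.voxel_size)})
    dtype = np.uint16 if image.n_cells < 2**16 else np.uint32
    tifffile.imwrite(str(path), image.voxels.astype(dtype), description=desc)
    return path


def boundary_mask(voxels: np.ndarray) -> np.ndarray:
    """Voxels with a 6-neighbor of a different label, or on the lattice border."""
    mask = np.zeros(voxels.shape, dtype=bool)
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        diff = voxels[tuple(sl_a)] != voxels[tuple(sl_b)]
        mask[tuple(sl_a)] |= diff
        mask[tuple(sl_b)] |= diff
        for edge in (0, -1):
            sl = [slice(None)] * 3
            sl[ax] = edge
            mask[tuple(sl)] = True
    return mask


def boundary_edt(image: LabelImage) -> DistanceMap:
    """Euclidean distance transform to inter-label boundary voxels.

    A voxel is a boundary voxel iff one of its 6 neighbors (or the lattice
    border) carries a different label; distances are measured in voxel units
    to boundary-voxel centers, so boundary voxels have value 0.
    """
    image.validate()
    mask = boundary_mask(image.voxels)
    values = ndimage.distance_transform_edt(~mask)
    return DistanceMap(np.asarray(values, dtype=np.float64), image.voxel_size)
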