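"""Detection and measurement of individual cilia as 3D objects.

Foreground voxels of the segmented marker channel are partitioned into
maximal connected components (default 26-connectivity, so thin diagonal
cilia are not fragmented), components smaller than a voxel-count
threshold are discarded as noise (default 10 voxels: objects *below*
the threshold are removed, a 10-voxel object is kept), and each
surviving component is treated as one cilium whose per-channel mean
intensity is the arithmetic mean over exactly its member voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io_formats import Calibration, ImageStack
from .thresholding import SegmentationMask

__all__ = [
    "CiliumObject",
    "DEFAULT_MIN_VOXELS",
    "label_components",
    "filter_by_volume",
    "measure_intensities",
]

#: Objects with fewer voxels than this are treated as noise and removed.
DEFAULT_MIN_VOXELS = 10

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class CiliumObject:
    """One detected 3D connected component, interpreted as a cilium.

    ``voxel_indices`` is an (n, 3) integer array of (z, y, x) indices;
    centroid is in µm (voxel centers at ``index * voxel_size``).
    Optional fields are filled by :func:`measure_intensities` and by the
    skeleton-based length measurement.
    """

    id: int
    voxel_indices: np.ndarray
    calibration: Calibration
    touches_border: bool = False
    mean_intensity: np.ndarray | None = None
    skeleton: "object | None" = None
    length_um: float | None = None
    total_skeleton_length_um: float | None = None

    def __post_init__(self) -> None:
        self.voxel_indices = np.atleast_2d(
            np.asarray(self.voxel_indices, dtype=np.int64)
        )
        if self.voxel_indices.shape[1] != 3 or len(self.voxel_indices) == 0:
            raise ValueError("voxel_indices must be a nonempty (n, 3) array")

    @property
    def volume_voxels(self) -> int:
        return len(self.voxel_indices)

    @property
    def volume_um3(self) -> float:
        return self.volume_voxels * self.calibration.voxel_volume_um3

    @property
    def centroid(self) -> tuple[float, float, float]:
        cz, cy, cx = self.voxel_indices.mean(axis=0)
        cal = self.calibration
        return (cz * cal.dz, cy * cal.dy, cx * cal.dx)

    def bounding_box(self, pad: int = 0, shape: tuple[int, int, int] | None = None):
        """Slices of the padded bounding box, clipped to ``shape``."""
        lo = self.voxel_indices.min(axis=0) - pad
        hi = self.voxel_indices.max(axis=0) + 1 + pad
        if shape is not None:
            lo = np.maximum(lo, 0)
            hi = np.minimum(hi, shape)
        else:
            lo = np.maximum(lo, 0)
        return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))

    def mask_crop(self, pad: int = 0, shape: tuple[int, int, int] | None = None):
        """Boolean crop of this object within its padded bounding box."""
        box = self.bounding_box(pad, shape)
        crop = np.zeros([s.stop - s.start for s in box], dtype=bool)
        offset = np.array([s.start for s in box])
        idx = self.voxel_indices - offset
        crop[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return crop, box


def label_components(
    mask: SegmentationMask | np.ndarray,
    calibration: Calibration,
    connectivity: int = 26,
) -> list[CiliumObject]:
    """Partition foreground voxels into maximal connected components.

    Labels are assigned in deterministic raster-scan order (z, then y,
    then x, by each component's first voxel).  Components touching the
    stack border are kept but flagged ``touches_border``.
    """
    if connectivity not in _STRUCTS:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTS)}")
    foreground = mask.foreground if isinstance(mask, SegmentationMask) else np.asarray(
        mask, dtype=bool
    )
    labels, n = ndimage.label(foreground, structure=_STRUCTS[connectivity])
    shape = np.array(foreground.shape)
    objects: list[CiliumObject] = []
    all_idx = np.argwhere(labels > 0)
    lab_of = labels[all_idx[:, 0], all_idx[:, 1], all_idx[:, 2]] if len(all_idx) else []
    for obj_id in range(1, n + 1):
        idx = all_idx[lab_of == obj_id]
        touches = bool((idx == 0).any() or (idx == shape - 1).any())
        objects.append(
            CiliumObject(
                id=obj_id,
                voxel_indices=idx,
                calibration=calibration,
                touches_border=touches,
            )
        )
    # scipy assigns labels in raster-scan order already; sort defensively by
    # the first (lexicographically smallest) voxel so the contract holds for
    # any labeling backend.
    objects.sort(key=lambda o: tuple(o.voxel_indices[0]))
    for new_id, obj in enumerate(objects, start=1):
        obj.id = new_id
    return objects


def filter_by_volume(
    objects: Sequence[CiliumObject], min_voxels: int = DEFAULT_MIN_VOXELS
) -> list[CiliumObject]:
    """Remove objects below the size threshold; order is preserved.

    An object of exactly ``min_voxels`` voxels is retained — only
    objects *below* the threshold are treated as noise.
    """
    return [obj for obj in objects if obj.volume_voxels >= min_voxels]


def measure_intensities(
    obj: CiliumObject, stack: ImageStack, t: int = 0
) -> CiliumObject:
    """Fill per-channel mean intensity over exactly the member voxels."""
    shape = stack.spatial_shape
    idx = obj.voxel_indices
    if (idx < 0).any() or (idx >= np.array(shape)).any():
        raise IndexError(f"object {obj.id} has voxels outside the stack")
    volume = stack.volume(t)
    means = volume[:, idx[:, 0], idx[:, 1], idx[:, 2]].mean(axis=1)
    return replace_mean(obj, np.asarray(means, dtype=float))


def replace_mean(obj: CiliumObject, means: np.ndarray) -> CiliumObject:
    new = replace(obj)
    new.mean_intensity = means
    return new
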