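"""Calibrated multi-channel stack I/O.

Internally every stack is held in a single canonical axis order
``(time, channel, z, y, x)``; axes missing on disk are inserted with
length 1.  All indices are 0-based and physical coordinates refer to
voxel centers, ``position = index * voxel_size``.

Calibration precedence when reading: explicit override > OME-XML
metadata > ImageJ/TIFF resolution tags.  A stack without any voxel-size
information is an error, never a silent default — µm lengths are the
headline output of the pipeline.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "Calibration",
    "ImageStack",
    "CalibrationError",
    "read_stack",
    "write_stack",
    "write_mask",
    "read_mask",
    "write_object_table",
    "OBJECT_TABLE_COLUMNS",
]


class CalibrationError(ValueError):
    """No voxel calibration available for a stack that needs one."""


@dataclass(frozen=True)
class Calibration:
    """Physical voxel edge lengths in µm (and optional frame interval, s).

    Confocal stacks of primary cilia are typically recorded with a
    lateral pixel size around 0.2 µm and an axial step of 0.4–0.5 µm,
    i.e. strongly anisotropic voxels.
    """

    dx: float
    dy: float
    dz: float
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError(f"voxel sizes must be positive, got {self}")

    @property
    def voxel_volume_um3(self) -> float:
        return self.dx * self.dy * self.dz

    def as_zyx(self) -> tuple[float, float, float]:
        return (self.dz, self.dy, self.dx)

    def scaled(self, factor: float) -> "Calibration":
        """Calibration of a grid upsampled by ``factor`` per axis."""
        return replace(
            self, dx=self.dx / factor, dy=self.dy / factor, dz=self.dz / factor
        )


@dataclass
class ImageStack:
    """Multi-channel volumetric (optionally time-resolved) image data.

    ``voxels`` is always ``(time, channel, z, y, x)``; use
    :meth:`channel` / :meth:`volume` for convenient views.
    """

    voxels: np.ndarray
    calibration: Calibration
    channel_names: list[str] = field(default_factory=list)
    marker_channel: int = 0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 5:
            raise ValueError(
                f"voxels must be (time, channel, z, y, x), got ndim={self.voxels.ndim}"
            )
        if not self.channel_names:
            self.channel_names = [f"C{i}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length does not match channel axis")
        if not 0 <= self.marker_channel < self.n_channels:
            raise ValueError(
                f"marker_channel {self.marker_channel} invalid for "
                f"{self.n_channels} channels"
            )
        if np.issubdtype(self.voxels.dtype, np.floating) and not np.all(
            np.isfinite(self.voxels)
        ):
            raise ValueError("stack intensities must be finite")

    @property
    def n_timepoints(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[1]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[2:]

    def channel(self, c: int, t: int = 0) -> np.ndarray:
        """3D (z, y, x) view of one channel at one timepoint."""
        if not 0 <= c < self.n_channels:
            raise IndexError(f"channel {c} out of range [0, {self.n_channels})")
        return self.voxels[t, c]

    def volume(self, t: int = 0) -> np.ndarray:
        """4D (channel, z, y, x) view at one timepoint."""
        return self.voxels[t]

    def timepoint(self, t: int) -> "ImageStack":
        return ImageStack(
            self.voxels[t : t + 1],
            self.calibration,
            list(self.channel_names),
            self.marker_channel,
        )


def _normalize_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder/pad an on-disk array with tifffile axis labels to TCZYX."""
    axes = axes.upper().replace("S", "C")  # treat samples-per-pixel as channels
    if "Q" in axes:
        # tifffile labels unknown axes 'Q'; a single unknown leading axis on a
        # 3D grayscale stack is taken as Z.
        if axes.count("Q") == 1 and "Z" in axes.replace("Q", ""):
            raise ValueError(f"ambiguous axis order {axes!r}")
        axes = axes.replace("Q", "Z", 1)
        if "Q" in axes:
            raise ValueError(f"ambiguous axis order {axes!r}")
    if len(set(axes)) != len(axes):
        raise ValueError(f"duplicate axes in {axes!r}")
    unknown = set(axes) - set("TCZYX")
    if unknown:
        raise ValueError(f"unsupported axes {sorted(unknown)} in {axes!r}")
    for ax in "TCZYX":
        if ax not in axes:
            data = data[np.newaxis]
            axes = ax + axes
    order = [axes.index(ax) for ax in "TCZYX"]
    return np.transpose(data, order)


def _calibration_from_ome(ome_xml: str) -> Calibration | None:
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None
    for elem in root.iter():
        if elem.tag.endswith("Pixels"):
            a = elem.attrib
            try:
                dx = float(a["PhysicalSizeX"])
                dy = float(a["PhysicalSizeY"])
                dz = float(a.get("PhysicalSizeZ", a["PhysicalSizeX"]))
            except (KeyError, ValueError):
                return None
            dt = a.get("TimeIncrement")
            return Calibration(dx, dy, dz, float(dt) if dt else None)
    return None


def _calibration_from_tags(tif: tifffile.TiffFile) -> Calibration | None:
    page = tif.pages[0]
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
    except KeyError:
        return None
    unit_scale = 1.0  # resolution tags are written as pixels per µm here
    res_unit = page.tags.get("ResolutionUnit")
    if res_unit is not None and getattr(res_unit.value, "value", res_unit.value) == 3:
        unit_scale = 1e4  # pixels per cm -> pixels per µm
    dx = unit_scale * xres[1] / xres[0] if xres[0] else None
    dy = unit_scale * yres[1] / yres[0] if yres[0] else None
    ij = tif.imagej_metadata or {}
    dz = ij.get("spacing")
    dt = ij.get("finterval")
    if dx is None or dy is None or dz is None:
        return None
    return Calibration(float(dx), float(dy), float(dz), float(dt) if dt else None)


def read_stack(
    path: str | Path,
    marker_channel: int = 0,
    calibration_override: Calibration | None = None,
    channel_names: Sequence[str] | None = None,
) -> ImageStack:
    """Read a TIFF / OME-TIFF z-stack into the canonical TCZYX layout.

    Parameters
    ----------
    path
        TIFF or OME-TIFF file with 2–5 dimensions.
    marker_channel
        Index of the channel carrying the ciliary marker staining
        (e.g. Arl13B or acetylated tubulin); segmentation runs on it.
    calibration_override
        Takes precedence over any calibration found in file metadata.

    Raises
    ------
    CalibrationError
        If neither the file metadata nor ``calibration_override``
        provide voxel sizes.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        voxels = _normalize_axes(data, series.axes)
        calibration = calibration_override
        if calibration is None and tif.ome_metadata:
            calibration = _calibration_from_ome(tif.ome_metadata)
        if calibration is None:
            calibration = _calibration_from_tags(tif)
    if calibration is None:
        raise CalibrationError(
            f"{path}: no voxel calibration in file metadata and no override given"
        )
    negative = np.issubdtype(voxels.dtype, np.signedinteger) and voxels.min() < 0
    if negative or (
        np.issubdtype(voxels.dtype, np.floating) and np.nanmin(voxels) < 0
    ):
        raise ValueError(f"{path}: negative intensities are not supported")
    return ImageStack(
        voxels,
        calibration,
        list(channel_names) if channel_names else [],
        marker_channel,
    )


def _ome_metadata(calibration: Calibration) -> dict:
    md = {
        "axes": "TCZYX",
        "PhysicalSizeX": calibration.dx,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": calibration.dy,
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeZ": calibration.dz,
        "PhysicalSizeZUnit": "µm",
    }
    if calibration.frame_interval is not None:
        md["TimeIncrement"] = calibration.frame_interval
        md["TimeIncrementUnit"] = "s"
    return md


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as OME-TIFF with full voxel calibration metadata."""
    tifffile.imwrite(
        Path(path),
        stack.voxels,
        ome=True,
        photometric="minisblack",
        metadata=_ome_metadata(stack.calibration),
    )


def write_mask(
    mask: np.ndarray, calibration: Calibration, path: str | Path
) -> None:
    """Write a (z, y, x) boolean or label volume as a calibrated OME-TIFF.

    Background is 0; objects keep their integer labels.  Boolean masks
    are stored as 0/255 8-bit for viewer compatibility.
    """
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError(f"mask must be (z, y, x), got ndim={mask.ndim}")
    if mask.dtype == bool:
        out = mask.astype(np.uint8) * 255
    else:
        out = mask.astype(np.min_scalar_type(int(mask.max()) if mask.size else 1))
    tifffile.imwrite(
        Path(path),
        out[np.newaxis, np.newaxis],  # TCZYX
        ome=True,
        photometric="minisblack",
        metadata=_ome_metadata(calibration),
    )


def read_mask(path: str | Path) -> tuple[np.ndarray, Calibration]:
    """Read back a mask/label volume written by :func:`write_mask`."""
    stack = read_stack(path)
    return stack.channel(0), stack.calibration


#: Stable column set of the per-cilium CSV table.
OBJECT_TABLE_COLUMNS = [
    "id",
    "volume_voxels",
    "volume_um3",
    "centroid_z_um",
    "centroid_y_um",
    "centroid_x_um",
    "length_um",
    "total_skeleton_length_um",
    "touches_border",
]


def write_object_table(objects: Sequence, path: str | Path) -> pd.DataFrame:
    """Write one CSV row per measured cilium.

    Columns: id, voxel and physical volume, centroid (µm), skeleton
    lengths (µm; empty when undefined), border flag, then one
    ``mean_intensity_<channel>`` column per channel.  Returns the frame
    that was written so callers can embed it in reports.
    """
    rows = []
    n_channels = 0
    for obj in objects:
        if obj.mean_intensity is not None:
            n_channels = max(n_channels, len(obj.mean_intensity))
    for obj in objects:
        row = {
            "id": obj.id,
            "volume_voxels": obj.volume_voxels,
            "volume_um3": obj.volume_um3,
            "centroid_z_um": obj.centroid[0],
            "centroid_y_um": obj.centroid[1],
            "centroid_x_um": obj.centroid[2],
            "length_um": obj.length_um,
            "total_skeleton_length_um": obj.total_skeleton_length_um,
            "touches_border": obj.touches_border,
        }
        if obj.length_um is None:
            logger.warning("cilium %s has no length measurement", obj.id)
        for c in range(n_channels):
            row[f"mean_intensity_{c}"] = (
                obj.mean_intensity[c] if obj.mean_intensity is not None else None
            )
        rows.append(row)
    columns = OBJECT_TABLE_COLUMNS + [f"mean_intensity_{c}" for c in range(n_channels)]
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(Path(path), index=False)
    return frame
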