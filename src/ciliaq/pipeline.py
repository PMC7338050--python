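"""Pipeline orchestration: segment → label → filter → measure → skeletonize.

`run_pipeline` executes the full single-stack workflow with every
applied parameter logged; `run_timelapse` repeats it per frame and
links detections into per-cilium traces.  Errors are re-raised with the
failing stage named, so a degenerate input (e.g. an all-zero stack that
yields a single-level histogram) fails cleanly at thresholding.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .analysis import GateParams, Track, track_over_time
from .components import (
    DEFAULT_MIN_VOXELS,
    CiliumObject,
    filter_by_volume,
    label_components,
    measure_intensities,
)
from .io_formats import ImageStack
from .skeletonize import SkelParams, measure_cilium
from .thresholding import segment_marker
from .timeseries import BleedthroughParams

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "StageError", "run_pipeline", "run_timelapse"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the quantification workflow.

    Defaults are the standard analysis parameters: 10-voxel size
    filter, 26-connectivity, 3× upscaling with sigma-3 blur for the
    skeleton, α=0.75 / β=0.02 bleed-through coefficients and the
    7.5 a.u. expression gate.
    """

    marker_channel: int = 0
    threshold_method: str = "renyi"
    manual_threshold: float | None = None
    connectivity: int = 26
    min_voxels: int = DEFAULT_MIN_VOXELS
    skel: SkelParams = SkelParams()
    gate: GateParams = GateParams()
    bleedthrough: BleedthroughParams = BleedthroughParams()
    skeletonize: bool = True
    max_displacement_um: float = 2.0
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def annotate(self, frame: pd.DataFrame) -> pd.DataFrame:
        frame = frame.copy()
        frame["config_hash"] = self.config_hash()
        frame["software_version"] = __version__
        return frame


@dataclass
class PipelineResult:
    objects: list[CiliumObject]
    table: pd.DataFrame
    label_image: np.ndarray
    threshold: float
    n_objects_prefilter: int


def _object_table(objects: Sequence[CiliumObject], config: PipelineConfig) -> pd.DataFrame:
    from .io_formats import OBJECT_TABLE_COLUMNS

    n_channels = max(
        (len(o.mean_intensity) for o in objects if o.mean_intensity is not None),
        default=0,
    )
    rows = []
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
        for c in range(n_channels):
            row[f"mean_intensity_{c}"] = (
                None if obj.mean_intensity is None else obj.mean_intensity[c]
            )
        rows.append(row)
    columns = OBJECT_TABLE_COLUMNS + [f"mean_intensity_{c}" for c in range(n_channels)]
    return config.annotate(pd.DataFrame(rows, columns=columns))


def run_pipeline(
    stack: ImageStack, config: PipelineConfig = PipelineConfig(), t: int = 0
) -> PipelineResult:
    """Quantify every cilium in one (single-timepoint) stack."""
    if config.marker_channel != stack.marker_channel:
        stack = ImageStack(
            stack.voxels, stack.calibration, list(stack.channel_names),
            config.marker_channel,
        )
    try:
        mask = segment_marker(stack, config.manual_threshold, t)
    except Exception as exc:  # noqa: BLE001 - re-tag with stage context
        raise StageError("thresholding", exc) from exc
    logger.info(
        "threshold=%.4g on channel %d; %d foreground voxels",
        mask.threshold_used, stack.marker_channel, mask.n_foreground,
    )

    try:
        objects = label_components(mask, stack.calibration, config.connectivity)
    except Exception as exc:  # noqa: BLE001
        raise StageError("labeling", exc) from exc
    n_pre = len(objects)
    objects = filter_by_volume(objects, config.min_voxels)
    logger.info(
        "objects: %d detected, %d after %d-voxel size filter",
        n_pre, len(objects), config.min_voxels,
    )

    try:
        objects = [measure_intensities(o, stack, t) for o in objects]
        if config.skeletonize:
            objects = [measure_cilium(o, stack, config.skel) for o in objects]
    except Exception as exc:  # noqa: BLE001
        raise StageError("measurement", exc) from exc

    label_image = np.zeros(stack.spatial_shape, dtype=np.int32)
    for obj in objects:
        idx = obj.voxel_indices
        label_image[idx[:, 0], idx[:, 1], idx[:, 2]] = obj.id
    table = _object_table(objects, config)
    return PipelineResult(objects, table, label_image, mask.threshold_used, n_pre)


def run_timelapse(
    stack: ImageStack, config: PipelineConfig = PipelineConfig()
) -> tuple[list[Track], pd.DataFrame]:
    """Per-frame quantification plus nearest-centroid linking.

    Skeletonization is controlled by ``config.skeletonize`` (biosensor
    recordings typically need intensities, not lengths).  Frames where segmentation degenerates (e.g. empty frames) contribute
    no detections but do not abort the recording.
    """
    if stack.n_timepoints < 2:
        raise ValueError("time-lapse analysis needs at least 2 timepoints")
    per_frame: list[list[CiliumObject]] = []
    for t in range(stack.n_timepoints):
        try:
            result = run_pipeline(stack, config, t=t)
            per_frame.append(result.objects)
        except StageError as exc:
            logger.warning("frame %d skipped (%s)", t, exc)
            per_frame.append([])
    tracks = track_over_time(per_frame, config.max_displacement_um)
    rows = []
    for track in tracks:
        for frame, obj in zip(track.frames, track.objects):
            row = {
                "track_id": track.id,
                "frame": frame,
                "time_s": (
                    frame * stack.calibration.frame_interval
                    if stack.calibration.frame_interval is not None
                    else frame
                ),
                "volume_voxels": obj.volume_voxels,
                "length_um": obj.length_um,
            }
            if obj.mean_intensity is not None:
                for c, value in enumerate(obj.mean_intensity):
                    row[f"mean_intensity_{c}"] = value
            rows.append(row)
    table = config.annotate(pd.DataFrame(rows))
    return tracks, table
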