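"""Downstream per-cilium analysis for expression-controlled experiments.

Ectopic expression of a ciliary construct lengthens cilia once its
ciliary level is high, so length comparisons are restricted to a low
expression regime: the mean ciliary fluorescence of non-transfected
control cells is subtracted from every cilium's mean intensity, cilia
at or above a fluorescence gate (default 7.5 a.u., strict ``<`` keeps
only values below it) are excluded, and treated-cell lengths are
expressed as a percentage of the control-cell mean.  A linear fit of
length on ciliary intensity with a zero-slope test quantifies the
expression/length correlation that motivates the gate.  A greedy
nearest-centroid linker turns per-frame detections of time-lapse
recordings into per-cilium traces.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .components import CiliumObject

__all__ = [
    "GateParams",
    "LengthIntensityFit",
    "DEFAULT_GATE_THRESHOLD",
    "subtract_control_background",
    "gate_by_expression",
    "normalize_lengths_to_control",
    "length_intensity_fit",
    "track_over_time",
]

#: Cilia with gated-channel intensity at or above this (a.u.) are excluded.
DEFAULT_GATE_THRESHOLD = 7.5


@dataclass(frozen=True)
class GateParams:
    """Expression gate: channel, strict upper bound, prior background."""

    gate_channel: int = 1
    gate_threshold: float = DEFAULT_GATE_THRESHOLD
    control_background: float = 0.0

    def __post_init__(self) -> None:
        if self.gate_threshold <= 0:
            raise ValueError("gate_threshold must be > 0")
        if self.control_background < 0:
            raise ValueError("control_background must be >= 0")


def _require_measured(obj: CiliumObject, channel: int) -> float:
    if obj.mean_intensity is None or channel >= len(obj.mean_intensity):
        raise ValueError(f"object {obj.id} has no measured intensity for channel {channel}")
    return float(obj.mean_intensity[channel])


def subtract_control_background(
    objects: Sequence[CiliumObject],
    control_objects: Sequence[CiliumObject],
    channel: int,
) -> list[CiliumObject]:
    """Subtract the mean ciliary fluorescence of control cilia.

    The background is the arithmetic mean over the control objects'
    per-cilium mean intensities in ``channel`` (non-transfected cells
    carry only autofluorescence/bleed signal there).
    """
    if not control_objects:
        raise ValueError("control_objects must be nonempty")
    background = float(
        np.mean([_require_measured(c, channel) for c in control_objects])
    )
    out = []
    for obj in objects:
        _require_measured(obj, channel)
        new = replace(obj)
        new.mean_intensity = np.array(obj.mean_intensity, dtype=float)
        new.mean_intensity[channel] -= background
        out.append(new)
    return out


def gate_by_expression(
    objects: Sequence[CiliumObject], params: GateParams = GateParams()
) -> list[CiliumObject]:
    """Keep exactly the cilia whose gated intensity is strictly below the gate.

    Assumes control background has already been subtracted (or is set in
    ``params.control_background``, subtracted here before comparing).
    """
    kept = []
    for obj in objects:
        value = _require_measured(obj, params.gate_channel) - params.control_background
        if value < params.gate_threshold:
            kept.append(obj)
    return kept


def normalize_lengths_to_control(
    treated: Sequence[float], control: Sequence[float]
) -> np.ndarray:
    """Lengths as percent of the control-cell mean length.

    ``treated[i] * 100 / mean(control)``; with treated == control the
    normalized mean is exactly 100%.
    """
    control_arr = np.asarray(control, dtype=float)
    if control_arr.size == 0 or not np.all(np.isfinite(control_arr)):
        raise ValueError("control lengths must be nonempty and finite")
    mean = control_arr.mean()
    if mean <= 0:
        raise ValueError("control mean length must be > 0")
    return np.asarray(treated, dtype=float) * 100.0 / mean


class LengthIntensityFit(NamedTuple):
    slope: float  # µm per a.u.
    intercept: float  # µm
    correlation: float  # Pearson r
    p_value: float  # two-sided test of zero slope


def length_intensity_fit(
    objects: Sequence[CiliumObject], channel: int
) -> LengthIntensityFit:
    """OLS fit of cilium length on ciliary intensity with zero-slope test."""
    pairs = [
        (_require_measured(obj, channel), obj.length_um)
        for obj in objects
        if obj.length_um is not None
    ]
    if len(pairs) < 3:
        raise ValueError("need at least 3 cilia with defined lengths")
    intensity = np.array([p[0] for p in pairs])
    length = np.array([p[1] for p in pairs])
    if np.ptp(intensity) == 0:
        raise ValueError("intensity is constant; slope undefined")
    result = stats.linregress(intensity, length)
    return LengthIntensityFit(
        float(result.slope),
        float(result.intercept),
        float(result.rvalue),
        float(result.pvalue),
    )


@dataclass
class Track:
    """One linked cilium across frames: per-frame object references."""

    id: int
    frames: list[int]
    objects: list[CiliumObject]

    def mean_intensity_trace(self, channel: int) -> np.ndarray:
        return np.array(
            [_require_measured(obj, channel) for obj in self.objects], dtype=float
        )


def track_over_time(
    frames: Sequence[Sequence[CiliumObject]], max_displacement_um: float = 2.0
) -> list[Track]:
    """Greedy nearest-centroid frame-to-frame linking of detections.

    Every detection belongs to exactly one track; detections farther
    than ``max_displacement_um`` from any open track start a new one.
    Links are assigned closest-pair-first, so two well-separated
    stationary cilia can never swap.
    """
    tracks: list[Track] = []
    open_tracks: list[Track] = []
    next_id = 1
    for t, detections in enumerate(frames):
        detections = list(detections)
        pairs = []
        for i, track in enumerate(open_tracks):
            prev = np.array(track.objects[-1].centroid)
            for j, obj in enumerate(detections):
                d = float(np.linalg.norm(prev - np.array(obj.centroid)))
                if d <= max_displacement_um:
                    pairs.append((d, i, j))
        pairs.sort()
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for d, i, j in pairs:
            if i in used_tracks or j in used_dets:
                continue
            open_tracks[i].frames.append(t)
            open_tracks[i].objects.append(detections[j])
            used_tracks.add(i)
            used_dets.add(j)
        still_open = [tr for i, tr in enumerate(open_tracks) if i in used_tracks]
        for j, obj in enumerate(detections):
            if j in used_dets:
                continue
            track = Track(id=next_id, frames=[t], objects=[obj])
            next_id += 1
            tracks.append(track)
            still_open.append(track)
        open_tracks = still_open
    # tracks were appended on creation in first-seen order; ensure stable ids
    return tracks
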