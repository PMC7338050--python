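"""Global Renyi-entropy segmentation of the ciliary marker channel.

The segmentation threshold is computed once per stack, from the
256-level histogram of a maximum-intensity projection of the marker
channel, and then applied to every z-slice.  The threshold selection
follows the Renyi-entropy procedure of Sahoo, Wilkins & Yeager (1997)
exactly as coded in the ImageJ Auto_Threshold plugin: three candidate
levels maximizing the Renyi entropy of the background/foreground
partition at orders ρ→1 (the Kapur limit), ρ=1/2 and ρ=2 are sorted and
combined with a weighting rule that depends on whether the sorted
candidates fall within 5 gray levels of each other.

Two conventions are fixed here and documented because the original
plugin leaves them implicit for >8-bit data:

* the histogram always has 256 bins spanning ``[min, max]`` of the
  projection, so the procedure depends only on the histogram *shape*
  (affine intensity rescaling does not change the mask);
* the returned threshold is the *upper edge* of the optimal bin on the
  intensity scale, and a voxel is foreground iff its intensity is
  strictly greater than the threshold.  For 8-bit integer data this
  reproduces ImageJ's "value > level" semantics bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ImageStack

__all__ = [
    "Histogram",
    "SegmentationMask",
    "DegenerateHistogramError",
    "max_project",
    "renyi_entropy_level",
    "renyi_entropy_threshold",
    "apply_threshold",
    "segment_marker",
]

N_BINS = 256

#: Sorted Renyi candidates closer than this many gray levels count as one mode.
_CLOSE_LEVELS = 5


class DegenerateHistogramError(ValueError):
    """Histogram with fewer than two occupied bins: nothing to separate."""


@dataclass(frozen=True)
class Histogram:
    """Gray-level distribution of a projection image.

    ``counts[i]`` is the number of pixels falling in
    ``[bin_edges[i], bin_edges[i+1])`` (the last bin is closed).
    """

    counts: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=float))
        if self.counts.ndim != 1 or self.bin_edges.shape != (len(self.counts) + 1,):
            raise ValueError("counts must be 1D with len(bin_edges) = n_bins + 1")
        if (self.counts < 0).any() or self.counts.sum() == 0:
            raise ValueError("histogram counts must be non-negative with total > 0")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @classmethod
    def from_image(cls, image: np.ndarray, n_bins: int = N_BINS) -> "Histogram":
        """256-bin histogram over the image's own [min, max] range."""
        image = np.asarray(image)
        lo, hi = float(image.min()), float(image.max())
        if hi == lo:
            hi = lo + 1.0  # single-valued image: one occupied bin
        counts, edges = np.histogram(image, bins=n_bins, range=(lo, hi))
        return cls(counts, edges)


@dataclass
class SegmentationMask:
    """Boolean foreground volume (z, y, x) plus provenance."""

    foreground: np.ndarray
    threshold_used: float
    source_channel: int

    def __post_init__(self) -> None:
        self.foreground = np.asarray(self.foreground, dtype=bool)
        if self.foreground.ndim != 3:
            raise ValueError("mask must be (z, y, x)")

    @property
    def n_foreground(self) -> int:
        return int(self.foreground.sum())


def max_project(stack: ImageStack, channel: int | None = None, t: int = 0) -> np.ndarray:
    """Maximum-intensity projection of one channel over z.

    Pixel (y, x) of the result is the maximum over all z-slices of that
    channel at timepoint ``t``.
    """
    if channel is None:
        channel = stack.marker_channel
    return stack.channel(channel, t).max(axis=0)


def renyi_entropy_level(counts: np.ndarray) -> int:
    """Optimal threshold *bin index* by the Renyi-entropy combination rule.

    Returns the level ``k`` such that bins ``<= k`` are background and
    bins ``> k`` are foreground.  Deterministic: within each Renyi
    order, the lowest level attaining the maximal entropy wins.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if (counts > 0).sum() < 2:
        raise DegenerateHistogramError(
            "need at least two occupied gray levels to compute a threshold"
        )
    p = counts / total
    P1 = np.cumsum(p)
    P2 = 1.0 - P1

    eps = np.finfo(float).eps
    first_bin = int(np.argmax(np.abs(P1) >= eps))
    last_candidates = np.nonzero(np.abs(P2) >= eps)[0]
    last_bin = int(last_candidates[-1])
    it = np.arange(first_bin, last_bin + 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        # order ρ -> 1 (Kapur/Shannon limit)
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
        c_plogp = np.cumsum(plogp)
        ent_back = -(c_plogp[it] / P1[it]) + np.log(P1[it])
        tail = c_plogp[-1] - c_plogp[it]
        ent_obj = -(tail / P2[it]) + np.log(P2[it])
        tot1 = ent_back + ent_obj
        t_star2 = _argmax_from(tot1, it)

        # order ρ = 1/2
        c_sqrt = np.cumsum(np.sqrt(p))
        back = c_sqrt[it] / np.sqrt(P1[it])
        obj = (c_sqrt[-1] - c_sqrt[it]) / np.sqrt(P2[it])
        prod = back * obj
        tot_half = np.where(prod > 0, np.log(np.where(prod > 0, prod, 1.0)), 0.0) / (
            1.0 - 0.5
        )
        t_star1 = _argmax_from(tot_half, it)

        # order ρ = 2
        c_sq = np.cumsum(p * p)
        back = c_sq[it] / (P1[it] * P1[it])
        obj = (c_sq[-1] - c_sq[it]) / (P2[it] * P2[it])
        prod = back * obj
        tot2 = np.where(prod > 0, np.log(np.where(prod > 0, prod, 1.0)), 0.0) / (
            1.0 - 2.0
        )
        t_star3 = _argmax_from(tot2, it)

    t1, t2, t3 = sorted((t_star1, t_star2, t_star3))
    if abs(t1 - t2) <= _CLOSE_LEVELS:
        beta = (1, 2, 1) if abs(t2 - t3) <= _CLOSE_LEVELS else (0, 1, 3)
    else:
        beta = (3, 1, 0) if abs(t2 - t3) <= _CLOSE_LEVELS else (1, 2, 1)
    omega = P1[t3] - P1[t1]
    opt = int(
        t1 * (P1[t1] + 0.25 * omega * beta[0])
        + 0.25 * t2 * omega * beta[1]
        + t3 * (P2[t3] + 0.25 * omega * beta[2])
    )
    return opt


def _argmax_from(values: np.ndarray, candidates: np.ndarray) -> int:
    """Lowest candidate with entropy strictly above all earlier ones and > 0.

    Mirrors the reference loop ``if (max_ent < tot_ent)`` with
    ``max_ent`` initialized to 0 and threshold initialized to 0.
    """
    best, best_level = 0.0, 0
    for level, v in zip(candidates, values):
        if v > best:
            best, best_level = float(v), int(level)
    return best_level


def renyi_entropy_threshold(hist: Histogram) -> float:
    """Threshold on the intensity scale from a projection histogram.

    The optimal bin index from :func:`renyi_entropy_level` is mapped to
    the upper edge of that bin, so foreground membership under the
    strict ``intensity > threshold`` rule equals bin-index membership
    ``bin > level``.  The result always lies strictly between the lowest
    and highest occupied intensity levels.
    """
    level = renyi_entropy_level(hist.counts)
    return float(hist.bin_edges[level + 1])


def apply_threshold(
    stack: ImageStack, channel: int, threshold: float, t: int = 0
) -> SegmentationMask:
    """Binarize one channel of the 3D stack: foreground iff value > threshold."""
    volume = stack.channel(channel, t)
    return SegmentationMask(volume > threshold, float(threshold), channel)


def segment_marker(
    stack: ImageStack, manual_threshold: float | None = None, t: int = 0
) -> SegmentationMask:
    """Segment the marker channel of a stack.

    The threshold is computed from the 256-bin histogram of the
    maximum-intensity projection of the marker channel (or taken from
    ``manual_threshold`` as an escape hatch) and applied globally to the
    full 3D channel with strict-greater semantics.
    """
    if manual_threshold is not None:
        return apply_threshold(stack, stack.marker_channel, manual_threshold, t)
    projection = max_project(stack, stack.marker_channel, t)
    hist = Histogram.from_image(projection)
    threshold = renyi_entropy_threshold(hist)
    return apply_threshold(stack, stack.marker_channel, threshold, t)
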