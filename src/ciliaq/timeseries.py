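"""Biosensor trace corrections for ratiometric cAMP/Ca²⁺ recordings.

Covers the arithmetic applied to per-ROI fluorescence traces:

* background subtraction per channel,
* FRET bleed-through / cross-excitation correction
  ``FRET_corrected = FRET − α·cerulean − β·citrine`` with the
  experimentally determined defaults α = 0.75 (donor emission leaking
  into the acceptor filter) and β = 0.02 (direct acceptor excitation),
* framewise channel ratios (cerulean/FRET_corrected, cerulean/citrine,
  mCherry/cpGFP), with zero-denominator frames flagged invalid (NaN)
  rather than silently becoming infinite,
* normalization to the mean over a pre-stimulus baseline window,
* plate-reader Ca²⁺ normalization
  ``(F − F_baseline) / (F_ionomycin − F_baseline) [/ positive_fraction]``.

Frames are sampled every few seconds (5 s in the reference recordings,
stimulus added after 120 s, i.e. a 24-frame baseline); the default
baseline window is all frames strictly before the stimulus frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TimeSeriesTrace",
    "BleedthroughParams",
    "PlateReaderPoints",
    "background_subtract",
    "fret_bleedthrough_correct",
    "estimate_bleedthrough",
    "ratio_trace",
    "baseline_normalize",
    "plate_reader_normalize",
]


@dataclass(frozen=True)
class BleedthroughParams:
    """Linear spectral-correction coefficients for the FRET channel."""

    alpha: float = 0.75  # donor (cerulean) bleed-through fraction
    beta: float = 0.02  # acceptor (citrine) cross-excitation fraction

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("bleed-through coefficients must be >= 0")


@dataclass
class TimeSeriesTrace:
    """Per-ROI fluorescence over frames, one row per channel.

    ``values`` has shape (n_channels, n_frames); invalid frames are
    NaN.  ``baseline_window`` is a half-open frame range ``(start,
    stop)`` with ``stop <= stimulus_frame``; by default it spans every
    frame strictly before the stimulus.
    """

    values: np.ndarray
    frame_times: np.ndarray
    stimulus_frame: int | None = None
    baseline_window: tuple[int, int] | None = None
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.values.shape[1] != len(self.frame_times):
            raise ValueError("values and frame_times disagree on frame count")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if self.stimulus_frame is not None:
            if not 0 < self.stimulus_frame <= self.n_frames:
                raise ValueError("stimulus_frame leaves no baseline frames")
            if self.baseline_window is None:
                self.baseline_window = (0, self.stimulus_frame)
        if self.baseline_window is not None:
            start, stop = self.baseline_window
            if not (0 <= start < stop <= self.n_frames):
                raise ValueError("baseline_window must be a nonempty frame range")
            if self.stimulus_frame is not None and stop > self.stimulus_frame:
                raise ValueError("baseline_window must precede the stimulus frame")
        if not self.channel_names:
            self.channel_names = [f"C{i}" for i in range(self.n_channels)]

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def channel(self, key: int | str) -> np.ndarray:
        if isinstance(key, str):
            key = self.channel_names.index(key)
        return self.values[key]

    def with_values(self, values: np.ndarray) -> "TimeSeriesTrace":
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[1] != self.n_frames:
            raise ValueError("trace operations must preserve the frame count")
        new = replace(self)
        new.values = values
        new.channel_names = (
            list(self.channel_names) if values.shape[0] == self.n_channels else []
        )
        if not new.channel_names:
            new.channel_names = [f"C{i}" for i in range(values.shape[0])]
        return new


@dataclass(frozen=True)
class PlateReaderPoints:
    """Raw plate-reader fluorescence and its normalization anchors."""

    F: float | np.ndarray
    F_baseline: float
    F_ionomycin: float
    positive_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.F_ionomycin == self.F_baseline:
            raise ValueError("F_ionomycin must differ from F_baseline")
        if self.positive_fraction is not None and not 0 < self.positive_fraction <= 1:
            raise ValueError("positive_fraction must be in (0, 1]")


def background_subtract(
    trace: TimeSeriesTrace, background: float | np.ndarray
) -> TimeSeriesTrace:
    """Subtract a per-channel background constant from every frame."""
    bg = np.asarray(background, dtype=float).reshape(-1)
    if bg.size == 1:
        bg = np.repeat(bg, trace.n_channels)
    if bg.size != trace.n_channels:
        raise ValueError("need one background value per channel")
    return trace.with_values(trace.values - bg[:, None])


def fret_bleedthrough_correct(
    fret_raw: float | np.ndarray,
    cerulean: float | np.ndarray,
    citrine: float | np.ndarray,
    params: BleedthroughParams = BleedthroughParams(),
):
    """Remove donor bleed-through and acceptor cross-excitation.

    ``FRET_corrected = FRET − α·cerulean − β·citrine``.
    """
    return (
        np.asarray(fret_raw, dtype=float)
        - params.alpha * np.asarray(cerulean, dtype=float)
        - params.beta * np.asarray(citrine, dtype=float)
    )


def estimate_bleedthrough(
    acceptor_channel: np.ndarray, donor_channel: np.ndarray
) -> float:
    """Bleed-through coefficient from a single-fluorophore control trace.

    Least-squares slope through the origin of acceptor-channel on
    donor-channel signal: with only one fluorophore present, all
    acceptor-channel signal is leakage, so the slope is the fraction to
    subtract.  This is a simple, reproducible stand-in for interactive
    colocalization-based estimation.
    """
    x = np.asarray(donor_channel, dtype=float).ravel()
    y = np.asarray(acceptor_channel, dtype=float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise ValueError("control trace has no signal in the donor channel")
    return float(np.dot(x, y) / denom)


def ratio_trace(numerator: np.ndarray, denominator: np.ndarray) -> np.ndarray:
    """Framewise quotient; zero-denominator frames become NaN (invalid)."""
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if num.shape != den.shape:
        raise ValueError("numerator and denominator must have the same frame count")
    out = np.full_like(num, np.nan, dtype=float)
    valid = den != 0
    np.divide(num, den, out=out, where=valid)
    return out


def baseline_normalize(trace: TimeSeriesTrace) -> TimeSeriesTrace:
    """Divide every frame by the per-channel mean over the baseline window.

    After normalization, the mean over baseline frames is exactly 1 per
    channel (within floating-point round-off).  Idempotent.
    """
    if trace.baseline_window is None:
        raise ValueError("trace has no baseline window (set stimulus_frame)")
    start, stop = trace.baseline_window
    baseline = np.nanmean(trace.values[:, start:stop], axis=1)
    if np.any(baseline == 0) or not np.all(np.isfinite(baseline)):
        raise ValueError("baseline mean is zero or undefined for some channel")
    return trace.with_values(trace.values / baseline[:, None])


def plate_reader_normalize(points: PlateReaderPoints):
    """Normalized plate-reader Ca²⁺ response.

    ``(F − F_baseline) / (F_ionomycin − F_baseline)``, divided by the
    fraction of reporter-positive cells when that fraction is given
    (population recordings where only transfected cells respond).
    """
    value = (np.asarray(points.F, dtype=float) - points.F_baseline) / (
        points.F_ionomycin - points.F_baseline
    )
    if points.positive_fraction is not None:
        value = value / points.positive_fraction
    return value if value.ndim else float(value)
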