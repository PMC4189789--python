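"""Per-pixel Fourier quantification of periodic intrinsic optical signals.

A whisker is deflected periodically (one brief stimulus train every
``repetition_period`` seconds) while tissue reflectance is imaged.  Each
pixel's time series therefore contains a small periodic modulation at the
stimulus-repetition frequency (0.05 Hz for a 20 s period).  The analysis
extracts, for every pixel, the fractional reflectance change dR/R at that
frequency — the amplitude of the stimulus-locked sinusoidal component divided
by the pixel's own mean reflectance — plus its phase, and summarises the
responsive region as the number of pixels exceeding a grid of dR/R
thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class ImageStack:
    """Reflectance time series, ``data`` shaped (frames, rows, cols)."""

    data: np.ndarray
    frame_rate: float  # Hz

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be 3-D (frames, rows, cols), got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite values")
        if not (np.isfinite(self.frame_rate) and self.frame_rate > 0):
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def duration(self) -> float:
        """Total duration in seconds."""
        return self.n_frames / self.frame_rate


@dataclass(frozen=True)
class StimulusProtocol:
    """Periodic single-whisker deflection protocol.

    One 3 s train of 3 Hz sinusoidal deflections (~15 degrees) is delivered
    every 20 s, repeated 35 times; the analysis only consumes the repetition
    frequency ``1/repetition_period``.
    """

    repetition_period: float = 20.0  # s
    train_frequency: float = 3.0  # Hz
    train_duration: float = 3.0  # s
    n_repeats: int = 35
    deflection_degrees: float = 15.0  # metadata only

    def __post_init__(self) -> None:
        if self.repetition_period <= self.train_duration:
            raise ValueError("repetition_period must exceed train_duration")
        if self.repetition_period <= 0:
            raise ValueError("repetition_period must be positive")

    @property
    def stim_frequency(self) -> float:
        return 1.0 / self.repetition_period


@dataclass
class ResponseMap:
    """Per-pixel dR/R magnitude and phase at the stimulus frequency."""

    magnitude: np.ndarray  # rows x cols, dimensionless, NaN where undefined
    phase: np.ndarray  # rows x cols, radians in (-pi, pi]
    stim_frequency: float
    bin_factor: int = 1

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.magnitude.shape != self.phase.shape:
            raise ValueError("magnitude and phase shapes differ")
        finite = np.isfinite(self.magnitude)
        if np.any(self.magnitude[finite] < 0):
            raise ValueError("magnitude must be non-negative")


@dataclass
class ThresholdCurve:
    """Pixel counts above each of an ascending grid of dR/R thresholds."""

    thresholds: np.ndarray
    pixel_counts: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.pixel_counts = np.asarray(self.pixel_counts, dtype=int)
        if self.thresholds.shape != self.pixel_counts.shape:
            raise ValueError("thresholds and pixel_counts must align")


@dataclass(frozen=True)
class EffectResult:
    F: float
    df_num: float
    df_den: float
    p: float


@dataclass
class GroupComparison:
    """Two-way (group x threshold) ANOVA on threshold-curve pixel counts."""

    group: EffectResult
    threshold: EffectResult
    interaction: EffectResult


def spatial_bin(stack: ImageStack, bin_factor: int) -> ImageStack:
    """Average ``bin_factor`` x ``bin_factor`` pixel blocks within each frame.

    Frame count and frame rate are unchanged; dimensions must be divisible by
    the factor.
    """
    if bin_factor < 1 or int(bin_factor) != bin_factor:
        raise ValueError(f"bin_factor must be a positive integer, got {bin_factor}")
    bin_factor = int(bin_factor)
    if bin_factor == 1:
        return ImageStack(stack.data.copy(), stack.frame_rate)
    n, r, c = stack.data.shape
    if r % bin_factor or c % bin_factor:
        raise ValueError(
            f"image dimensions ({r}, {c}) are not divisible by bin_factor {bin_factor}"
        )
    binned = stack.data.reshape(n, r // bin_factor, bin_factor, c // bin_factor, bin_factor)
    return ImageStack(binned.mean(axis=(2, 4)), stack.frame_rate)


def stimulus_bin_index(n_frames: int, frame_rate: float, stim_frequency: float) -> int:
    """FFT bin of the stimulus frequency; requires a whole number of cycles.

    The stack must span an integer number of stimulus periods so that the
    stimulus frequency falls exactly on a DFT bin — otherwise spectral
    leakage silently biases every magnitude, so the mismatch is an error.
    """
    k_exact = stim_frequency * n_frames / frame_rate
    k = int(round(k_exact))
    if abs(k_exact - k) > 1e-9:
        raise ValueError(
            f"stimulus frequency {stim_frequency} Hz does not fall on an FFT bin: "
            f"{k_exact:.6f} cycles in {n_frames} frames at {frame_rate} Hz "
            "(stack must span a whole number of stimulus periods)"
        )
    if k < 2:
        raise ValueError(f"need at least 2 full stimulus cycles, got {k}")
    if k > n_frames // 2:
        raise ValueError(f"stimulus bin {k} exceeds the Nyquist bin {n_frames // 2}")
    return k


def compute_response_map(
    stack: ImageStack,
    protocol: StimulusProtocol,
    bin_factor: int = 1,
    detrend: str = "mean",
) -> ResponseMap:
    """Extract per-pixel dR/R magnitude and phase at the stimulus frequency.

    For each pixel with time series ``x_t`` and temporal mean ``m``, the
    complete series is Fourier transformed and the fractional amplitude of the
    component at the stimulus frequency is ``2 |X(f_stim)| / (n m)`` — exactly
    the amplitude ``A`` of a sinusoid ``m (1 + A cos(2 pi f t + phi))``.
    Phase is the argument of ``X(f_stim)``.

    Parameters
    ----------
    bin_factor : spatial binning applied before the transform.
    detrend : ``"mean"`` (subtract the temporal mean; the default — a nonzero
        bin is insensitive to the offset anyway) or ``"linear"`` (remove a
        least-squares line first).

    Pixels with non-positive mean reflectance cannot be normalised; their
    magnitude and phase are NaN and a warning is issued.
    """
    if bin_factor != 1:
        stack = spatial_bin(stack, bin_factor)
    data = stack.data
    n = stack.n_frames
    k = stimulus_bin_index(n, stack.frame_rate, protocol.stim_frequency)

    mean = data.mean(axis=0)
    series = data - mean
    if detrend == "linear":
        t = np.arange(n, dtype=float) - (n - 1) / 2.0
        slope = np.tensordot(t, series, axes=(0, 0)) / np.dot(t, t)
        series = series - t[:, None, None] * slope[None, :, :]
    elif detrend != "mean":
        raise ValueError(f"unknown detrend mode {detrend!r}")

    coef = np.fft.rfft(series, axis=0)[k]
    bad = mean <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        magnitude = 2.0 * np.abs(coef) / (n * mean)
    phase = np.angle(coef)
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} pixel(s) with non-positive mean reflectance set to NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        magnitude = np.where(bad, np.nan, magnitude)
        phase = np.where(bad, np.nan, phase)
    return ResponseMap(magnitude=magnitude, phase=phase,
                       stim_frequency=protocol.stim_frequency, bin_factor=bin_factor)


def default_threshold_grid(
    maps: ResponseMap | Sequence[ResponseMap],
    n_thresholds: int = 10,
    lo_percentile: float = 50.0,
    hi_percentile: float = 99.5,
) -> np.ndarray:
    """Evenly spaced dR/R thresholds between magnitude percentiles.

    When several maps are given the percentiles are taken over their pooled
    finite magnitudes, giving a grid shared by every map in a comparison.
    """
    if isinstance(maps, ResponseMap):
        maps = [maps]
    values = np.concatenate([m.magnitude[np.isfinite(m.magnitude)].ravel() for m in maps])
    if values.size == 0:
        raise ValueError("no finite magnitudes to build a threshold grid from")
    lo, hi = np.percentile(values, [lo_percentile, hi_percentile])
    if not hi > lo:
        raise ValueError("degenerate magnitude distribution: percentile range is empty")
    return np.linspace(lo, hi, n_thresholds)


def threshold_curve(
    response: ResponseMap,
    thresholds: Sequence[float],
    roi: Optional[np.ndarray] = None,
) -> ThresholdCurve:
    """Count pixels with magnitude strictly greater than each threshold.

    ``roi`` optionally restricts the count to a boolean pixel mask; NaN
    magnitudes (flagged pixels) never count.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.ndim != 1 or thresholds.size == 0:
        raise ValueError("thresholds must be a non-empty 1-D sequence")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly ascending")
    mag = response.magnitude
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != mag.shape:
            raise ValueError(f"ROI shape {roi.shape} does not match map shape {mag.shape}")
        if not roi.any():
            raise ValueError("ROI mask is empty")
        mag = mag[roi]
    values = mag[np.isfinite(mag)].ravel()
    counts = (values[None, :] > thresholds[:, None]).sum(axis=1)
    return ThresholdCurve(thresholds=thresholds, pixel_counts=counts)


def compare_threshold_curves(
    group_a: Sequence[ThresholdCurve],
    group_b: Sequence[ThresholdCurve],
    labels: tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """Two-way ANOVA (group x threshold) on pixel counts across animals.

    Each curve is one animal; counts at every threshold enter an ordinary
    two-way ANOVA with group and threshold as categorical factors plus their
    interaction (type-II sums of squares).  All curves must share one
    threshold grid and each group needs at least two animals.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 threshold curves per group")
    grid = group_a[0].thresholds
    rows = []
    for label, curves in zip(labels, (group_a, group_b)):
        for i, curve in enumerate(curves):
            if curve.thresholds.shape != grid.shape or not np.allclose(
                curve.thresholds, grid, rtol=0, atol=0
            ):
                raise ValueError("all curves must share an identical threshold grid")
            for j, count in enumerate(curve.pixel_counts):
                rows.append({"group": label, "unit": f"{label}{i}", "thr": j, "count": float(count)})
    df = pd.DataFrame(rows)
    fit = smf.ols("count ~ C(group) * C(thr)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    df_den = float(table.loc["Residual", "df"])

    def effect(name: str) -> EffectResult:
        row = table.loc[name]
        return EffectResult(F=float(row["F"]), df_num=float(row["df"]),
                            df_den=df_den, p=float(row["PR(>F)"]))

    return GroupComparison(
        group=effect("C(group)"),
        threshold=effect("C(thr)"),
        interaction=effect("C(group):C(thr)"),
    )
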