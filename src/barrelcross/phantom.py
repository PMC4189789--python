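"""Synthetic intrinsic-signal imaging stacks with exact ground truth.

The phantom emulates what periodic single-whisker stimulation produces in
barrel cortex reflectance movies: a compact Gaussian-profiled region whose
reflectance is modulated at the stimulus-repetition frequency (0.05 Hz for a
20 s period), riding on a large static baseline together with slow drift,
narrow-band physiological confounds (respiration/heartbeat surrogates) and
white camera noise.  Every nuisance component sits on a non-stimulus DFT bin,
so the Fourier readout of a noiseless phantom is exact and the ground-truth
amplitude map returned with the stack is the analytic answer, not an estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ois import ImageStack, stimulus_bin_index


@dataclass(frozen=True)
class OISPhantomConfig:
    """Phantom parameters.

    Defaults compress a 35-repeat, 20 s-period acquisition to desk scale:
    700 frames at 1 frame/s keep the stimulus exactly 35 cycles on bin 35,
    and only frequency relationships matter to the analysis.  ``peak_drr`` is
    the fractional reflectance modulation at the blob centre (dimensionless);
    baseline, noise, drift and confound amplitudes are in camera units.
    """

    n_frames: int = 700
    frame_rate: float = 1.0  # Hz
    stim_frequency: float = 0.05  # Hz
    image_shape: tuple[int, int] = (64, 64)  # rows, cols
    blob_center: tuple[float, float] = (32.0, 32.0)  # row, col
    blob_sigma: float = 6.0  # pixels
    peak_drr: float = 1e-3
    baseline_reflectance: float = 1000.0
    white_noise_sd: float = 2.0
    drift_amplitude: float = 5.0
    confound_frequencies: tuple[float, ...] = (0.35, 0.45)  # Hz, 7x / 9x stim bin
    confound_amplitude: float = 5.0
    waveform: str = "sine"  # "sine" or "boxcar"
    train_duty: float = 0.15  # on-fraction per period, boxcar mode only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_rate <= 0 or self.stim_frequency <= 0:
            raise ValueError("frame_rate and stim_frequency must be positive")
        # whole number of stimulus cycles => stimulus frequency on an FFT bin
        stimulus_bin_index(self.n_frames, self.frame_rate, self.stim_frequency)
        if self.peak_drr < 0:
            raise ValueError("peak_drr must be non-negative")
        if self.blob_sigma <= 0:
            raise ValueError("blob_sigma must be positive")
        r, c = self.blob_center
        nr, nc = self.image_shape
        pad = 3.0 * self.blob_sigma
        if not (pad <= r <= nr - 1 - pad and pad <= c <= nc - 1 - pad):
            raise ValueError(
                f"blob at {self.blob_center} with sigma {self.blob_sigma} is not "
                f"fully inside a {self.image_shape} image at 3 sigma"
            )
        if self.baseline_reflectance <= 0:
            raise ValueError("baseline_reflectance must be positive")
        if self.white_noise_sd < 0 or self.drift_amplitude < 0 or self.confound_amplitude < 0:
            raise ValueError("noise/drift/confound amplitudes must be non-negative")
        if self.waveform not in ("sine", "boxcar"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if not 0 < self.train_duty < 1:
            raise ValueError("train_duty must be in (0, 1)")
        k_stim = round(self.stim_frequency * self.n_frames / self.frame_rate)
        for f in self.confound_frequencies:
            k = f * self.n_frames / self.frame_rate
            if abs(k - round(k)) > 1e-9:
                raise ValueError(f"confound frequency {f} Hz is not on an FFT bin")
            if round(k) == k_stim:
                raise ValueError(f"confound frequency {f} Hz collides with the stimulus bin")
            if round(k) > self.n_frames // 2 or round(k) < 1:
                raise ValueError(f"confound frequency {f} Hz is outside (0, Nyquist]")

    @property
    def stimulus_bin(self) -> int:
        return round(self.stim_frequency * self.n_frames / self.frame_rate)


@dataclass
class Phantom:
    """Generated stack plus the analytic amplitude map the analysis should recover."""

    stack: ImageStack
    truth: np.ndarray  # rows x cols fundamental dR/R amplitude
    config: OISPhantomConfig


def gaussian_blob(config: OISPhantomConfig) -> np.ndarray:
    """Peak-normalised Gaussian spatial profile of the responsive region."""
    nr, nc = config.image_shape
    rows = np.arange(nr, dtype=float)[:, None]
    cols = np.arange(nc, dtype=float)[None, :]
    d2 = (rows - config.blob_center[0]) ** 2 + (cols - config.blob_center[1]) ** 2
    return np.exp(-d2 / (2.0 * config.blob_sigma**2))


def _boxcar_fundamental(config: OISPhantomConfig, period_frames: int, on_frames: int) -> float:
    """Normalised |DFT| of the tiled unit boxcar at the stimulus bin.

    The stack holds k periods of an ``on_frames``-wide boxcar, so
    ``|X_k| = k sin(pi k L / n) / sin(pi k / n)``; dividing by ``n`` gives
    the per-frame coefficient the dR/R readout normalises with.
    """
    n = config.n_frames
    k = config.stimulus_bin
    num = math.sin(math.pi * k * on_frames / n)
    den = math.sin(math.pi * k / n)
    return k * abs(num / den) / n


def generate_ois_stack(config: OISPhantomConfig) -> Phantom:
    """Generate a phantom reflectance stack and its ground-truth amplitude map.

    Pixel (r, c) is ``B (1 + A_rc w(t))`` plus drift, confounds and white
    noise, where ``A_rc = peak_drr exp(-d^2 / (2 sigma^2))`` and ``w`` is a
    unit cosine at the stimulus frequency (default) or a periodic boxcar with
    ``train_duty`` on-fraction.  The returned ``truth`` map is the fractional
    amplitude of the stimulus-frequency component exactly as the Fourier
    readout defines it (including, in boxcar mode, the small mean shift the
    on-phase adds to the normalising baseline).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_frames
    t = np.arange(n, dtype=float) / config.frame_rate
    amp = config.peak_drr * gaussian_blob(config)
    B = config.baseline_reflectance

    if config.waveform == "sine":
        w = np.cos(2.0 * math.pi * config.stim_frequency * t)
        truth = amp.copy()
    else:
        period_frames = round(n / config.stimulus_bin)
        if period_frames * config.stimulus_bin != n:
            raise ValueError(
                "boxcar mode needs a whole number of frames per stimulus period "
                f"({n} frames / bin {config.stimulus_bin})"
            )
        on_frames = max(1, round(config.train_duty * period_frames))
        w = ((np.arange(n) % period_frames) < on_frames).astype(float)
        duty = on_frames / period_frames
        # readout normalises by the pixel's own mean B (1 + A duty)
        fund = 2.0 * _boxcar_fundamental(config, period_frames, on_frames)
        truth = fund * amp / (1.0 + amp * duty)

    data = B * (1.0 + amp[None, :, :] * w[:, None, None])

    nuisance = np.zeros(n)
    if config.drift_amplitude > 0:
        nuisance += config.drift_amplitude * np.sin(2.0 * math.pi * t / (n / config.frame_rate))
    for f in config.confound_frequencies:
        if config.confound_amplitude > 0:
            phase = rng.uniform(0.0, 2.0 * math.pi)
            nuisance += config.confound_amplitude * np.sin(2.0 * math.pi * f * t + phase)
    data += nuisance[:, None, None]

    if config.white_noise_sd > 0:
        data += rng.normal(0.0, config.white_noise_sd, size=data.shape)

    return Phantom(stack=ImageStack(data, config.frame_rate), truth=truth, config=config)
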