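"""Spectrotemporal contours: the per-frame dominant-frequency trace of a call."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Grid steps of the default short-time analysis (250 kHz audio, 512-sample
# window, 75% overlap).  Contours built outside a spectrogram (e.g. ideal
# trajectories from the generator) use these so that grid-normalized
# quantities such as sinuosity are computed on the same lattice.
DEFAULT_FRAME_STEP_S = 128 / 250_000  # 0.512 ms hop
DEFAULT_BIN_STEP_KHZ = 250_000 / 512 / 1000  # 0.488 kHz


@dataclass
class Contour:
    """Ordered (time, frequency, magnitude) points for one detected call.

    Parameters
    ----------
    times : array of float
        Frame-center times in seconds, strictly increasing, uniform spacing.
    freqs_khz : array of float
        Contour frequency per frame, kHz.
    mags : array of float
        Per-frame magnitude (spectrogram power at the ridge).
    frame_step_s : float
        Spacing of the time grid (STFT hop), seconds.
    bin_step_khz : float
        Spacing of the frequency grid (STFT bin), kHz.
    frame_bw_khz : array of float, optional
        Active bandwidth of the detected component per frame (used by
        noise-rejection rules; empty if not from a detector).
    call_id : int, optional
    """

    times: np.ndarray
    freqs_khz: np.ndarray
    mags: np.ndarray
    frame_step_s: float = DEFAULT_FRAME_STEP_S
    bin_step_khz: float = DEFAULT_BIN_STEP_KHZ
    frame_bw_khz: np.ndarray = field(default_factory=lambda: np.empty(0))
    call_id: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.freqs_khz = np.asarray(self.freqs_khz, dtype=float)
        self.mags = np.asarray(self.mags, dtype=float)
        self.frame_bw_khz = np.asarray(self.frame_bw_khz, dtype=float)
        if self.times.size < 2:
            raise ValueError("a contour needs at least 2 points")
        if self.times.size != self.freqs_khz.size or self.times.size != self.mags.size:
            raise ValueError("times, freqs_khz and mags must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("contour times must be strictly increasing")
        if self.frame_step_s <= 0 or self.bin_step_khz <= 0:
            raise ValueError("grid steps must be positive")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def onset_s(self) -> float:
        """Estimated call onset: first frame center minus half a frame step."""
        return max(0.0, float(self.times[0]) - self.frame_step_s / 2)

    @property
    def duration_ms(self) -> float:
        """Span of the contour plus one frame step, in ms."""
        return (float(self.times[-1] - self.times[0]) + self.frame_step_s) * 1000.0

    def shifted(self, dt_s: float) -> "Contour":
        """Copy of the contour with all times translated by ``dt_s`` seconds."""
        return Contour(
            times=self.times + dt_s,
            freqs_khz=self.freqs_khz.copy(),
            mags=self.mags.copy(),
            frame_step_s=self.frame_step_s,
            bin_step_khz=self.bin_step_khz,
            frame_bw_khz=self.frame_bw_khz.copy(),
            call_id=self.call_id,
        )
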