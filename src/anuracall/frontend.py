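"""Time-domain front end: pre-emphasis and windowed framing.

Pre-emphasis is the first-order high-pass s'(n) = s(n) - alpha*s(n-1) that
lifts the high-frequency band (where the SNR of vocal sound is worst) before
spectral analysis. Framing cuts the signal into windows of duration Tw
advanced by a shift Ts and multiplies each by a window function; the frame
length in samples is N = round(rate * Tw / 1000).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio import AudioSignal

WINDOW_KINDS = ("rectangular", "hamming")


@dataclass(frozen=True)
class FramingOptions:
    """Window kind, duration Tw and shift Ts (both milliseconds)."""

    window: str = "hamming"
    tw_ms: float = 30.0
    ts_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.window not in WINDOW_KINDS:
            raise ValueError(f"window must be one of {WINDOW_KINDS}")
        if not (0 < self.ts_ms <= self.tw_ms):
            raise ValueError("require 0 < Ts <= Tw")


@dataclass
class FrameMatrix:
    """Windowed frames: F rows of N samples each, plus start times (s)."""

    frames: np.ndarray
    rate: float
    options: FramingOptions
    start_times: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_length(self) -> int:
        return self.frames.shape[1]


def round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def samples_per_window(rate: float, tw_ms: float) -> int:
    """Frame length N = round(rate * Tw / 1000), round-half-up.

    At 44.1 kHz and Tw = 30 ms this is exactly 44.1 * 30 = 1323; rounding
    only matters for durations such as 25 ms (1102.5 -> 1103).
    """
    return round_half_up(rate * tw_ms / 1000.0)


def pre_emphasize(signal: AudioSignal, alpha: float) -> AudioSignal:
    """Apply s'(n) = s(n) - alpha * s(n-1), with s(-1) = 0.

    ``alpha`` must lie in [0, 1); alpha = 0 is the identity.
    """
    if not (0 <= alpha < 1):
        raise ValueError(f"pre-emphasis alpha must be in [0, 1), got {alpha}")
    s = signal.samples
    out = s - alpha * np.concatenate(([0.0], s[:-1]))
    return signal.replace(samples=out)


def hamming_weights(n: int, convention: str = "periodic") -> np.ndarray:
    """Hamming window weights over indices 0..N-1.

    The raised-cosine form 0.54 +/- 0.46*cos(2*pi*n/N) admits two phasings:

    - ``periodic`` (default): 0.54 - 0.46*cos(2*pi*n/N), minimum 0.08 at the
      edges and maximum 1 at the window centre (exactly 1 for even N);
    - ``centred``: 0.54 + 0.46*cos(2*pi*m/N) with m measured from the window
      centre — the same window written with its peak at the origin.
    """
    if n < 2:
        raise ValueError("window length must be at least 2 samples")
    idx = np.arange(n)
    if convention == "periodic":
        return 0.54 - 0.46 * np.cos(2 * np.pi * idx / n)
    if convention == "centred":
        m = idx - (n - 1) / 2
        return 0.54 + 0.46 * np.cos(2 * np.pi * m / n)
    raise ValueError(f"unknown Hamming convention {convention!r}")


def window_weights(kind: str, n: int) -> np.ndarray:
    if kind == "rectangular":
        return np.ones(n)
    if kind == "hamming":
        return hamming_weights(n)
    raise ValueError(f"unknown window kind {kind!r}")


def frame_signal(signal: AudioSignal, options: FramingOptions) -> FrameMatrix:
    """Cut the signal into F = floor((L - N)/S) + 1 overlapping windowed
    frames; trailing samples that do not fill a window are discarded.

    Rejects signals shorter than one window.
    """
    n = samples_per_window(signal.rate, options.tw_ms)
    s_shift = round_half_up(signal.rate * options.ts_ms / 1000.0)
    length = signal.samples.size
    if length < n:
        raise ValueError(
            f"signal of {length} samples is shorter than one window "
            f"({n} samples at Tw={options.tw_ms} ms)")
    n_frames = (length - n) // s_shift + 1
    starts = np.arange(n_frames) * s_shift
    idx = starts[:, None] + np.arange(n)[None, :]
    frames = signal.samples[idx] * window_weights(options.window, n)[None, :]
    return FrameMatrix(frames=frames, rate=signal.rate, options=options,
                       start_times=starts / signal.rate)
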