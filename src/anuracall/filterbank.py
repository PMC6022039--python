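"""Per-frame power spectra, mel scale, filter banks and filter-bank energies.

The filter-bank energy (FBE) summarizes a K-bin power spectrum with only M
values, one per band filter. Two bank geometries are provided: contiguous
equal-width rectangular bands, and mel-warped triangular filters evenly
spaced on the mel axis with 50 % overlap (HTK geometry, unit-peak triangles).

The mel scale used is m = c * ln(1 + f/700). The conventional anchor places
1000 mel at 1 kHz, which fixes c = 1000/ln(1 + 1000/700) ~= 1127.01; a legacy
constant of 1197 is also selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .frontend import FrameMatrix

#: anchored constant: hz_to_mel(1000) == 1000 exactly
MEL_CONSTANT_ANCHORED = 1000.0 / np.log(1.0 + 1000.0 / 700.0)
#: alternative printed in parts of the literature
MEL_CONSTANT_LEGACY = 1197.0


@dataclass
class PowerSpectrum:
    """One-sided per-frame power spectra (F x K) on a common bin grid."""

    power: np.ndarray        # F x K, non-negative
    freqs: np.ndarray        # K bin centre frequencies, Hz
    rate: float
    nfft: int

    @property
    def n_frames(self) -> int:
        return self.power.shape[0]


@dataclass
class FilterBankSpec:
    """Bank of M band filters as per-filter weight vectors over the bins."""

    kind: str                # "rectangular" | "mel"
    m: int
    lf: float
    hf: float
    weights: np.ndarray      # M x K
    freqs: np.ndarray        # K bin frequencies the weights refer to
    edges: np.ndarray        # band edges: M+1 (rect) or M+2 (mel) Hz values

    @property
    def centres(self) -> np.ndarray:
        if self.kind == "mel":
            return self.edges[1:-1]
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def to_frame(self) -> pd.DataFrame:
        """Filter geometry (index, lower/centre/upper Hz) for export."""
        if self.kind == "mel":
            lower, centre, upper = self.edges[:-2], self.edges[1:-1], self.edges[2:]
        else:
            lower, upper = self.edges[:-1], self.edges[1:]
            centre = 0.5 * (lower + upper)
        return pd.DataFrame({"filter": np.arange(1, self.m + 1),
                             "lower_hz": lower, "centre_hz": centre,
                             "upper_hz": upper})


@dataclass
class FBEMatrix:
    """Per-frame filter-bank energies (F x M), linear or log scale."""

    energies: np.ndarray
    scale: str               # "linear" | "log"
    spec: FilterBankSpec

    @property
    def m(self) -> int:
        return self.energies.shape[1]


def next_pow2(n: int) -> int:
    return 1 << max(0, int(np.ceil(np.log2(max(1, n)))))


def power_spectrum(frames: FrameMatrix, nfft: int | None = None) -> PowerSpectrum:
    """One-sided power spectrum of every frame.

    The normalization satisfies Parseval: the sum of the K bin powers of a
    frame equals the energy (sum of squares) of its windowed samples. ``nfft``
    defaults to the next power of two at or above the frame length, with
    zero-padding.
    """
    if frames.n_frames == 0:
        raise ValueError("no frames to transform")
    n = frames.frame_length
    if nfft is None:
        nfft = next_pow2(n)
    if nfft < n:
        raise ValueError("nfft must be at least the frame length")
    spec = np.fft.rfft(frames.frames, nfft, axis=1)
    power = np.abs(spec) ** 2 / nfft
    # fold the negative-frequency half into bins 1..nfft/2-1
    power[:, 1:-1] *= 2.0
    if nfft % 2:  # odd nfft: the last bin is not Nyquist, fold it too
        power[:, -1] *= 2.0
    freqs = np.fft.rfftfreq(nfft, 1.0 / frames.rate)
    return PowerSpectrum(power=power, freqs=freqs, rate=frames.rate, nfft=nfft)


def hz_to_mel(f, constant: float = MEL_CONSTANT_ANCHORED):
    """Mel value of frequency ``f`` (Hz): m = c * ln(1 + f/700)."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    out = constant * np.log1p(f / 700.0)
    return out.item() if out.ndim == 0 else out


def mel_to_hz(m, constant: float = MEL_CONSTANT_ANCHORED):
    """Inverse mel warp: f = 700 * (exp(m/c) - 1)."""
    m = np.asarray(m, dtype=float)
    out = 700.0 * np.expm1(m / constant)
    return out.item() if out.ndim == 0 else out


def design_filterbank(kind: str, m: int, lf: float, hf: float, rate: float,
                      nfft: int,
                      mel_constant: float = MEL_CONSTANT_ANCHORED,
                      ) -> FilterBankSpec:
    """Design a bank of ``m`` filters covering [lf, hf].

    rectangular
        M contiguous equal-width bands partitioning [lf, hf]; every spectrum
        bin inside the range belongs to exactly one band (weight 1).
    mel
        M isosceles triangles with centres evenly spaced on the mel axis and
        50 % overlap (each triangle's feet are its neighbours' centres),
        normalized to unit peak.
    """
    if not (0 <= lf < hf <= rate / 2):
        raise ValueError("require 0 <= Lf < Hf <= rate/2")
    if m < 1:
        raise ValueError("filter count M must be >= 1")
    freqs = np.fft.rfftfreq(nfft, 1.0 / rate)

    if kind == "rectangular":
        edges = np.linspace(lf, hf, m + 1)
        weights = np.zeros((m, freqs.size))
        # assign each in-range bin to exactly one band (upper edge inclusive
        # only for the last band) so the bank partitions the in-band bins
        band = np.searchsorted(edges, freqs, side="right") - 1
        in_range = (freqs >= lf) & (freqs <= hf)
        band = np.clip(band, 0, m - 1)
        for j in range(m):
            weights[j, in_range & (band == j)] = 1.0
    elif kind == "mel":
        mel_edges = np.linspace(hz_to_mel(lf, mel_constant),
                                hz_to_mel(hf, mel_constant), m + 2)
        edges = mel_to_hz(mel_edges, mel_constant)
        weights = np.zeros((m, freqs.size))
        for j in range(m):
            left, centre, right = edges[j], edges[j + 1], edges[j + 2]
            up = (freqs - left) / (centre - left)
            down = (right - freqs) / (right - centre)
            weights[j] = np.clip(np.minimum(up, down), 0.0, 1.0)
    else:
        raise ValueError(f"unknown filter bank kind {kind!r}")

    if np.any(weights.sum(axis=1) <= 0):
        raise ValueError(
            f"frequency band [{lf}, {hf}] Hz is too narrow for M={m} filters "
            f"at a bin resolution of {rate / nfft:.2f} Hz")
    return FilterBankSpec(kind=kind, m=m, lf=lf, hf=hf, weights=weights,
                          freqs=freqs, edges=edges)


def apply_filterbank(spectrum: PowerSpectrum, spec: FilterBankSpec) -> FBEMatrix:
    """Filter-bank energies: weighted sums of bin powers per filter."""
    if spectrum.freqs.size != spec.freqs.size or not np.allclose(
            spectrum.freqs, spec.freqs):
        raise ValueError("spectrum and filter bank use different bin grids")
    energies = spectrum.power @ spec.weights.T
    return FBEMatrix(energies=energies, scale="linear", spec=spec)


def log_scale(fbe: FBEMatrix, floor: float | None = None) -> FBEMatrix:
    """Natural log of the energies, clamped below at ``floor``.

    The default floor is 1e-12 times the largest energy in the matrix, which
    keeps silent bands finite without compressing the useful dynamics.
    """
    if fbe.scale == "log":
        raise ValueError("energies are already log-scaled")
    if floor is None:
        peak = float(np.max(fbe.energies)) if fbe.energies.size else 0.0
        floor = 1e-12 * peak if peak > 0 else 1e-300
    out = np.log(np.maximum(fbe.energies, floor))
    return FBEMatrix(energies=out, scale="log", spec=fbe.spec)
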