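"""Cepstral representation of log filter-bank energies.

The log-FBE of a frame is treated as a short real "signal" over the filter
index and expanded on an orthonormal Fourier-type basis — the spectrum of a
spectrum, i.e. the cepstrum. Two bases are supported:

``dct``
    Orthonormal DCT-II, the natural choice given the even symmetry of a
    spectrum; truncating it gives the classical MFCC.
``dft``
    Real discrete Fourier expansion with the cosine/sine pair of each
    harmonic packed into consecutive real coefficients (orthonormal, so
    Parseval holds and truncation errors are comparable with the DCT).

Coefficient counting: "C cepstral coefficients" keeps quefrency indices
1..C, excluding the mean term c0 (HTK convention), for C <= M-1. C = M
returns the complete orthonormal set including the mean term. The mean term
is always carried alongside so the log-FBE can be approximately
reconstructed from a truncated cepstrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.fft

from .filterbank import FBEMatrix, FilterBankSpec


@dataclass
class CepstraMatrix:
    """Per-frame cepstral coefficients c_ik (F frames x C coefficients)."""

    coeffs: np.ndarray        # F x C
    indices: np.ndarray       # quefrency index of each retained column
    c0: np.ndarray            # F mean terms (kept for reconstruction)
    transform: str            # "dct" | "dft"
    m: int                    # source filter count
    liftered: bool = False
    lifter_l: float | None = None
    spec: FilterBankSpec | None = None

    @property
    def c(self) -> int:
        return self.coeffs.shape[1]

    @property
    def n_frames(self) -> int:
        return self.coeffs.shape[0]


@lru_cache(maxsize=8)
def _dft_basis(m: int) -> np.ndarray:
    """Orthonormal real-DFT basis, columns ordered mean, cos1, sin1, cos2...

    Column 0 is the constant 1/sqrt(M); each harmonic k contributes a cosine
    and a sine column with norm sqrt(2/M); for even M the final (Nyquist)
    column is the alternating sequence with norm 1/sqrt(M).
    """
    n = np.arange(m)
    cols = [np.full(m, 1.0 / np.sqrt(m))]
    for k in range(1, (m - 1) // 2 + 1):
        cols.append(np.sqrt(2.0 / m) * np.cos(2 * np.pi * k * n / m))
        cols.append(np.sqrt(2.0 / m) * np.sin(2 * np.pi * k * n / m))
    if m % 2 == 0 and m > 1:
        cols.append((1.0 / np.sqrt(m)) * np.cos(np.pi * n))
    return np.column_stack(cols)


def _expand(values: np.ndarray, transform: str) -> np.ndarray:
    """Full M-coefficient expansion of each row of ``values``."""
    if transform == "dct":
        return scipy.fft.dct(values, type=2, norm="ortho", axis=1)
    if transform == "dft":
        return values @ _dft_basis(values.shape[1])
    raise ValueError(f"unknown cepstral transform {transform!r}")


def _inverse(full: np.ndarray, transform: str) -> np.ndarray:
    if transform == "dct":
        return scipy.fft.idct(full, type=2, norm="ortho", axis=1)
    return full @ _dft_basis(full.shape[1]).T


def cepstrum(fbe: FBEMatrix, transform: str = "dct", c: int = 13) -> CepstraMatrix:
    """First C cepstral coefficients of each frame's log-FBE.

    Requires log-scaled energies and 1 <= C <= M. For C <= M-1 the retained
    quefrency indices are 1..C; C = M keeps the full set 0..M-1 (including
    the mean term) so that the expansion is complete.
    """
    if fbe.scale != "log":
        raise ValueError("cepstrum requires log-scaled filter-bank energies")
    m = fbe.m
    if not (1 <= c <= m):
        raise ValueError(f"require 1 <= C <= M, got C={c}, M={m}")
    full = _expand(fbe.energies, transform)
    if c == m:
        indices = np.arange(m)
        coeffs = full
    else:
        indices = np.arange(1, c + 1)
        coeffs = full[:, 1:c + 1]
    return CepstraMatrix(coeffs=coeffs.copy(), indices=indices,
                         c0=full[:, 0].copy(), transform=transform, m=m,
                         spec=fbe.spec)


def lifter_factors(indices: np.ndarray, lifter_l: float) -> np.ndarray:
    """Sine-lifter gains 1 + (L/2) sin(pi * i / L) per quefrency index i."""
    if lifter_l < 0:
        raise ValueError("lifter parameter L must be non-negative")
    if lifter_l == 0:
        return np.ones(indices.size)
    return 1.0 + (lifter_l / 2.0) * np.sin(np.pi * indices / lifter_l)


def lifter(cepstra: CepstraMatrix, lifter_l: float | None) -> CepstraMatrix:
    """Rescale coefficient i by 1 + (L/2) sin(pi*i/L); ``None`` disables."""
    if lifter_l is None:
        return cepstra
    factors = lifter_factors(cepstra.indices, lifter_l)
    return CepstraMatrix(coeffs=cepstra.coeffs * factors,
                         indices=cepstra.indices, c0=cepstra.c0,
                         transform=cepstra.transform, m=cepstra.m,
                         liftered=True, lifter_l=lifter_l, spec=cepstra.spec)


def unlifter(cepstra: CepstraMatrix) -> CepstraMatrix:
    """Invert the sine lifter (exact, since every gain is nonzero)."""
    if not cepstra.liftered:
        return cepstra
    factors = lifter_factors(cepstra.indices, cepstra.lifter_l)
    return CepstraMatrix(coeffs=cepstra.coeffs / factors,
                         indices=cepstra.indices, c0=cepstra.c0,
                         transform=cepstra.transform, m=cepstra.m,
                         liftered=False, lifter_l=None, spec=cepstra.spec)


def reconstruct_fbe(cepstra: CepstraMatrix) -> FBEMatrix:
    """Approximate log-FBE from a truncated cepstrum.

    The truncated inverse expansion: exact at C = M, and with squared error
    weakly decreasing in C (orthonormal basis). Liftered input is rejected —
    invert the lifter first.
    """
    if cepstra.liftered:
        raise ValueError("unlifter the cepstra before reconstruction")
    full = np.zeros((cepstra.n_frames, cepstra.m))
    full[:, cepstra.indices] = cepstra.coeffs
    if 0 not in cepstra.indices:
        full[:, 0] = cepstra.c0
    energies = _inverse(full, cepstra.transform)
    return FBEMatrix(energies=energies, scale="log", spec=cepstra.spec)
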