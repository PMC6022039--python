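"""Feature extraction: AudioSignal -> per-frame feature table.

`SpectrumFeatureExtractor` is a stateless scikit-learn transformer mapping a
list of recordings to a tidy frame-level table (one row per frame, columns =
metadata + named features), driven entirely by an OptionSet.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .audio import AudioSignal
from .cepstrum import cepstrum, lifter
from .filterbank import (apply_filterbank, design_filterbank, log_scale,
                         next_pow2, power_spectrum)
from .frontend import FramingOptions, frame_signal, pre_emphasize, samples_per_window
from .mpeg7 import MPEG7_FEATURE_NAMES, mpeg7_frame_features
from .options import OptionSet

#: metadata columns preceding the feature columns in every feature table
META_COLUMNS = ("recording_id", "frame_index", "start_time_s", "label")


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the feature columns of a frame-level feature table."""
    return [c for c in table.columns if c not in META_COLUMNS]


def extract_features(signal: AudioSignal, options: OptionSet
                     ) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Per-frame features of one recording.

    Returns ``(matrix, names, start_times)`` where matrix is F x D.
    """
    if options.alpha is not None:
        signal = pre_emphasize(signal, options.alpha)
    framing = FramingOptions(window=options.window, tw_ms=options.tw_ms,
                             ts_ms=options.ts_ms)
    frames = frame_signal(signal, framing)

    if options.representation == "mpeg7":
        mat = mpeg7_frame_features(frames.frames, signal.rate,
                                   band=(options.lf_hz, options.hf_hz))
        return mat, list(MPEG7_FEATURE_NAMES), frames.start_times

    nfft = next_pow2(frames.frame_length)
    ps = power_spectrum(frames, nfft)
    kind = "mel" if options.scaling == "mel" else "rectangular"
    bank = design_filterbank(kind, options.m, options.lf_hz,
                             min(options.hf_hz, signal.rate / 2),
                             signal.rate, nfft)
    fbe = apply_filterbank(ps, bank)

    if options.representation == "fbe":
        if options.energy_scale == "log":
            fbe = log_scale(fbe)
            names = [f"logfbe_{j}" for j in range(1, options.m + 1)]
        else:
            names = [f"fbe_{j}" for j in range(1, options.m + 1)]
        return fbe.energies, names, frames.start_times

    # mfcc: cepstrum of the log energies, optional liftering
    cep = cepstrum(log_scale(fbe), transform=options.transform, c=options.c)
    cep = lifter(cep, options.lifter_l)
    names = [f"c{int(i)}" for i in cep.indices]
    return cep.coeffs, names, frames.start_times


class SpectrumFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer from recordings to a frame-level feature table.

    Parameters
    ----------
    options : OptionSet
        The full set of extraction options (representation, pre-emphasis,
        framing, filter bank, cepstrum, lifter).

    The transformer is stateless: ``fit`` only validates the options.
    """

    def __init__(self, options: OptionSet = OptionSet()):
        self.options = options

    def fit(self, X=None, y=None) -> "SpectrumFeatureExtractor":
        if not isinstance(self.options, OptionSet):
            raise TypeError("options must be an OptionSet")
        return self

    def transform(self, X) -> pd.DataFrame:
        """Extract features from a recording or a list of recordings."""
        self.fit()
        if isinstance(X, AudioSignal):
            X = [X]
        parts = []
        for rec in X:
            mat, names, starts = extract_features(rec, self.options)
            part = pd.DataFrame(mat, columns=names)
            part.insert(0, "recording_id", rec.id)
            part.insert(1, "frame_index", np.arange(mat.shape[0]))
            part.insert(2, "start_time_s", starts)
            part.insert(3, "label", rec.label)
            parts.append(part)
        if not parts:
            raise ValueError("no recordings to transform")
        return pd.concat(parts, ignore_index=True)


def extract_table(recordings, options: OptionSet) -> pd.DataFrame:
    """Functional wrapper over SpectrumFeatureExtractor."""
    return SpectrumFeatureExtractor(options).transform(recordings)
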