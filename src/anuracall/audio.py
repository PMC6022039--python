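"""Core audio container shared by every stage of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class AudioSignal:
    """A mono sound recording: the discrete time-domain signal s(n).

    Parameters
    ----------
    samples : ndarray of float
        Amplitude sequence, dimensionless, nominally within [-1, 1].
    rate : float
        Sampling rate in Hz.
    label : str or None
        Call-class label, if the recording is labelled.
    id : str or None
        Recording identifier.
    """

    samples: np.ndarray
    rate: float
    label: str | None = None
    id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioSignal requires a 1-D (mono) sample array")
        if self.samples.size < 1:
            raise ValueError("AudioSignal requires at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("AudioSignal samples must all be finite")
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.samples.size / self.rate

    @property
    def power(self) -> float:
        """Mean-square amplitude of the signal."""
        return float(np.mean(self.samples**2))

    def replace(self, **changes) -> "AudioSignal":
        fields = {"samples": self.samples, "rate": self.rate,
                  "label": self.label, "id": self.id}
        fields.update(changes)
        return AudioSignal(**fields)
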