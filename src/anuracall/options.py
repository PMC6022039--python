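"""The 11 extraction options and the four preset configurations.

An OptionSet fixes every choice of the spectrum-representation chain:
pre-emphasis coefficient, window kind, frame duration Tw and shift Ts,
frequency limits Lf/Hf, filter count M, frequency-axis scaling (linear or
mel), cepstral transform (DCT/DFT or none), coefficient count C, and lifter
parameter L — plus which representation the chain emits (MPEG-7 descriptor
set, filter-bank energies, or cepstral coefficients).
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

REPRESENTATIONS = ("mpeg7", "fbe", "mfcc")

#: scan order of the coordinate search (the option-table row order)
OPTION_ORDER = ("alpha", "window", "tw_ms", "ts_ms", "lf_hz", "hf_hz",
                "m", "scaling", "transform", "c", "lifter_l")


@dataclass(frozen=True)
class OptionSet:
    """One point of the 11-dimensional extraction-option space."""

    representation: str = "mfcc"
    alpha: float | None = 0.97       # pre-emphasis; None disables
    window: str = "hamming"          # "hamming" | "rectangular"
    tw_ms: float = 25.0
    ts_ms: float = 10.0
    lf_hz: float = 300.0
    hf_hz: float = 3700.0
    m: int | None = 20               # filter count
    scaling: str = "mel"             # frequency axis: "linear" | "mel"
    transform: str | None = "dct"    # "dct" | "dft" | None
    c: int | None = 13               # cepstral coefficient count
    lifter_l: float | None = 22.0    # sine lifter parameter; None disables
    energy_scale: str = "log"        # FBE energy scale: "linear" | "log"

    def __post_init__(self) -> None:
        if self.representation not in REPRESENTATIONS:
            raise ValueError(f"unknown representation {self.representation!r}")
        if not (0 < self.ts_ms <= self.tw_ms):
            raise ValueError("require 0 < Ts <= Tw")
        if not (0 <= self.lf_hz < self.hf_hz):
            raise ValueError("require 0 <= Lf < Hf")
        if self.alpha is not None and not (0 <= self.alpha < 1):
            raise ValueError("alpha must be None or in [0, 1)")
        if self.scaling not in ("linear", "mel"):
            raise ValueError("scaling must be 'linear' or 'mel'")
        if self.energy_scale not in ("linear", "log"):
            raise ValueError("energy_scale must be 'linear' or 'log'")
        if self.representation == "mfcc":
            if self.m is None or self.c is None or self.transform is None:
                raise ValueError("mfcc requires M, C and a cepstral transform")
            if self.c > self.m:
                raise ValueError(f"require C <= M, got C={self.c}, M={self.m}")
        if self.representation == "fbe" and self.m is None:
            raise ValueError("fbe requires a filter count M")

    def replace(self, **changes) -> "OptionSet":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def n_features(self) -> int:
        if self.representation == "mpeg7":
            return 18
        if self.representation == "fbe":
            return int(self.m)
        return int(self.c)


# The four preset option columns: the MPEG-7 and FBE baselines share the
# wide analysis band (64 Hz - 16 kHz, Tw 30 ms); MFCC-HTK is the HTK default
# front end; MFCC-opt is the coordinate-search optimum (no pre-emphasis,
# Tw 20 ms, band 1000-5000 Hz, C = M = 20, no lifter).
PRESETS: dict[str, OptionSet] = {
    "mpeg7": OptionSet(representation="mpeg7", alpha=None, window="hamming",
                       tw_ms=30.0, ts_ms=10.0, lf_hz=64.0, hf_hz=16000.0,
                       m=None, scaling="linear", transform=None, c=None,
                       lifter_l=None, energy_scale="linear"),
    "fbe": OptionSet(representation="fbe", alpha=None, window="hamming",
                     tw_ms=30.0, ts_ms=10.0, lf_hz=64.0, hf_hz=16000.0,
                     m=18, scaling="linear", transform=None, c=None,
                     lifter_l=None, energy_scale="linear"),
    "mfcc_htk": OptionSet(representation="mfcc", alpha=0.97, window="hamming",
                          tw_ms=25.0, ts_ms=10.0, lf_hz=300.0, hf_hz=3700.0,
                          m=20, scaling="mel", transform="dct", c=13,
                          lifter_l=22.0),
    "mfcc_opt": OptionSet(representation="mfcc", alpha=None, window="hamming",
                          tw_ms=20.0, ts_ms=10.0, lf_hz=1000.0, hf_hz=5000.0,
                          m=20, scaling="mel", transform="dct", c=20,
                          lifter_l=None),
}


def preset(name: str) -> OptionSet:
    """Look up one of the preset option columns by name."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
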