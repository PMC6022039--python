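"""File formats and run configuration: WAV, CSV feature tables, manifests,
JSON models, and the config hash that ties a pipeline run together."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io.wavfile

from .audio import AudioSignal
from .features import META_COLUMNS
from .options import OptionSet
from .synth import CorpusManifest


def read_wav(path) -> AudioSignal:
    """Read a mono PCM WAV file, normalizing samples to [-1, 1].

    Multi-channel files are rejected. 16/24/32-bit integer and float
    encodings are supported.
    """
    rate, data = scipy.io.wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: only mono WAV files are supported "
                         f"(got {data.shape[1]} channels)")
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV encoding {data.dtype}")
    return AudioSignal(samples, float(rate), id=Path(path).stem)


def write_wav(path, signal: AudioSignal) -> None:
    """Write a signal as mono 16-bit PCM WAV (samples clipped to [-1, 1])."""
    clipped = np.clip(signal.samples, -1.0, 1.0)
    data = np.round(clipped * 32767.0).astype(np.int16)
    scipy.io.wavfile.write(path, int(signal.rate), data)


def write_features(table: pd.DataFrame, path, config_hash: str | None = None
                   ) -> None:
    """Write a frame-level feature table as CSV (lossless float round trip);
    a JSON sidecar carries the config hash."""
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks metadata columns {missing}")
    table.to_csv(path, index=False, float_format="%.17g")
    if config_hash is not None:
        sidecar = Path(str(path) + ".meta.json")
        sidecar.write_text(json.dumps({"config_hash": config_hash}))


def read_features(path, expected_hash: str | None = None) -> pd.DataFrame:
    """Read a feature-table CSV, optionally verifying its config hash."""
    table = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: header lacks metadata columns {missing}")
    if expected_hash is not None:
        sidecar = Path(str(path) + ".meta.json")
        if not sidecar.exists():
            raise ValueError(f"{path}: no config-hash sidecar to verify")
        stored = json.loads(sidecar.read_text())["config_hash"]
        if stored != expected_hash:
            raise ValueError(
                f"{path}: config hash mismatch ({stored} != {expected_hash})")
    return table


def write_manifest(manifest: CorpusManifest, csv_path) -> None:
    """Manifest rows as CSV plus a JSON sidecar with seed and parameters."""
    manifest.table.to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = Path(str(csv_path) + ".meta.json")
    sidecar.write_text(json.dumps(
        {"seed": manifest.seed, "params": manifest.params}, indent=2))


def read_manifest(csv_path) -> CorpusManifest:
    table = pd.read_csv(csv_path)
    sidecar = Path(str(csv_path) + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return CorpusManifest(table=table, seed=meta.get("seed", -1),
                          params=meta.get("params", {}))


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    options: OptionSet
    seed: int
    classifiers: tuple[str, ...] = ()
    corpus_params: dict = field(default_factory=dict)
    output_dir: str = "."

    def to_dict(self) -> dict:
        return {"options": self.options.to_dict(), "seed": self.seed,
                "classifiers": list(self.classifiers),
                "corpus_params": self.corpus_params,
                "output_dir": self.output_dir}

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def save_model_json(model, path) -> None:
    """Serialize a from-scratch model (MinDis, MaxLik, HMM) as JSON."""
    from .classifiers import (DiscreteHmmClassifier, GaussianMaximumLikelihood,
                              MinimumDistanceClassifier)
    if isinstance(model, MinimumDistanceClassifier):
        payload = {"kind": "MinDis",
                   "classes": model.classes_.tolist(),
                   "means": model.means_.tolist()}
    elif isinstance(model, GaussianMaximumLikelihood):
        payload = {"kind": "MaxLik",
                   "classes": model.classes_.tolist(),
                   "means": model.means_.tolist(),
                   "covariances": model.covariances_.tolist(),
                   "priors": model.priors_.tolist()}
    elif isinstance(model, DiscreteHmmClassifier):
        payload = {"kind": "HMM",
                   "classes": model.classes_.tolist(),
                   "codebook": model.codebook_.tolist(),
                   "scaler_mean": model.scaler_.mean_.tolist(),
                   "scaler_scale": model.scaler_.scale_.tolist(),
                   "models": {str(c): [m.tolist() for m in model.models_[c]]
                              for c in model.classes_}}
    else:
        raise ValueError(f"JSON serialization unsupported for {type(model)}")
    Path(path).write_text(json.dumps(payload))


def load_model_json(path):
    from sklearn.preprocessing import StandardScaler

    from .classifiers import (DiscreteHmmClassifier, GaussianMaximumLikelihood,
                              MinimumDistanceClassifier)
    payload = json.loads(Path(path).read_text())
    kind = payload["kind"]
    if kind == "MinDis":
        model = MinimumDistanceClassifier()
        model.classes_ = np.asarray(payload["classes"])
        model.means_ = np.asarray(payload["means"])
        return model
    if kind == "MaxLik":
        model = GaussianMaximumLikelihood()
        model.classes_ = np.asarray(payload["classes"])
        model.means_ = np.asarray(payload["means"])
        model.covariances_ = np.asarray(payload["covariances"])
        model.priors_ = np.asarray(payload["priors"])
        return model
    if kind == "HMM":
        model = DiscreteHmmClassifier()
        model.classes_ = np.asarray(payload["classes"])
        model.codebook_ = np.asarray(payload["codebook"])
        scaler = StandardScaler()
        scaler.mean_ = np.asarray(payload["scaler_mean"])
        scaler.scale_ = np.asarray(payload["scaler_scale"])
        model.scaler_ = scaler
        model.models_ = {c: tuple(np.asarray(m)
                                  for m in payload["models"][str(c)])
                         for c in model.classes_}
        return model
    raise ValueError(f"unknown model kind {kind!r}")
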