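"""End-to-end experiment runner: corpus -> features -> classifiers -> metrics.

Training uses the pattern (low-noise) recordings only; hyper-option choices
are scored on the validation split and final performance on the test split.
Frame-wise classifiers are aggregated to recording labels by majority vote;
the HMM consumes each recording's frame sequence directly. Headline metrics
are recording-level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .audio import AudioSignal
from .classifiers import (CLASSIFIER_ORDER, DiscreteHmmClassifier,
                          label_recording, make_classifier)
from .features import extract_table, feature_columns
from .metrics import MetricsReport, best_classifier, metrics_from_labels
from .options import OptionSet
from .synth import CorpusManifest

DEFAULT_CLASSIFIERS = CLASSIFIER_ORDER


def split_ids(manifest: CorpusManifest, split: str) -> list[str]:
    t = manifest.table
    return t.loc[t["split"] == split, "id"].tolist()


def run_experiment(recordings: list[AudioSignal], manifest: CorpusManifest,
                   options: OptionSet,
                   classifier_kinds=DEFAULT_CLASSIFIERS,
                   seed: int = 0, eval_split: str = "test",
                   features: pd.DataFrame | None = None,
                   ) -> dict[str, MetricsReport]:
    """Train every requested classifier on the pattern frames and report
    recording-level metrics on ``eval_split``.

    ``features`` may carry a precomputed frame table for these options to
    avoid re-extraction.
    """
    if features is None:
        features = extract_table(recordings, options)
    cols = feature_columns(features)
    table = manifest.table.set_index("id")
    classes = sorted(table["class"].unique().tolist())

    pattern_ids = set(split_ids(manifest, "pattern"))
    eval_ids = split_ids(manifest, eval_split)
    if not eval_ids:
        raise ValueError(f"no recordings in split {eval_split!r}")

    is_pattern = features["recording_id"].isin(pattern_ids)
    x_train = features.loc[is_pattern, cols].to_numpy()
    y_train = features.loc[is_pattern, "label"].to_numpy()
    eval_frames = features[features["recording_id"].isin(eval_ids)]
    y_true = [table.loc[rid, "class"] for rid in eval_ids]

    # per-recording frame blocks, in eval_ids order
    grouped = {rid: grp for rid, grp in eval_frames.groupby("recording_id")}
    blocks = [grouped[rid][cols].to_numpy() for rid in eval_ids]

    reports: dict[str, MetricsReport] = {}
    for kind in classifier_kinds:
        clf = make_classifier(kind, seed=seed)
        if isinstance(clf, DiscreteHmmClassifier):
            train_seqs, train_labels = [], []
            for rid, grp in features[is_pattern].groupby("recording_id"):
                train_seqs.append(grp[cols].to_numpy())
                train_labels.append(table.loc[rid, "class"])
            clf.fit(train_seqs, train_labels)
            y_pred = clf.predict(blocks)
        else:
            clf.fit(x_train, y_train)
            y_pred = [label_recording(clf.predict(block)) for block in blocks]
        reports[kind] = metrics_from_labels(y_true, y_pred, classes)
    return reports


def evaluate_options(recordings, manifest, options: OptionSet,
                     classifier_kinds=DEFAULT_CLASSIFIERS, seed: int = 0,
                     eval_split: str = "validation",
                     criterion: str = "GM") -> dict:
    """Score one option point: best classifier by the criterion and its
    macro metrics (the coordinate-search objective)."""
    reports = run_experiment(recordings, manifest, options, classifier_kinds,
                             seed=seed, eval_split=eval_split)
    best = best_classifier(reports, criterion)
    return {"best_classifier": best, "macro": reports[best].macro,
            "reports": reports}


def corpus_objective(recordings, manifest, classifier_kinds=DEFAULT_CLASSIFIERS,
                     seed: int = 0, eval_split: str = "validation",
                     criterion: str = "GM"):
    """Bind a corpus and classifier set into an OptionSet -> record callable."""
    def objective(options: OptionSet) -> dict:
        return evaluate_options(recordings, manifest, options,
                                classifier_kinds, seed=seed,
                                eval_split=eval_split, criterion=criterion)
    return objective
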