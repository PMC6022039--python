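"""Option-space exploration: one-dimension-at-a-time coordinate search,
the eight-stage representation ladder, and the cepstral-count sweep.

An exhaustive scan of the 11-dimensional option space with O_i values per
option would cost O_1*O_2*...*O_11 pipeline evaluations. Scanning one
option at a time from a starting point, fixing each winner before moving
on, costs only

    1 + (O_1 - 1) + ... + (O_k - 1)  =  O_1 + ... + O_k - (k - 1)

evaluations (100 for 11 options with 10 values each). The search is greedy
and order-dependent; the scan order is the option-table row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import METRIC_NAMES
from .options import OPTION_ORDER, OptionSet

logger = logging.getLogger(__name__)

#: a candidate must beat the incumbent by more than this (as a fraction,
#: 0.001 = 0.1 percentage point) to displace it on an almost-flat scan
DEFAULT_FLAT_MARGIN = 0.001


def expected_evaluations(grid_sizes) -> int:
    """Closed-form evaluation budget: sum(O_i) - (k - 1)."""
    sizes = list(grid_sizes)
    return sum(sizes) - (len(sizes) - 1)


@dataclass
class SearchTrace:
    """Ordered record of every option-space evaluation."""

    evaluations: list[dict] = field(default_factory=list)
    start: OptionSet | None = None
    final: OptionSet | None = None

    @property
    def n_evaluations(self) -> int:
        return len(self.evaluations)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ev in self.evaluations:
            row = {"step": ev["step"], "option": ev["option"],
                   "value": ev["value"], "adopted": ev["adopted"],
                   "best_classifier": ev["best_classifier"]}
            row.update({m: ev["macro"].get(m, np.nan) for m in METRIC_NAMES})
            rows.append(row)
        return pd.DataFrame(rows)


def coordinate_search(start: OptionSet, grids: dict[str, list], objective,
                      order=OPTION_ORDER, criterion: str = "GM",
                      flat_margin: float = DEFAULT_FLAT_MARGIN) -> SearchTrace:
    """Greedy one-option-at-a-time search from ``start``.

    ``grids`` maps option names to candidate value lists; each grid must
    contain the incumbent value (otherwise the evaluation budget formula
    breaks). ``objective`` maps an OptionSet to a record with keys
    ``best_classifier`` and ``macro`` (metric dict). After scanning one
    option, its best value is fixed before the next option is scanned; on an
    almost-flat scan the incumbent is kept unless a candidate wins by more
    than ``flat_margin``.
    """
    order = [o for o in order if o in grids]
    extra = set(grids) - set(order)
    if extra:
        raise ValueError(f"grids for unknown options: {sorted(extra)}")

    trace = SearchTrace(start=start)
    step = 0

    def evaluate(opts: OptionSet, option_name: str, value, adopted=False):
        nonlocal step
        rec = objective(opts)
        step += 1
        trace.evaluations.append({
            "step": step, "option": option_name, "value": value,
            "options": opts, "best_classifier": rec["best_classifier"],
            "macro": dict(rec["macro"]), "adopted": adopted})
        return rec["macro"][criterion]

    current = start
    incumbent_score = evaluate(current, "start", None, adopted=True)

    for name in order:
        grid = list(grids[name])
        inc_value = getattr(current, name)
        if not any(_option_eq(v, inc_value) for v in grid):
            raise ValueError(
                f"grid for {name!r} omits the incumbent value {inc_value!r}")
        best_value, best_score = inc_value, incumbent_score
        for value in grid:
            if _option_eq(value, inc_value):
                continue
            try:
                candidate = current.replace(**{name: value})
            except ValueError:
                # infeasible combination (e.g. C > M mid-scan): counted
                # against the budget but scored as a failure
                step += 1
                trace.evaluations.append({
                    "step": step, "option": name, "value": value,
                    "options": None, "best_classifier": None,
                    "macro": {m: np.nan for m in METRIC_NAMES},
                    "adopted": False})
                continue
            score = evaluate(candidate, name, value)
            if score > best_score + (flat_margin if not np.isnan(best_score) else 0):
                best_value, best_score = value, score
        if not _option_eq(best_value, inc_value):
            current = current.replace(**{name: best_value})
            incumbent_score = best_score
            logger.info("option %s set to %r (%s=%.4f)", name, best_value,
                        criterion, best_score)
        for ev in trace.evaluations:
            if ev["option"] == name and _option_eq(ev["value"], best_value):
                ev["adopted"] = True
    trace.final = current
    return trace


def _option_eq(a, b) -> bool:
    if a is None or b is None:
        return a is b
    if isinstance(a, str) or isinstance(b, str):
        return a == b
    return np.isclose(a, b)


def default_grids(start: OptionSet) -> dict[str, list]:
    """Scan ranges mirroring the documented per-option studies."""
    m = start.m or 20
    grids = {
        "alpha": [None, 0.5, 0.9, 0.95, 0.97, 0.99],
        "window": ["rectangular", "hamming"],
        "tw_ms": [10.0, 15.0, 20.0, 25.0, 30.0, 40.0, 50.0],
        "ts_ms": [5.0, 10.0, 15.0, 20.0, 25.0],
        "lf_hz": [0.0, 150.0, 300.0, 500.0, 1000.0, 1500.0, 2000.0],
        "hf_hz": [3000.0, 3700.0, 5000.0, 8000.0, 12000.0, 16000.0],
        "m": [10, 15, 20, 25, 30, 40],
        "scaling": ["linear", "mel"],
        "transform": ["dft", "dct"],
        "c": sorted({2, 5, 8, 10, 13, 16, m} | {start.c or 13}),
        "lifter_l": [None, 10.0, 22.0, 30.0, 40.0],
    }
    for name in list(grids):
        inc = getattr(start, name)
        if not any(_option_eq(v, inc) for v in grids[name]):
            grids[name] = [inc] + grids[name]
    return grids


# ---------------------------------------------------------------------------
# the eight-stage representation ladder

def ladder_stage_options(n_features: int = 18) -> list[tuple[str, OptionSet]]:
    """The eight staged configurations from the descriptor baseline to the
    fully optimized cepstral front end, all with ``n_features`` features.

    1. MPEG-7 descriptors; 2. linear-frequency linear-energy FBE;
    3. + log energies; 4. + mel frequency axis; 5. stage 4 with optimized
    Tw/Lf/Hf; 6. DCT of stage 4 (cepstrum, C = M); 7. stage 6 with optimal
    Tw; 8. stage 7 with optimal Lf/Hf.
    """
    base_fbe = OptionSet(representation="fbe", alpha=None, window="hamming",
                         tw_ms=30.0, ts_ms=10.0, lf_hz=64.0, hf_hz=16000.0,
                         m=n_features, scaling="linear", transform=None,
                         c=None, lifter_l=None, energy_scale="linear")
    mel_log = base_fbe.replace(scaling="mel", energy_scale="log")
    mel_log_dct = mel_log.replace(representation="mfcc", transform="dct",
                                  c=n_features)
    stages = [
        ("MPEG-7", OptionSet(representation="mpeg7", alpha=None,
                             window="hamming", tw_ms=30.0, ts_ms=10.0,
                             lf_hz=64.0, hf_hz=16000.0, m=None,
                             scaling="linear", transform=None, c=None,
                             lifter_l=None, energy_scale="linear")),
        ("FBE", base_fbe),
        ("LogFBE", base_fbe.replace(energy_scale="log")),
        ("MelLogFBE", mel_log),
        ("MelLogFBE-opt", mel_log.replace(tw_ms=20.0, lf_hz=1000.0,
                                          hf_hz=5000.0)),
        ("MelLogDCT", mel_log_dct),
        ("MFCC-optTw", mel_log_dct.replace(tw_ms=20.0)),
        ("MFCC-opt", mel_log_dct.replace(tw_ms=20.0, lf_hz=1000.0,
                                         hf_hz=5000.0)),
    ]
    return stages


def stage_ladder(recordings, manifest, classifier_kinds=None, seed: int = 0,
                 n_features: int = 18, eval_split: str = "test",
                 criterion: str = "GM") -> pd.DataFrame:
    """Evaluate the eight ladder stages; one row per stage with the
    GM-selected best classifier and its macro metrics."""
    from .pipeline import DEFAULT_CLASSIFIERS, evaluate_options
    if classifier_kinds is None:
        classifier_kinds = DEFAULT_CLASSIFIERS
    rows = []
    for name, opts in ladder_stage_options(n_features):
        rec = evaluate_options(recordings, manifest, opts, classifier_kinds,
                               seed=seed, eval_split=eval_split,
                               criterion=criterion)
        row = {"stage": name, "best_classifier": rec["best_classifier"]}
        row.update(rec["macro"])
        rows.append(row)
    return pd.DataFrame(rows)


def feature_count_sweep(options: OptionSet, c_values, recordings, manifest,
                        classifier_kinds=None, seed: int = 0,
                        eval_split: str = "test",
                        criterion: str = "GM") -> pd.DataFrame:
    """Best-classifier metrics as a function of the cepstral count C."""
    from .pipeline import DEFAULT_CLASSIFIERS, evaluate_options
    if options.transform is None:
        raise ValueError("feature-count sweep requires a cepstral transform")
    if classifier_kinds is None:
        classifier_kinds = DEFAULT_CLASSIFIERS
    rows = []
    for c in c_values:
        if c > options.m:
            logger.warning("skipping C=%d > M=%d", c, options.m)
            continue
        rec = evaluate_options(recordings, manifest, options.replace(c=int(c)),
                               classifier_kinds, seed=seed,
                               eval_split=eval_split, criterion=criterion)
        row = {"C": int(c), "best_classifier": rec["best_classifier"]}
        row.update(rec["macro"])
        rows.append(row)
    return pd.DataFrame(rows)
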