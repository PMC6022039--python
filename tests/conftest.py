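"""Shared fixtures: small, fast synthetic corpora for pipeline-level tests."""

import dataclasses

import pytest

from anuracall.synth import DEFAULT_CLASS_SPECS, make_corpus

#: short-call variants of the shipped class specs, for fast pipeline tests
SMALL_SPECS = tuple(
    dataclasses.replace(s, duration_mean=1.0, duration_sd=0.2)
    for s in DEFAULT_CLASS_SPECS)


@pytest.fixture(scope="session")
def small_corpus():
    """16 one-second recordings, 4 balanced classes, default SNR profile."""
    return make_corpus(SMALL_SPECS, (0.25, 0.25, 0.25, 0.25),
                       n_recordings=16, seed=3)
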