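"""Shared fixtures.

The expensive session fixtures build feature matrices through the full
synthesis → preprocessing → coherence → assembly path once and share them
across tests:

* ``default_bundle`` — the default study design (24 + 20 participants × 2
  conditions, full 62-bin grid).
* ``separated_bundle`` — a strongly separated design: one high-snr
  amplitude cell per group whose entrainment collapses in the reversed
  condition, so condition classification is nearly noise-free and the
  target cell carries almost all label information.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from entrainflow.pipeline import PipelineConfig, _build_matrix

SEPARATED_CELL = ("a", "posterior", 1.0, 200.0, 10.0)


@pytest.fixture(scope="session")
def default_bundle():
    """(matrix, rejections, diagnostics) for the default synthetic cohort."""
    cfg = PipelineConfig(seed=11, diagnostics={"enabled": False})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _build_matrix(cfg)


@pytest.fixture(scope="session")
def default_matrix(default_bundle):
    return default_bundle[0]


@pytest.fixture(scope="session")
def separated_bundle():
    cfg = PipelineConfig(
        seed=13,
        synth={
            "cells": [list(SEPARATED_CELL),
                      ["b", "right", 1.2, 150.0, 10.0]],
            "reversed_snr_factor": {"a": 0.1, "b": 0.1},
        },
        preproc={"enabled": False},
        diagnostics={"enabled": False},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _build_matrix(cfg)


@pytest.fixture(scope="session")
def separated_matrix(separated_bundle):
    return separated_bundle[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
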