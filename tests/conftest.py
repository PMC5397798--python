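"""Shared fixtures: tiny alphabets, handmade alignments, and a small
synthetic suite reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from msacore.alphabet import reduced_alphabet
from msacore.io import Alignment, SSConfidence
from msacore.synthgen import SuiteConfig, generate_suite_in_memory
from msacore import workflows


def one_hot_ss(residues: str, state: str = "H") -> SSConfidence:
    probs = np.zeros((len(residues), 3))
    probs[:, "HEC".index(state)] = 1.0
    return SSConfidence(residues, probs)


@pytest.fixture(scope="session")
def alphabet():
    return reduced_alphabet()


@pytest.fixture
def toy_alignment():
    return Alignment(["a", "b"], ["AC-D", "A-CD"])


@pytest.fixture(scope="session")
def small_suite():
    cfg = SuiteConfig(seed=11, n_benchmarks=6, k=5, m=40)
    return generate_suite_in_memory(cfg)


@pytest.fixture(scope="session")
def small_sets(small_suite, alphabet):
    return workflows.prepare_window_sets(
        small_suite, alphabet, n_train=40, n_sample=50, n_test=200,
        seed=5, n_folds=3,
    )
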