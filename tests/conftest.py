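"""Shared fixtures: small layouts and cached simulated maps.

The Chr1-scale simulation plus SCN normalization is a few seconds, so it is
session-scoped and reused wherever a realistic map is needed.
"""
from __future__ import annotations

import numpy as np
import pytest

import bact3c as b3c


@pytest.fixture(scope="session")
def chr1_truth():
    return b3c.TruthSpec.chr1_like(seed=11)


@pytest.fixture(scope="session")
def chr1_map(chr1_truth):
    cm, _ = b3c.simulate_map(chr1_truth)
    return cm


@pytest.fixture(scope="session")
def chr1_norm(chr1_map):
    return b3c.scn_normalize(chr1_map).matrix


@pytest.fixture(scope="session")
def small_layout():
    return b3c.RepliconLayout.single("rep", 50_000, circular=True)


@pytest.fixture(scope="session")
def small_bins(small_layout):
    return b3c.bin_genome(small_layout, 5_000)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_raw(matrix, bins, valid=None):
    return b3c.ContactMatrix(np.asarray(matrix, dtype=float), bins, state="raw", valid=valid)


def make_norm(matrix, bins, valid=None):
    return b3c.ContactMatrix(np.asarray(matrix, dtype=float), bins, state="normalized",
                             valid=valid)
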