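"""Shared fixtures: one seeded synthetic cohort and one trained map per
session, so the expensive training step runs once."""

from __future__ import annotations

import numpy as np
import pytest

import epicart as ec

SEED = 0


@pytest.fixture(scope="session")
def design():
    return ec.default_design(SEED)


@pytest.fixture(scope="session")
def cohort(design):
    matrix, truth = ec.generate_cohort(design)
    return matrix, truth


@pytest.fixture(scope="session")
def centered(cohort):
    matrix, _ = cohort
    return ec.center_genes(matrix)


@pytest.fixture(scope="session")
def som(centered):
    return ec.train_som(centered, random_state=SEED)


@pytest.fixture(scope="session")
def portraits(som, cohort):
    matrix, _ = cohort
    return [ec.sample_portrait(som, s) for s in matrix.sample_ids]


@pytest.fixture(scope="session")
def detector(portraits, cohort):
    matrix, _ = cohort
    y = [matrix.classes[s] for s in matrix.sample_ids]
    return ec.SpotDetector().fit(portraits, y)


@pytest.fixture(scope="session")
def spot_map(detector):
    return detector.spot_map_


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
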