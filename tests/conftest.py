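"""Shared fixtures and deterministic hypothesis settings."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import wgskit as w

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rubric() -> w.RubricTable:
    return w.load_rubric()


@pytest.fixture(scope="session")
def symmetric_trial() -> dict[str, w.Annotation]:
    """Both views of one noise-free, deficit-free (symmetric) gait trial."""
    return w.simulate_trial(w.GaitProfile(seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230323)


def random_assessment(rng: np.random.Generator, rubric: w.RubricTable) -> w.Assessment:
    codes = {
        it.item_id: it.codes[rng.integers(len(it.codes))] for it in rubric
    }
    return w.Assessment.from_codes(codes)


@pytest.fixture(scope="session")
def make_assessment():
    return random_assessment
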