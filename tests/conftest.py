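"""Shared fixtures: a small simulated cohort and toy genome pieces.

Fixtures are session-scoped where generation is expensive; tests must not
mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from themis.intervals import GenomicInterval
from themis.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale study conditions: 4 x 8-Mb toy genome, 16 healthy +
    4 x 5 cancer samples, 6000 fragments each, late-stage tumor fractions."""
    return SimulationConfig(
        seed=20260901,
        chrom_lengths={f"chr{i}": 8_000_000 for i in range(1, 5)},
        n_healthy=16,
        n_cancer_per_type=5,
        cancer_types=("BRCA", "NSCLC", "COREAD", "LIHC"),
        fragments_per_sample=6000,
        n_clusters=6,
        peaks_per_cluster=12,
    ).with_strong_signal()


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def toy_chrom_sizes() -> dict[str, int]:
    return {"chrA": 10_000_000, "chrB": 10_000_000}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(99)


def make_interval(chrom: str, start: int, end: int) -> GenomicInterval:
    return GenomicInterval(chrom, start, end)
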