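"""Shared fixtures: small seeded datasets reused across the suite."""

import logging

import numpy as np
import pytest

from tiscmr import SimConfig, simulate_dataset

logging.getLogger("tiscmr").setLevel(logging.ERROR)


def tiny_config(**overrides):
    base = dict(
        n_individuals=60, n_snps=300, n_genes=10, n_causal_genes=3,
        n_pleiotropic_snps=10, cells_per_individual_range=(30, 50),
        sampling_mode="uneven", eqtl_effect_mode="time_varying", rng_seed=9,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def tiny_cfg():
    return tiny_config()


@pytest.fixture(scope="session")
def tiny_data(tiny_cfg):
    """60 individuals x 10 genes x 300 SNPs, uneven sampling."""
    return simulate_dataset(tiny_cfg)


@pytest.fixture(scope="session")
def kl_data():
    """Sparse series from a known 2-component Karhunen-Loeve expansion.

    300 individuals, 3-6 observations each on [0, 10]; component variances
    9 and 1; measurement noise sd 0.5.  Returns (series, xi1, xi2, T).
    """
    from tiscmr.pace import IndividualSeries

    rng = np.random.default_rng(7)
    T = 10.0
    p1 = lambda t: np.sqrt(2 / T) * np.sin(2 * np.pi * t / T)  # noqa: E731
    p2 = lambda t: np.sqrt(2 / T) * np.cos(2 * np.pi * t / T)  # noqa: E731
    n = 300
    xi1 = rng.normal(0, 3.0, n)
    xi2 = rng.normal(0, 1.0, n)
    series = []
    for i in range(n):
        m = int(rng.integers(3, 7))
        t = np.sort(rng.uniform(0, T, m))
        x = 2.0 + 0.1 * t + xi1[i] * p1(t) + xi2[i] * p2(t) + rng.normal(0, 0.5, m)
        series.append(IndividualSeries(f"I{i}", t, x))
    return series, xi1, xi2, T
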