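"""Shared fixtures: small synthetic studies reused across test modules."""

import numpy as np
import pytest

from neuroads import (
    PreprocessConfig,
    SimulationConfig,
    build_feature_matrix,
    clean_epochs,
    generate_dataset,
)
from neuroads.synthgen import DEFAULT_ADS
from neuroads.types import AdSpec


def short_ad_table(duration_s: float = 8.0) -> tuple[AdSpec, ...]:
    """The default 8-ad topic/style grid with uniform short durations."""
    return tuple(AdSpec(a.ad_id, a.topic, a.style, duration_s) for a in DEFAULT_ADS)


@pytest.fixture(scope="session")
def short_ads():
    return short_ad_table()


@pytest.fixture(scope="session")
def small_dataset(short_ads):
    """4 subjects x 8 short ads, artifacts on, ground truth kept."""
    cfg = SimulationConfig(n_subjects=4, ads=short_ads, seed=42, keep_clean=True)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_clean_epochs(small_dataset):
    """Cleaned epochs of the small study (ICA skipped for speed)."""
    pc = PreprocessConfig(ica_enabled=False)
    out = []
    for rec in small_dataset.recordings:
        out.extend(clean_epochs(rec, small_dataset.config.ads, small_dataset.ratings, pc))
    return out


@pytest.fixture(scope="session")
def small_features(small_clean_epochs):
    return build_feature_matrix(small_clean_epochs)


def bh_stepup_oracle(pvals: np.ndarray, q: float) -> np.ndarray:
    """Brute-force Benjamini-Hochberg step-up by direct threshold enumeration.

    Finds the largest k with p_(k) <= k q / m and flags every p at or below
    that order statistic.
    """
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_max = k
    flags = np.zeros(m, dtype=bool)
    if k_max:
        flags[order[:k_max]] = True
    return flags
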