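"""Shared fixtures: small cohorts, epoch sets and toy matrices."""

from __future__ import annotations

import numpy as np
import pytest

from slgraph import CohortSpec, EpochSet, generate_cohort
from slgraph.preprocess import PreprocessConfig

# Problem sizes used throughout the suite: short recordings at the analysis
# rate so the heavy simulations stay fast while every stage is exercised.
FAST_FS = 250.0
FAST_DURATION = 12.0  # 6 epochs of 2 s; 4 are kept after rejection
FAST_KEEP = 4


def fast_spec(**overrides) -> CohortSpec:
    base = dict(n_patients=5, n_controls=5, fs=FAST_FS, duration=FAST_DURATION,
                artifact_rate=0.0, seed=0)
    base.update(overrides)
    return CohortSpec(**base)


def fast_preprocess(**overrides) -> PreprocessConfig:
    base = dict(n_keep=FAST_KEEP)
    base.update(overrides)
    return PreprocessConfig(**base)


def make_epochset(data: np.ndarray, fs: float = FAST_FS,
                  labels: tuple[str, ...] | None = None,
                  band: str | None = None) -> EpochSet:
    """Wrap an (epochs, channels, samples) array as a clean EpochSet."""
    data = np.asarray(data, dtype=float)
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(data.shape[1]))
    return EpochSet(data=data, fs=fs, channel_labels=labels,
                    rejected_mask=np.zeros(data.shape[0], dtype=bool), band=band)


@pytest.fixture(scope="session")
def small_cohort():
    """A 3+3 cohort with the default planted alpha deficit."""
    spec = fast_spec(n_patients=3, n_controls=3, seed=11)
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
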