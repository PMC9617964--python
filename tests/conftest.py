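"""Shared fixtures: cached full-scale Monte-Carlo studies and helpers."""

from __future__ import annotations

import functools

import numpy as np
import pytest

import permnet as pn

MASTER_SEED = 74123  # one fixed seed for every full-scale study in the suite


@functools.lru_cache(maxsize=None)
def _run_study(scenario: str, effect: bool) -> pn.ExperimentResult:
    return pn.run_scenario(pn.make_spec(scenario, effect=effect, master_seed=MASTER_SEED))


@pytest.fixture(scope="session")
def study():
    """Callable fixture: ``study(scenario, effect)`` returns the cached
    full-scale (1000-replicate) experiment result for that condition."""
    return _run_study


def bootstrap_se(values, statistic, n_boot: int = 2000, seed: int = 0) -> float:
    """Bootstrap standard error of ``statistic`` over a replicate sample."""
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    stats = np.apply_along_axis(statistic, 1, values[idx])
    return float(stats.std(ddof=1))


def rate_band(q: float, n: int = 1000) -> float:
    """Three binomial standard errors around a Monte-Carlo rate ``q``."""
    return 3.0 * np.sqrt(q * (1.0 - q) / n)
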