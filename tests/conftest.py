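"""Shared fixtures and helpers for the neosync test suite."""

from __future__ import annotations

import numpy as np
import pytest

from neosync.types import SyntheticConfig


def make_config(modality: str, duration: float, sampling_rate: float,
                seed: int, **params) -> SyntheticConfig:
    return SyntheticConfig(modality=modality, duration=duration,
                           sampling_rate=sampling_rate, seed=seed,
                           modality_params=params)


def match_events(detected: np.ndarray, planted: np.ndarray,
                 tol_s: float) -> tuple[int, int, int]:
    """Greedy one-to-one matching; returns (true positives, misses, extras)."""
    detected = np.sort(np.asarray(detected, dtype=float))
    used = np.zeros(detected.size, dtype=bool)
    tp = 0
    for t in np.sort(np.asarray(planted, dtype=float)):
        if detected.size == 0:
            continue
        free = np.flatnonzero(~used)
        if free.size == 0:
            continue
        j = free[np.argmin(np.abs(detected[free] - t))]
        if abs(detected[j] - t) <= tol_s:
            used[j] = True
            tp += 1
    return tp, len(planted) - tp, int((~used).sum())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
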