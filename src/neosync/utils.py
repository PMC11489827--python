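"""Shared numerical helpers: seeded RNG streams, robust scale estimates, templates."""

from __future__ import annotations

import numpy as np

#: MAD -> SD consistency factor for a normal distribution.
MAD_TO_SD = 1.0 / 0.6744897501960817


def substream(seed: int, index: int) -> np.random.Generator:
    """Independent generator number ``index`` derived from a master seed.

    Each event class in the simulator draws from its own stream so that the
    ground truth of one class is unchanged when another class is reconfigured.
    """
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(int(index),)))


def robust_sd(x: np.ndarray) -> float:
    """Robust SD via the median absolute deviation (normal-consistent)."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return np.nan
    return float(np.median(np.abs(x - np.median(x))) * MAD_TO_SD)


def diff_noise_sd(x: np.ndarray) -> float:
    """Noise SD estimated from the MAD of the first difference.

    The first difference suppresses slow signal components; for white noise
    its SD is sqrt(2) times the per-sample SD.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        return np.nan
    d = np.diff(x)
    return float(np.median(np.abs(d - np.median(d))) * MAD_TO_SD / np.sqrt(2.0))


def biexp_template(rise_ms: float, decay_ms: float, sampling_rate: float,
                   duration_ms: float | None = None) -> np.ndarray:
    """Unit-peak bi-exponential synaptic event template.

    shape(t) = exp(-t/tau_d) - exp(-t/tau_r), normalized to a peak of 1.
    """
    if rise_ms <= 0 or decay_ms <= rise_ms:
        raise ValueError("require 0 < rise_ms < decay_ms")
    if duration_ms is None:
        duration_ms = rise_ms + 8.0 * decay_ms
    t = np.arange(0.0, duration_ms * 1e-3, 1.0 / sampling_rate)
    tau_r, tau_d = rise_ms * 1e-3, decay_ms * 1e-3
    y = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    return y / y.max()


def matched_kernel(template: np.ndarray) -> np.ndarray:
    """Correlation kernel that is amplitude-preserving for its own template.

    Correlating a signal containing ``a * template`` with
    ``template / ||template||^2`` yields ``a`` at perfect alignment while
    attenuating white noise by a factor ``1 / ||template||``.
    """
    t = np.asarray(template, dtype=float)
    return t / float(np.dot(t, t))


def matched_filter(x: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Amplitude-preserving matched filter (aligned to template onset)."""
    from scipy.signal import fftconvolve

    k = matched_kernel(template)[::-1]
    y = fftconvolve(x, k, mode="full")
    # correlation value at lag i corresponds to template onset at sample i
    return y[len(template) - 1: len(template) - 1 + len(x)]


def poisson_times(rng: np.random.Generator, rate_per_min: float,
                  duration_s: float) -> np.ndarray:
    """Homogeneous Poisson event times in [0, duration) (sorted, seconds)."""
    if rate_per_min < 0:
        raise ValueError("rate must be >= 0")
    n = rng.poisson(rate_per_min * duration_s / 60.0)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def find_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index ranges of True runs in a boolean vector."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[mask[edges + 1]] + 1)
    ends = list(edges[~mask[edges + 1]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))
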