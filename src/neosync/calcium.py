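"""Fluorescence-trace pipeline: dF/F0, transient onsets, network events.

The baseline F0(t) is obtained by deliberately oversmoothing F(t) with a
second-order Savitzky-Golay filter (window 1,500 frames), so transients ride
on a slowly varying baseline and dF/F0 = (F - F0)/F0 is approximately zero
away from events. Network events (giant depolarizing potentials, GDPs) are
defined by co-activation: a transient is GDP-related if some 500-ms interval
containing it has >= 20% of all recorded cells active, and neighboring
GDP-related transients sharing such an interval belong to the same GDP.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .types import CaTRaster, FluorescenceTraceSet, GDPEvent
from .utils import diff_noise_sd, find_runs

__all__ = ["compute_dff", "detect_cats", "detect_gdps", "cat_frequency",
           "gdp_frequency"]


def compute_dff(F: np.ndarray, frame_times: np.ndarray, window_frames: int = 1500,
                polyorder: int = 2, missing_mask: np.ndarray | None = None
                ) -> FluorescenceTraceSet:
    """Baseline estimation and relative fluorescence change.

    ``window_frames`` is interpreted in frames of the native rate and adjusted
    down to the nearest odd integer. Frames flagged in ``missing_mask``
    propagate to dF/F0 as NaN and are excluded from all downstream counts.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    frame_times = np.asarray(frame_times, dtype=float)
    n_frames = F.shape[1]
    window = int(window_frames)
    if window % 2 == 0:
        window -= 1
    if window < polyorder + 1:
        raise ValueError("window too small for the polynomial order")
    if n_frames <= window:
        raise ValueError(
            f"trace length {n_frames} <= window {window}; pass a smaller "
            "window_frames explicitly for short recordings")
    if missing_mask is None:
        missing_mask = np.zeros(n_frames, dtype=bool)
    missing_mask = np.asarray(missing_mask, dtype=bool)

    F0 = savgol_filter(F, window_length=window, polyorder=polyorder,
                       axis=1, mode="interp")
    if np.any(F0 <= 0):
        raise ValueError("non-positive baseline; check raw fluorescence units")
    dff = (F - F0) / F0
    dff[:, missing_mask] = np.nan
    return FluorescenceTraceSet(F=F, frame_times=frame_times,
                                missing_mask=missing_mask, F0=F0, dff=dff)


def detect_cats(traces: FluorescenceTraceSet, threshold_sd: float = 5.0,
                min_amplitude_dff: float = 0.1, refractory_s: float = 0.5,
                release_frac: float = 0.5) -> CaTRaster:
    """Threshold/refractory transient-onset detector.

    The per-cell threshold is the larger of ``threshold_sd`` robust noise SDs
    (noise estimated from the MAD of the first difference of dF/F0) and the
    absolute ``min_amplitude_dff``. The onset is the first frame of each
    suprathreshold excursion, with hysteresis: after an onset the detector
    re-arms only once the trace falls below ``release_frac`` times the
    threshold, so noise dips on a transient's decay do not re-trigger. Onsets
    closer than ``refractory_s`` are merged. Masked frames never carry onsets
    and interrupt excursions.
    """
    if traces.dff is None:
        raise ValueError("run compute_dff first")
    refractory = refractory_s
    onsets: list[np.ndarray] = []
    for x in traces.dff:
        finite = np.isfinite(x)
        if not finite.any():
            onsets.append(np.empty(0))
            continue
        sigma = diff_noise_sd(x)
        thr = max(threshold_sd * sigma, min_amplitude_dff)
        above = np.zeros(x.size, dtype=bool)
        above[finite] = x[finite] >= thr
        starts = []
        prev_end = None
        for s, e in find_runs(above):
            if prev_end is not None:
                gap = x[prev_end:s]
                gap = gap[np.isfinite(gap)]
                released = gap.size == 0 or gap.min() < release_frac * thr
            else:
                released = True
            if released:
                starts.append(s)
            prev_end = e
        times = traces.frame_times[starts]
        kept: list[float] = []
        for t in times:
            if not kept or t - kept[-1] >= refractory:
                kept.append(float(t))
        onsets.append(np.asarray(kept))
    return CaTRaster(onsets=onsets, n_cells=traces.n_cells,
                     analyzed_duration=traces.analyzed_duration)


def _window_count(times: np.ndarray, cells: np.ndarray, start: float,
                  window: float) -> int:
    """Distinct active cells with >= 1 onset inside the closed [start, start+w]."""
    lo = np.searchsorted(times, start - 1e-12, side="left")
    hi = np.searchsorted(times, start + window + 1e-12, side="right")
    return len(set(cells[lo:hi].tolist()))


def _is_gdp_related(i: int, times: np.ndarray, cells: np.ndarray,
                    window: float, need: float) -> bool:
    # any maximizing interval containing onset i can be slid so its right edge
    # lies on an onset in [t_i, t_i + w]; checking those windows is exhaustive
    t = times[i]
    lo = np.searchsorted(times, t - 1e-12, side="left")
    hi = np.searchsorted(times, t + window + 1e-12, side="right")
    for k in range(lo, hi):
        if _window_count(times, cells, times[k] - window, window) >= need:
            return True
    return False


def _share_window(ti: float, tj: float, times: np.ndarray, cells: np.ndarray,
                  window: float, need: float) -> bool:
    """True if some length-``window`` interval containing both onsets is >= need."""
    if tj - ti > window + 1e-12:
        return False
    lo = np.searchsorted(times, tj - 1e-12, side="left")
    hi = np.searchsorted(times, ti + window + 1e-12, side="right")
    for k in range(lo, hi):
        start = times[k] - window
        if start - 1e-12 <= ti and _window_count(times, cells, start, window) >= need:
            return True
    return False


def detect_gdps(raster: CaTRaster, window_s: float = 0.5,
                fraction: float = 0.20) -> list[GDPEvent]:
    """Chain co-active transients into network events.

    Rule 1: a transient is GDP-related if it falls into a ``window_s`` interval
    during which >= ``fraction`` of all cells are active (>= 1 onset inside).
    Rule 2: GDP-related transients sharing such an interval join the same GDP.
    The boundary is inclusive: exactly 20% of cells qualifies at the default.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if raster.n_cells < 1:
        raise ValueError("need at least one cell")
    times, cells = raster.all_onsets()
    if times.size == 0:
        return []
    need = fraction * raster.n_cells - 1e-9

    related = [i for i in range(times.size)
               if _is_gdp_related(i, times, cells, window_s, need)]
    if not related:
        return []

    # union-find over GDP-related onsets; only pairs within one window can join
    parent = list(range(len(related)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    rel_times = times[related]
    for a in range(len(related)):
        for b in range(a + 1, len(related)):
            if rel_times[b] - rel_times[a] > window_s + 1e-12:
                break
            if find(a) == find(b):
                continue
            if _share_window(rel_times[a], rel_times[b], times, cells,
                             window_s, need):
                parent[find(b)] = find(a)

    groups: dict[int, list[int]] = {}
    for a, idx in enumerate(related):
        groups.setdefault(find(a), []).append(idx)

    events = []
    for members in groups.values():
        ts = times[members]
        peak = max(_window_count(times, cells, times[m] - window_s, window_s)
                   for m in members)
        events.append(GDPEvent(start=float(ts.min()), end=float(ts.max()),
                               member_cells=set(cells[members].tolist()),
                               peak_participation=peak / raster.n_cells))
    events.sort(key=lambda e: e.start)
    return events


def cat_frequency(raster: CaTRaster) -> tuple[np.ndarray, float]:
    """Per-cell and mean transient frequency in min^-1 (mask-corrected)."""
    if raster.analyzed_duration <= 0:
        raise ValueError("analyzed duration must be positive")
    per_cell = np.array([len(o) for o in raster.onsets], dtype=float) \
        / raster.analyzed_duration * 60.0
    return per_cell, float(per_cell.mean())


def gdp_frequency(gdps: list[GDPEvent], analyzed_duration: float) -> float:
    """Network-event frequency in min^-1 over the mask-corrected duration."""
    if analyzed_duration <= 0:
        raise ValueError("analyzed duration must be positive")
    return len(gdps) / analyzed_duration * 60.0
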