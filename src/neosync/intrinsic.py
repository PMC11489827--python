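"""Current-clamp feature extraction: RMP, membrane resistance, AP metrics.

Resting membrane potential is the median of Vm(t) at zero current in
consecutive 20-s intervals (test-pulse epochs excised). Membrane resistance
comes from the steady-state deflection of 500-ms hyperpolarizing test pulses.
Action potentials are onsets where the Savitzky-Golay-smoothed first
derivative of Vm crosses 20 V/s upward; excitability metrics (AP threshold,
rheobase, maximum mean and instantaneous rates) follow from the AP tables of
a 500-ms current-step family, aggregated across series by the mean, except
rheobase which uses the median.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .types import IntrinsicProperties, Sweep, SweepSet
from .utils import find_runs

__all__ = ["estimate_rmp", "estimate_rm", "detect_aps", "excitability_metrics",
           "aggregate_series"]


def _pulse_epochs(sweep: Sweep) -> list[tuple[int, int]]:
    """Half-open sample ranges where the command current is non-zero."""
    return find_runs(sweep.command != 0)


def estimate_rmp(sweep: Sweep, interval_s: float = 20.0,
                 stat_window: tuple[float, float] | None = None,
                 post_pulse_blank_s: float = 0.1) -> dict:
    """Median membrane potential per consecutive interval, plus a summary.

    Test-pulse epochs (command != 0) are excised together with a short
    post-pulse recovery margin before taking medians. The summary is the mean
    of the interval medians whose centers fall inside ``stat_window``
    (seconds; default: all intervals).
    """
    rate = sweep.sampling_rate
    n = sweep.data.size
    if interval_s * rate > n:
        raise ValueError("interval longer than the sweep")
    valid = np.ones(n, dtype=bool)
    blank = int(round(post_pulse_blank_s * rate))
    for i0, i1 in _pulse_epochs(sweep):
        valid[i0:min(i1 + blank, n)] = False

    step = int(round(interval_s * rate))
    centers, medians = [], []
    for i0 in range(0, n - step + 1, step):
        seg = sweep.data[i0:i0 + step][valid[i0:i0 + step]]
        if seg.size == 0:
            continue
        centers.append((i0 + step / 2) / rate)
        medians.append(float(np.median(seg)))
    centers = np.asarray(centers)
    medians = np.asarray(medians)

    if stat_window is None:
        sel = np.ones(centers.size, dtype=bool)
    else:
        sel = (centers >= stat_window[0]) & (centers < stat_window[1])
    summary = float(np.mean(medians[sel])) if sel.any() else np.nan
    return {"times": centers, "medians": medians, "summary_mv": summary}


def estimate_rm(sweep: Sweep, baseline_window_s: float = 0.1,
                ss_window_s: float = 0.1) -> dict:
    """Membrane resistance from test-pulse steady-state deflections.

    For each pulse epoch found in the command trace, Rm = dV / I with dV the
    mean voltage change over the final ``ss_window_s`` of the pulse relative
    to the mean over ``baseline_window_s`` immediately before it. A pulse is
    flagged when the deflection at mid-pulse differs from the steady-state
    value by more than 5% (steady state not reached).
    """
    rate = sweep.sampling_rate
    rows = []
    for i0, i1 in _pulse_epochs(sweep):
        amp = float(sweep.command[i0])
        if amp == 0:
            continue
        nb = int(round(baseline_window_s * rate))
        ns = int(round(ss_window_s * rate))
        if i0 - nb < 0 or ns > i1 - i0:
            continue
        baseline = float(np.mean(sweep.data[i0 - nb:i0]))
        ss = float(np.mean(sweep.data[i1 - ns:i1]))
        mid = (i0 + i1) // 2
        half = float(np.mean(sweep.data[mid - ns // 2: mid + ns // 2])) \
            if ns >= 2 else ss
        dv = ss - baseline
        rm = dv / amp * 1e3          # mV / pA -> MOhm
        not_steady = abs((half - baseline) - dv) > 0.05 * abs(dv) if dv != 0 else True
        if not_steady:
            warnings.warn("test pulse did not reach steady state", stacklevel=2)
        rows.append((i0 / rate, amp, dv, rm, not_steady))
    table = pd.DataFrame(rows, columns=["pulse_start_s", "amp_pa", "dv_mv",
                                        "rm_mohm", "not_steady_flag"])
    mean_rm = float(table["rm_mohm"].mean()) if len(table) else np.nan
    return {"per_pulse": table, "rm_mohm": mean_rm}


def detect_aps(sweep: Sweep, sg_window: int = 5, sg_order: int = 2,
               dvdt_threshold: float = 20.0,
               release_frac: float = 0.5) -> pd.DataFrame:
    """AP onsets from the smoothed first derivative of Vm.

    The derivative (central first difference times the sampling rate, V/s) is
    smoothed with a second-order Savitzky-Golay filter (5-sample window).
    An onset is the first sample where the smoothed derivative is >= the
    threshold (inclusive crossing); the detector re-arms only once the
    smoothed derivative falls below ``release_frac`` times the threshold, so
    single-sample noise dips at the crossing cannot re-trigger. Returns a
    table with onset times and Vm at onset.
    """
    rate = sweep.sampling_rate
    if rate < 10_000:
        warnings.warn("sampling rate < 10 kHz gives coarse dV/dt resolution",
                      stacklevel=2)
    dvdt = np.gradient(sweep.data) * rate / 1e3      # mV/sample -> V/s
    smoothed = savgol_filter(dvdt, window_length=sg_window, polyorder=sg_order)
    onsets = []
    prev_end = None
    for s, e in find_runs(smoothed >= dvdt_threshold):
        if prev_end is None or smoothed[prev_end:s].min() < release_frac * dvdt_threshold:
            onsets.append(s)
        prev_end = e
    return pd.DataFrame({
        "time_s": np.asarray(onsets, dtype=float) / rate,
        "vm_mv": sweep.data[onsets] if onsets else np.empty(0),
        "sample": np.asarray(onsets, dtype=int),
    })


def excitability_metrics(step_sweeps: SweepSet,
                         ap_tables: list[pd.DataFrame] | None = None,
                         step_duration_s: float = 0.5) -> list[IntrinsicProperties]:
    """Per-series excitability metrics from a current-step family.

    Only APs whose onsets fall within the step epoch count. Per series:
    rheobase = lowest step amplitude with >= 1 AP; AP threshold = Vm at the
    onset of the first AP at that amplitude; maximum mean rate = max APs per
    step / step duration; maximum instantaneous rate = 1 / min inter-spike
    interval. Metrics without support are NaN.
    """
    if not step_sweeps.sweeps:
        raise ValueError("need at least one step sweep")
    if ap_tables is None:
        ap_tables = [detect_aps(s) for s in step_sweeps.sweeps]

    by_series: dict[int, list[tuple[Sweep, pd.DataFrame]]] = {}
    for sweep, table in zip(step_sweeps.sweeps, ap_tables):
        by_series.setdefault(sweep.series_index, []).append((sweep, table))

    out = []
    for series in sorted(by_series):
        rheobase = np.nan
        ap_thr = np.nan
        max_mean = np.nan
        max_inst = np.nan
        entries = sorted(by_series[series],
                         key=lambda e: (e[0].step_amplitude_pa is None,
                                        e[0].step_amplitude_pa))
        for sweep, table in entries:
            epochs = _pulse_epochs(sweep)
            if not epochs:
                continue
            i0, i1 = epochs[0]
            t0, t1 = i0 / sweep.sampling_rate, i1 / sweep.sampling_rate
            in_step = table[(table["time_s"] >= t0) & (table["time_s"] < t1)]
            if len(in_step) == 0:
                continue
            amp = sweep.step_amplitude_pa
            if np.isnan(rheobase) and amp is not None:
                rheobase = float(amp)
                ap_thr = float(in_step["vm_mv"].iloc[0])
            rate_mean = len(in_step) / step_duration_s
            max_mean = rate_mean if np.isnan(max_mean) else max(max_mean, rate_mean)
            if len(in_step) >= 2:
                inst = 1.0 / np.min(np.diff(in_step["time_s"].to_numpy()))
                max_inst = inst if np.isnan(max_inst) else max(max_inst, inst)
        out.append(IntrinsicProperties(ap_threshold=ap_thr, rheobase=rheobase,
                                       max_mean_rate=max_mean,
                                       max_inst_rate=max_inst))
    return out


def aggregate_series(series_props: list[IntrinsicProperties]) -> IntrinsicProperties:
    """Aggregate per-series metrics: mean everywhere, median for rheobase.

    NaN (undefined) entries are excluded; an all-NaN metric stays NaN.
    """
    def _nanmean(vals):
        vals = np.asarray(vals, dtype=float)
        return float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan

    def _nanmedian(vals):
        vals = np.asarray(vals, dtype=float)
        return float(np.nanmedian(vals)) if np.isfinite(vals).any() else np.nan

    return IntrinsicProperties(
        rmp=_nanmean([p.rmp for p in series_props]),
        rm=_nanmean([p.rm for p in series_props]),
        ap_threshold=_nanmean([p.ap_threshold for p in series_props]),
        rheobase=_nanmedian([p.rheobase for p in series_props]),
        max_mean_rate=_nanmean([p.max_mean_rate for p in series_props]),
        max_inst_rate=_nanmean([p.max_inst_rate for p in series_props]),
    )
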