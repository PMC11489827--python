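"""Domain containers shared across the analysis modules.

Conventions: time in seconds (0-based, intervals half-open [start, end) unless
noted), membrane potential in mV, currents in pA, resistance in MOhm,
capacitance in pF, fluorescence in arbitrary units, rates reported in min^-1.
Event tables are plain :class:`pandas.DataFrame` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd


@dataclass
class FluorescenceTraceSet:
    """Per-cell somatic fluorescence with baseline and relative change.

    ``F`` is a (cells x frames) matrix of raw fluorescence, ``F0`` the
    oversmoothed baseline and ``dff`` the relative change (F - F0) / F0.
    ``missing_mask`` flags frames (e.g. residual z-drift epochs) that are
    excluded from all downstream counts and durations; ``dff`` is NaN there.
    """

    F: np.ndarray
    frame_times: np.ndarray
    missing_mask: np.ndarray
    F0: np.ndarray | None = None
    dff: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.F.shape[0]

    @property
    def n_frames(self) -> int:
        return self.F.shape[1]

    @property
    def frame_interval(self) -> float:
        return float(np.median(np.diff(self.frame_times)))

    @property
    def analyzed_duration(self) -> float:
        """Mask-corrected duration in seconds."""
        return float(np.count_nonzero(~self.missing_mask) * self.frame_interval)


@dataclass
class CaTRaster:
    """Calcium-transient onset raster: one sorted onset-time array per cell."""

    onsets: list[np.ndarray]
    n_cells: int
    analyzed_duration: float

    def all_onsets(self) -> tuple[np.ndarray, np.ndarray]:
        """All onsets pooled and time-sorted; returns (times, cell_ids)."""
        times = np.concatenate([np.asarray(o, dtype=float) for o in self.onsets]) \
            if self.onsets else np.empty(0)
        cells = np.concatenate([np.full(len(o), c) for c, o in enumerate(self.onsets)]) \
            if self.onsets else np.empty(0, dtype=int)
        order = np.argsort(times, kind="stable")
        return times[order], cells[order].astype(int)


@dataclass
class GDPEvent:
    """Network event: a chain of co-active calcium transients."""

    start: float
    end: float
    member_cells: set[int]
    peak_participation: float

    @property
    def n_members(self) -> int:
        return len(self.member_cells)


@dataclass
class Sweep:
    """A single recorded sweep: measured trace plus command (injected) current."""

    data: np.ndarray            # mV (current clamp) or pA (voltage clamp)
    command: np.ndarray         # injected current in pA, same length as data
    sampling_rate: float
    step_amplitude_pa: float | None = None
    series_index: int = 0

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.data.size / self.sampling_rate


@dataclass
class SweepSet:
    """Sweeps grouped by protocol.

    ``protocol`` is one of ``zero_current_test_pulse``, ``step_series``,
    ``mini_continuous``, ``paired_pulse``. For paired-pulse data,
    ``stim_times`` holds the within-sweep stimulus times (seconds).
    """

    sweeps: list[Sweep]
    sampling_rate: float
    protocol: str
    step_amplitudes: list[float] | None = None
    stim_times: list[float] | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.step_amplitudes is not None:
            amps = list(self.step_amplitudes)
            if any(b < a for a, b in zip(amps, amps[1:])):
                raise ValueError("step_amplitudes must be monotone increasing")


@dataclass
class IntrinsicProperties:
    """Passive and excitability features of one cell / one series.

    Undefined metrics (e.g. rheobase when no current step elicited an AP) are
    NaN, never 0, and are excluded from aggregation.
    """

    rmp: float = np.nan
    rm: float = np.nan
    ap_threshold: float = np.nan
    rheobase: float = np.nan
    max_mean_rate: float = np.nan
    max_inst_rate: float = np.nan


@dataclass
class MiniEventSet:
    """Detected miniature synaptic events (amplitudes as positive magnitudes)."""

    times: np.ndarray
    amplitudes: np.ndarray
    areas: np.ndarray           # pA*ms
    analyzed_duration: float

    @property
    def n_events(self) -> int:
        return int(self.times.size)


@dataclass
class EvokedTrialSet:
    """Paired-pulse evoked trials with per-pulse outcome bookkeeping.

    ``raw_amplitudes`` (n_trials x n_pulses) are baseline-relative peak inward
    deflections (positive magnitudes); ``outcomes`` True marks a success.
    ``corrected_amplitudes`` subtract the per-pulse mean failure amplitude.
    """

    sweeps: SweepSet
    stim_times: np.ndarray
    raw_amplitudes: np.ndarray | None = None
    outcomes: np.ndarray | None = None
    corrected_amplitudes: np.ndarray | None = None
    mean_failure_amplitude: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return len(self.sweeps.sweeps)

    def failure_rate(self, pulse: int = 0) -> float:
        """Fraction of trials classified as failures for one pulse (0-based)."""
        if self.outcomes is None:
            raise ValueError("run classify_evoked first")
        return float(np.mean(~self.outcomes[:, pulse]))


@dataclass
class LFPRecording:
    """Continuous LFP plus the electrode's technical-noise reference segment."""

    signal: np.ndarray
    noise_reference: np.ndarray
    sampling_rate: float
    artifact_mask: list[tuple[float, float]] = field(default_factory=list)
    injection_time: float | None = None

    @property
    def duration(self) -> float:
        return self.signal.size / self.sampling_rate


@dataclass
class SpectralEstimate:
    """Welch PSD with band-integrated power, optionally noise-normalized."""

    frequencies: np.ndarray
    psd: np.ndarray
    band: tuple[float, float]
    bandpower: float
    normalized_bandpower: float | None = None


@dataclass
class SyntheticConfig:
    """Describes one synthetic dataset: modality, duration, rate, seed, params."""

    modality: str
    duration: float
    sampling_rate: float
    seed: int
    modality_params: dict[str, Any] = field(default_factory=dict)

    VALID_MODALITIES = ("calcium", "currentclamp", "voltageclamp_mini",
                        "voltageclamp_evoked", "lfp")

    def __post_init__(self) -> None:
        if self.modality not in self.VALID_MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")


@dataclass
class SyntheticGroundTruth:
    """Planted truth emitted alongside every synthetic dataset."""

    event_times: dict[str, Any] = field(default_factory=dict)
    event_amplitudes: dict[str, Any] = field(default_factory=dict)
    event_durations: dict[str, Any] = field(default_factory=dict)
    planted_rates: dict[str, float] = field(default_factory=dict)
    membrane_params: dict[str, float] = field(default_factory=dict)
    failure_flags: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the ground-truth table layout (one row per event)."""
        rows = []
        for cls, times in self.event_times.items():
            amps = self.event_amplitudes.get(cls)
            durs = self.event_durations.get(cls)
            if isinstance(times, dict):       # per-cell event lists
                for cell, ts in times.items():
                    for i, t in enumerate(np.atleast_1d(ts)):
                        amp = np.atleast_1d(amps[cell])[i] if amps is not None else np.nan
                        rows.append((cls, float(t), float(amp), np.nan, -1, cell))
            else:
                for i, t in enumerate(np.atleast_1d(times)):
                    amp = np.atleast_1d(amps)[i] if amps is not None else np.nan
                    dur = np.atleast_1d(durs)[i] if durs is not None else np.nan
                    rows.append((cls, float(t), float(amp), float(dur), -1, -1))
        if self.failure_flags is not None:
            flags = np.atleast_2d(self.failure_flags)
            for trial in range(flags.shape[0]):
                for pulse in range(flags.shape[1]):
                    rows.append((f"failure_pulse{pulse + 1}", np.nan,
                                 float(flags[trial, pulse]), np.nan, trial, -1))
        return pd.DataFrame(rows, columns=["event_class", "time_s", "amplitude",
                                           "duration_s", "trial", "cell"])
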