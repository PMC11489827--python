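"""Synthetic-data generators with planted, machine-readable ground truth.

Every generator consumes a :class:`~neosync.types.SyntheticConfig` and returns
``(data, SyntheticGroundTruth)``. Each event class draws from its own seeded
RNG substream, so reconfiguring one class leaves the others' ground truth
unchanged, and identical config + seed yields bit-identical output.

The defaults in :mod:`neosync.presets` encode the recording conditions this
package is designed around: 8-min two-photon imaging blocks, 20 kHz
current/voltage-clamp sweeps, and 30-min LFP sessions with a 5-min
technical-noise reference.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal.windows import tukey

from . import presets
from .types import (LFPRecording, FluorescenceTraceSet, Sweep, SweepSet,
                    SyntheticConfig, SyntheticGroundTruth)
from .utils import biexp_template, substream

__all__ = [
    "gen_calcium", "gen_currentclamp", "gen_voltageclamp", "gen_lfp",
    "generate", "ap_template", "espw_template",
]

# RNG substream indices, one per planted event class / noise source.
_STREAMS = {
    "cat": 0, "gdp": 1, "ca_noise": 2, "ca_drift": 3,
    "cc_noise": 10,
    "mini_times": 20, "mini_amps": 21, "vc_noise": 22, "evoked_failures": 23,
    "espw": 30, "burst": 31, "lfp_noise": 32, "lfp_ref_noise": 33, "burst_phase": 34,
}


def _rng(config: SyntheticConfig, name: str) -> np.random.Generator:
    return substream(config.seed, _STREAMS[name])


def _renewal_times(rng: np.random.Generator, rate_per_min: float, duration_s: float,
                   dead_time_s: float = 0.0) -> np.ndarray:
    """Event times at a target rate with a hard minimum separation.

    A renewal process with gaps ``dead + Exponential(mean - dead)`` keeps the
    configured mean rate while guaranteeing non-overlapping event supports.
    """
    if rate_per_min < 0:
        raise ValueError("rate must be >= 0")
    if rate_per_min == 0:
        return np.empty(0)
    mean_gap = 60.0 / rate_per_min
    if dead_time_s >= mean_gap:
        raise ValueError("dead time exceeds the mean inter-event interval")
    times = []
    t = rng.exponential(mean_gap)
    while t < duration_s:
        times.append(t)
        t += dead_time_s + rng.exponential(mean_gap - dead_time_s)
    return np.asarray(times)


# --------------------------------------------------------------------------- #
# calcium imaging
# --------------------------------------------------------------------------- #

def gen_calcium(config: SyntheticConfig):
    """Poisson somatic Ca2+ transients with network co-activation epochs.

    Per cell, F(t) = F0_drift(t) * (1 + sum of transients) + noise. Network
    events co-activate at least ``gdp_participation`` of all cells within a
    span well inside the 500-ms co-activation window used downstream.
    """
    p = {**presets.CALCIUM_CONTROL, **config.modality_params}
    n_cells = int(p["n_cells"])
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if not (0.0 < p["gdp_participation"] <= 1.0):
        raise ValueError("gdp_participation must be in (0, 1]")
    if p["cell_rate_per_min"] < 0 or p["gdp_rate_per_min"] < 0:
        raise ValueError("rates must be >= 0")

    duration = float(config.duration)
    rate = float(config.sampling_rate)
    n_frames = int(round(duration * rate))
    frame_times = np.arange(n_frames) / rate

    rng_cat = _rng(config, "cat")
    rng_gdp = _rng(config, "gdp")
    rng_noise = _rng(config, "ca_noise")
    rng_drift = _rng(config, "ca_drift")

    onsets = [np.sort(_renewal_times(rng_cat, p["cell_rate_per_min"], duration))
              for _ in range(n_cells)]

    gdp_times = _renewal_times(rng_gdp, p["gdp_rate_per_min"],
                               max(duration - p["gdp_span_s"], 0.0),
                               dead_time_s=2.0 * p["gdp_span_s"])
    n_members = int(np.ceil(p["gdp_participation"] * n_cells))
    for t_gdp in gdp_times:
        members = rng_gdp.choice(n_cells, size=n_members, replace=False)
        jitter = rng_gdp.uniform(0.0, p["gdp_span_s"], size=n_members)
        for cell, dt in zip(members, jitter):
            onsets[cell] = np.sort(np.append(onsets[cell], t_gdp + dt))

    # transient kernel: instantaneous rise, exponential decay
    kernel_len = int(round(8.0 * p["decay_s"] * rate)) + 1
    kernel = p["amp_dff"] * np.exp(-np.arange(kernel_len) / (p["decay_s"] * rate))

    phase = rng_drift.uniform(0.0, 2.0 * np.pi)
    drift = 1.0 + p["drift_amp"] * np.sin(
        2.0 * np.pi * frame_times / p["drift_period_s"] + phase)

    F = np.empty((n_cells, n_frames))
    for c in range(n_cells):
        s = np.zeros(n_frames)
        idx = np.round(np.asarray(onsets[c]) * rate).astype(int)
        for i in idx:
            stop = min(i + kernel_len, n_frames)
            s[i:stop] += kernel[: stop - i]
        F[c] = p["f0"] * drift * (1.0 + s)
    F += rng_noise.normal(0.0, p["noise_sd_dff"] * p["f0"], size=F.shape)

    traces = FluorescenceTraceSet(F=F, frame_times=frame_times,
                                  missing_mask=np.zeros(n_frames, dtype=bool))
    truth = SyntheticGroundTruth(
        event_times={"cat": {c: onsets[c] for c in range(n_cells)},
                     "gdp": gdp_times},
        planted_rates={"cat_per_min": p["cell_rate_per_min"],
                       "gdp_per_min": p["gdp_rate_per_min"]},
    )
    return traces, truth


# --------------------------------------------------------------------------- #
# current clamp
# --------------------------------------------------------------------------- #

def ap_template(sampling_rate: float, amp_mv: float = 60.0, sigma_ms: float = 0.3,
                ahp_mv: float = 8.0) -> np.ndarray:
    """Biphasic action-potential waveform stamped onto the membrane trace.

    A Gaussian upstroke (peak dV/dt = amp / (sigma * sqrt(e)), ~121 V/s at the
    defaults) followed by a shallow afterhyperpolarization, ~4 ms total.
    """
    t = np.arange(0.0, 4e-3, 1.0 / sampling_rate)
    sig = sigma_ms * 1e-3
    spike = amp_mv * np.exp(-0.5 * ((t - 1e-3) / sig) ** 2)
    ahp = ahp_mv * np.exp(-0.5 * ((t - 2.5e-3) / 5e-4) ** 2)
    return spike - ahp


def _integrate_membrane(I: np.ndarray, rate: float, r_mohm: float, c_pf: float,
                        e_rest: float, v_threshold: float | None = None,
                        v_reset: float = -55.0, refractory_s: float = 0.003,
                        template: np.ndarray | None = None):
    """Single-compartment leaky integrator driven by piecewise-constant current.

    Uses the exact exponential update per constant-current segment, so the
    noise-free step response equals the closed-form RC solution to machine
    precision. If ``v_threshold`` is given, integrate-and-fire spikes are
    detected analytically within each segment, the template waveform is added
    at the crossing sample, and the state resets after the refractory period.
    """
    tau = r_mohm * c_pf * 1e-6              # MOhm * pF = us -> seconds
    dt = 1.0 / rate
    decay = np.exp(-dt / tau)
    n = I.size
    V = np.empty(n)
    ap_idx: list[int] = []

    # segment boundaries where the command current changes
    change = np.flatnonzero(np.diff(I)) + 1
    bounds = np.concatenate(([0], change, [n]))
    v = e_rest
    pos = 0
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        if b1 <= pos:
            continue
        seg_start = max(b0, pos)
        v_inf = e_rest + I[seg_start] * r_mohm * 1e-3    # pA * MOhm = uV
        while seg_start < b1:
            k = np.arange(b1 - seg_start)
            traj = v_inf + (v - v_inf) * decay ** (k + 1)
            if v_threshold is None or traj.max() < v_threshold:
                V[seg_start:b1] = traj
                v = traj[-1] if traj.size else v
                seg_start = b1
            else:
                cross = int(np.argmax(traj >= v_threshold))
                V[seg_start:seg_start + cross + 1] = traj[: cross + 1]
                spike_at = seg_start + cross
                ap_idx.append(spike_at)
                refr = max(int(round(refractory_s * rate)), 1)
                hold_end = min(spike_at + refr, b1)
                V[spike_at:hold_end] = v_reset
                v = v_reset
                seg_start = hold_end
        pos = b1

    if template is not None:
        for i in ap_idx:
            stop = min(i + template.size, n)
            V[i:stop] += template[: stop - i]
    return V, np.asarray(ap_idx, dtype=int) / rate


def gen_currentclamp(config: SyntheticConfig):
    """Current-clamp sweeps from a leaky integrate-and-fire neuron.

    ``modality_params['protocol']`` selects the stimulus set:

    - ``zero_current_test_pulse`` (default): one continuous sweep with brief
      hyperpolarizing test pulses at 20-s intervals (resting-potential and
      membrane-resistance protocol). Set ``test_pulse_pa`` to 0 to disable
      the pulses (pure zero-current recording).
    - ``step_series``: ``n_series`` repetitions of a 500-ms depolarizing step
      family (excitability protocol); spikes are stamped as template
      waveforms at the integrate-and-fire crossing times.
    """
    p = {**presets.CURRENTCLAMP_DEFAULTS, **presets.MEMBRANE_PRE_BACLOFEN,
         **config.modality_params}
    rate = float(config.sampling_rate)
    rng = _rng(config, "cc_noise")
    protocol = p.get("protocol", "zero_current_test_pulse")
    r, c, e = float(p["r_mohm"]), float(p["c_pf"]), float(p["e_rest_mv"])
    tau = r * c * 1e-6

    truth = SyntheticGroundTruth(
        membrane_params={"r_mohm": r, "c_pf": c, "e_rest_mv": e})

    if protocol == "zero_current_test_pulse":
        if p["test_pulse_pa"] != 0 and tau >= p["test_pulse_dur_s"] / 3.0:
            warnings.warn("membrane tau >= pulse duration / 3: steady state "
                          "not reached within the test pulse", stacklevel=2)
        n = int(round(config.duration * rate))
        I = np.zeros(n)
        pulse_starts = []
        if p["test_pulse_pa"] != 0:
            t0 = p["test_pulse_interval_s"] / 2.0
            while t0 + p["test_pulse_dur_s"] < config.duration:
                i0 = int(round(t0 * rate))
                i1 = i0 + int(round(p["test_pulse_dur_s"] * rate))
                I[i0:i1] = p["test_pulse_pa"]
                pulse_starts.append(t0)
                t0 += p["test_pulse_interval_s"]
        V, _ = _integrate_membrane(I, rate, r, c, e)
        if p["noise_sd_mv"] > 0:
            V = V + rng.normal(0.0, p["noise_sd_mv"], size=n)
        sweeps = SweepSet(sweeps=[Sweep(V, I, rate)], sampling_rate=rate,
                          protocol="zero_current_test_pulse")
        truth.event_times["test_pulse"] = np.asarray(pulse_starts)
        return sweeps, truth

    if protocol != "step_series":
        raise ValueError(f"unknown current-clamp protocol {protocol!r}")

    template = ap_template(rate, p["ap_amp_mv"], p["ap_sigma_ms"])
    amps = np.arange(p["step_start_pa"], p["step_stop_pa"] + p["step_increment_pa"] / 2,
                     p["step_increment_pa"])
    pre = int(round(0.1 * rate))
    dur = int(round(p["step_dur_s"] * rate))
    post = int(round(0.2 * rate))
    sweeps = []
    ap_times: dict[int, np.ndarray] = {}
    idx = 0
    for series in range(int(p["n_series"])):
        for amp in amps:
            I = np.zeros(pre + dur + post)
            I[pre:pre + dur] = amp
            V, aps = _integrate_membrane(
                I, rate, r, c, e, v_threshold=p["v_threshold_mv"],
                v_reset=p["v_reset_mv"], refractory_s=p["refractory_s"],
                template=template)
            if p["noise_sd_mv"] > 0:
                V = V + rng.normal(0.0, p["noise_sd_mv"], size=V.size)
            sweeps.append(Sweep(V, I, rate, step_amplitude_pa=float(amp),
                                series_index=series))
            ap_times[idx] = aps
            idx += 1
    out = SweepSet(sweeps=sweeps, sampling_rate=rate, protocol="step_series",
                   step_amplitudes=list(map(float, amps)))
    truth.event_times["ap"] = ap_times
    truth.membrane_params["v_threshold_mv"] = p["v_threshold_mv"]
    return out, truth


# --------------------------------------------------------------------------- #
# voltage clamp
# --------------------------------------------------------------------------- #

def gen_voltageclamp(config: SyntheticConfig):
    """Miniature (continuous) or evoked paired-pulse voltage-clamp data.

    Mini mode plants Poisson-timed bi-exponential inward events with lognormal
    amplitudes on Gaussian baseline noise. Evoked mode builds trial-aligned
    sweeps with a stimulus artifact and per-pulse Bernoulli (or exactly
    planted) failures; EPSC amplitudes are negative (inward) deflections.
    """
    if config.modality == "voltageclamp_mini":
        return _gen_minis(config)
    return _gen_evoked(config)


def _gen_minis(config: SyntheticConfig):
    p = {**presets.MINI_CONTROL, **config.modality_params}
    rate = float(config.sampling_rate)
    n = int(round(config.duration * rate))
    rng_t = _rng(config, "mini_times")
    rng_a = _rng(config, "mini_amps")
    rng_n = _rng(config, "vc_noise")

    template = biexp_template(p["rise_ms"], p["decay_ms"], rate)
    times = _renewal_times(rng_t, p["rate_per_min"], config.duration,
                           dead_time_s=2.0 * p["decay_ms"] * 1e-3)
    amps = np.exp(rng_a.normal(np.log(p["median_amp_pa"]), p["sigma_log"],
                               size=times.size))
    trace = rng_n.normal(0.0, p["noise_sd_pa"], size=n) if p["noise_sd_pa"] > 0 \
        else np.zeros(n)
    for t0, a in zip(times, amps):
        i = int(round(t0 * rate))
        stop = min(i + template.size, n)
        trace[i:stop] -= a * template[: stop - i]

    sweeps = SweepSet(sweeps=[Sweep(trace, np.zeros(n), rate)],
                      sampling_rate=rate, protocol="mini_continuous")
    truth = SyntheticGroundTruth(
        event_times={"mini": times}, event_amplitudes={"mini": amps},
        planted_rates={"mini_per_min": p["rate_per_min"]})
    return sweeps, truth


def _gen_evoked(config: SyntheticConfig):
    p = {**presets.EVOKED_CONTROL, **config.modality_params}
    rate = float(config.sampling_rate)
    n_trials = int(p["n_trials"])
    rng_f = _rng(config, "evoked_failures")
    rng_n = _rng(config, "vc_noise")

    noise_sd = p["noise_sd_pa"]
    if "snr" in p and p["snr"] is not None:
        noise_sd = p["success_amp1_pa"] / float(p["snr"])

    if "failure_pattern" in p and p["failure_pattern"] is not None:
        flags = np.asarray(p["failure_pattern"], dtype=bool)
        if flags.shape[0] != n_trials:
            raise ValueError("failure_pattern length must equal n_trials")
        if flags.ndim == 1:
            flags = np.column_stack([flags, flags])
    elif p.get("failure_mode", "bernoulli") == "exact":
        k = int(p["n_failures_exact"])
        if not 0 <= k <= n_trials:
            raise ValueError("n_failures_exact outside [0, n_trials]")
        base = np.zeros(n_trials, dtype=bool)
        base[:k] = True
        flags = np.column_stack([rng_f.permutation(base),
                                 rng_f.permutation(base)])
    else:
        prob = float(p["failure_prob"])
        if not 0.0 <= prob <= 1.0:
            raise ValueError("failure probability outside [0, 1]")
        flags = rng_f.random((n_trials, 2)) < prob

    n = int(round(p["trial_duration_s"] * rate))
    stim = np.array([p["stim1_time_s"],
                     p["stim1_time_s"] + p["paired_pulse_interval_s"]])
    epsc = biexp_template(p["rise_ms"], p["decay_ms"], rate)
    t_art = np.arange(0.0, 2e-3, 1.0 / rate)
    artifact = p["artifact_amp_pa"] * np.exp(-t_art / (p["artifact_tail_ms"] * 1e-3))
    success_amp = np.array([p["success_amp1_pa"], p["success_amp2_pa"]])
    latency = int(round(p["latency_ms"] * 1e-3 * rate))

    amplitudes = np.where(flags, 0.0, success_amp[None, :])
    sweeps = []
    for trial in range(n_trials):
        trace = rng_n.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
        for pulse, t0 in enumerate(stim):
            i = int(round(t0 * rate))
            stop = min(i + artifact.size, n)
            trace[i:stop] += artifact[: stop - i]
            a = amplitudes[trial, pulse]
            if a > 0:
                j = i + latency
                stop = min(j + epsc.size, n)
                trace[j:stop] -= a * epsc[: stop - j]
        sweeps.append(Sweep(trace, np.zeros(n), rate))

    out = SweepSet(sweeps=sweeps, sampling_rate=rate, protocol="paired_pulse",
                   stim_times=list(stim))
    truth = SyntheticGroundTruth(
        event_amplitudes={"eepsc": amplitudes},
        planted_rates={"failure_prob": float(p.get("failure_prob", np.nan))},
        failure_flags=flags)
    return out, truth


# --------------------------------------------------------------------------- #
# in vivo LFP
# --------------------------------------------------------------------------- #

def _pink_noise(rng: np.random.Generator, n: int, rate: float, alpha: float,
                rms: float) -> np.ndarray:
    """1/f^alpha Gaussian noise via frequency-domain shaping, scaled to rms."""
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    spec = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
    scale = np.zeros(freqs.size)
    scale[1:] = freqs[1:] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * scale, n=n)
    return x * (rms / np.std(x))


def espw_template(sampling_rate: float, amp_mv: float, width_ms: float,
                  ripple_hz: float, ripple_frac: float,
                  polarity: float = -1.0) -> np.ndarray:
    """Early-sharp-wave waveform: monophasic deflection plus 15-30 Hz ripple."""
    sig = width_ms * 1e-3 / 4.0
    t = np.arange(-3.0 * sig, 3.0 * sig, 1.0 / sampling_rate)
    envelope = np.exp(-0.5 * (t / sig) ** 2)
    deflection = polarity * amp_mv * envelope
    ripple = ripple_frac * amp_mv * envelope * np.sin(2.0 * np.pi * ripple_hz * t)
    return deflection + ripple


def gen_lfp(config: SyntheticConfig):
    """1/f background LFP with planted sharp waves and oscillatory bursts.

    The returned recording carries the raw-rate signal (so the analysis stage
    exercises its own downsampling) and a separate technical-noise reference
    segment drawn from the same noise process but containing no events.
    """
    p = {**presets.LFP_P35_CONTROL, **config.modality_params}
    rate = float(config.sampling_rate)
    duration = float(config.duration)
    n = int(round(duration * rate))

    signal = _pink_noise(_rng(config, "lfp_noise"), n, rate,
                         p["noise_alpha"], p["noise_rms_mv"])
    reference = _pink_noise(_rng(config, "lfp_ref_noise"),
                            int(round(p["reference_duration_s"] * rate)), rate,
                            p["noise_alpha"], p["noise_rms_mv"])
    if p["drift_amp_mv"] > 0:
        t = np.arange(n) / rate
        signal = signal + p["drift_amp_mv"] * np.sin(
            2.0 * np.pi * t / p["drift_period_s"])

    rng_espw = _rng(config, "espw")
    rng_burst = _rng(config, "burst")
    rng_phase = _rng(config, "burst_phase")

    # --- eSPWs
    tmpl = espw_template(rate, p["espw_amp_mv"], p["espw_width_ms"],
                         p["espw_ripple_hz"], p["espw_ripple_frac"],
                         p["espw_polarity"])
    if tmpl.size > n:
        raise ValueError("eSPW template longer than the recording")
    half = tmpl.size // 2
    espw_times = _renewal_times(rng_espw, p["espw_rate_per_min"], duration,
                                dead_time_s=1.0)
    espw_times = espw_times[(espw_times * rate > half)
                            & (espw_times * rate < n - half)]
    for t0 in espw_times:
        i = int(round(t0 * rate)) - half
        signal[i:i + tmpl.size] += tmpl

    # --- theta-beta bursts
    burst_starts = _renewal_times(rng_burst, p["burst_rate_per_min"], duration,
                                  dead_time_s=p["burst_dur_max_s"] + 1.0)
    burst_durs = rng_burst.uniform(p["burst_dur_min_s"], p["burst_dur_max_s"],
                                   size=burst_starts.size)
    keep = burst_starts + burst_durs < duration
    burst_starts, burst_durs = burst_starts[keep], burst_durs[keep]
    merged_starts, merged_durs = [], []
    for s, d in zip(burst_starts, burst_durs):
        if merged_starts and s <= merged_starts[-1] + merged_durs[-1]:
            warnings.warn("overlapping planted bursts merged in ground truth",
                          stacklevel=2)
            merged_durs[-1] = max(merged_durs[-1], s + d - merged_starts[-1])
        else:
            merged_starts.append(s)
            merged_durs.append(d)
    for s, d in zip(merged_starts, merged_durs):
        i0 = int(round(s * rate))
        m = int(round(d * rate))
        tt = np.arange(m) / rate
        # tapered-cosine envelope: sustained amplitude with brief on/off ramps,
        # so the planted duration is well-defined
        env = tukey(m, alpha=0.25)
        phase = rng_phase.uniform(0.0, 2.0 * np.pi)
        signal[i0:i0 + m] += p["burst_amp_mv"] * env * np.sin(
            2.0 * np.pi * p["burst_carrier_hz"] * tt + phase)

    rec = LFPRecording(signal=signal, noise_reference=reference,
                       sampling_rate=rate)
    truth = SyntheticGroundTruth(
        event_times={"espw": espw_times, "burst": np.asarray(merged_starts)},
        event_amplitudes={"espw": np.full(espw_times.size, p["espw_amp_mv"])},
        event_durations={"burst": np.asarray(merged_durs)},
        planted_rates={"espw_per_min": p["espw_rate_per_min"],
                       "burst_per_min": p["burst_rate_per_min"]})
    return rec, truth


# --------------------------------------------------------------------------- #

_GENERATORS = {
    "calcium": gen_calcium,
    "currentclamp": gen_currentclamp,
    "voltageclamp_mini": gen_voltageclamp,
    "voltageclamp_evoked": gen_voltageclamp,
    "lfp": gen_lfp,
}


def generate(config: SyntheticConfig):
    """Dispatch to the generator for ``config.modality``."""
    return _GENERATORS[config.modality](config)
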