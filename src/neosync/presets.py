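"""Default simulation presets.

Each preset encodes the recording conditions of one experiment type in the
neonatal CA1 study design this package targets: control values are the
published control-condition measurements (used as planted ground truth for
parameter-recovery testing), "silenced" presets the corresponding
chemogenetically inhibited condition.
"""

from __future__ import annotations

# --- two-photon calcium imaging, P2-5, 8-min blocks -------------------------

CALCIUM_CONTROL = dict(
    n_cells=20,
    duration_s=480.0,            # 8-min imaging block
    frame_rate_hz=10.0,
    cell_rate_per_min=1.4,       # control somatic CaT frequency
    gdp_rate_per_min=2.0,        # network-event rate
    gdp_participation=0.8,       # fraction of cells recruited per GDP
    gdp_span_s=0.3,              # co-activation jitter (well inside 500 ms)
    amp_dff=0.5,
    decay_s=1.0,
    noise_sd_dff=0.05,
    drift_amp=0.05,              # slow multiplicative baseline drift
    drift_period_s=300.0,
    f0=100.0,
)

CALCIUM_SILENCED = dict(CALCIUM_CONTROL, cell_rate_per_min=0.0, gdp_rate_per_min=0.0)

# --- current clamp -----------------------------------------------------------

#: Passive parameters matching the published pre-baclofen P29-31 cell averages.
MEMBRANE_PRE_BACLOFEN = dict(r_mohm=154.5, c_pf=100.0, e_rest_mv=-61.3)
MEMBRANE_POST_BACLOFEN = dict(r_mohm=85.8, c_pf=100.0, e_rest_mv=-67.2)

CURRENTCLAMP_DEFAULTS = dict(
    noise_sd_mv=0.2,
    test_pulse_pa=-10.0,         # -10 pA at P2-5 (-20 pA at P8-12)
    test_pulse_dur_s=0.5,
    test_pulse_interval_s=20.0,
    step_start_pa=0.0,
    step_stop_pa=120.0,
    step_increment_pa=10.0,
    step_dur_s=0.5,
    n_series=3,
    v_threshold_mv=-45.0,    # rheobase ~110 pA given the default R and E_rest
    v_reset_mv=-55.0,
    refractory_s=0.003,
    ap_amp_mv=60.0,
    ap_sigma_ms=0.3,             # peak dV/dt ~ 120 V/s, well above the 20 V/s criterion
)

# --- voltage clamp: miniature EPSCs ------------------------------------------

MINI_CONTROL = dict(
    rate_per_min=0.13,           # control mEPSC frequency (printed value, min^-1)
    median_amp_pa=20.0,
    sigma_log=0.3,               # lognormal amplitude spread
    rise_ms=1.5,
    decay_ms=6.0,
    noise_sd_pa=2.5,
)

MINI_SILENCED = dict(MINI_CONTROL, rate_per_min=0.05)

# --- voltage clamp: evoked paired-pulse EPSCs --------------------------------
# The control preset's success amplitude is set so that the failure-corrected
# mean over all trials (successes carry the full amplitude, failures ~0 after
# correction) has closed-form expectation 46.5 * 22/30 = 34.1 pA, the published
# control mean; the exact planted failure count 8/30 matches the published
# 25 +/- 6 % control failure rate.

EVOKED_CONTROL = dict(
    n_trials=30,
    failure_prob=0.25,           # Bernoulli mode
    n_failures_exact=8,          # deterministic mode (noiseless worked examples)
    success_amp1_pa=46.5,
    success_amp2_pa=55.8,        # mild paired-pulse facilitation
    rise_ms=1.0,
    decay_ms=5.0,
    latency_ms=3.0,
    paired_pulse_interval_s=0.05,
    trial_duration_s=0.5,
    stim1_time_s=0.1,
    artifact_amp_pa=200.0,
    artifact_tail_ms=0.3,
    noise_sd_pa=0.0,
)

EVOKED_SILENCED = dict(
    EVOKED_CONTROL,
    failure_prob=0.92,           # post-silencing failure rate
    n_failures_exact=92,         # of 100 trials in the worked example
    n_trials=100,
    success_amp1_pa=21.25,       # 21.25 * 0.08 = 1.7 pA mean, the published value
    success_amp2_pa=25.5,
)


def evoked_expected_corrected_mean(preset: dict, pulse: int = 1) -> float:
    """Closed-form expectation of the failure-corrected mean amplitude.

    With k planted failures out of n trials and success amplitude A, failures
    measure ~0 and carry amplitude A otherwise, so the corrected per-cell mean
    over all trials is A * (n - k) / n.
    """
    amp = preset[f"success_amp{pulse}_pa"]
    n = preset["n_trials"]
    k = preset["n_failures_exact"]
    return amp * (n - k) / n


# --- in vivo LFP -------------------------------------------------------------

LFP_COMMON = dict(
    source_rate_hz=20_000.0,
    noise_rms_mv=0.02,
    noise_alpha=1.0,             # 1/f background
    reference_duration_s=300.0,  # 5-min technical-noise reference
    drift_amp_mv=0.05,
    drift_period_s=200.0,
)

#: P3-5: activity dominated by early sharp waves.
LFP_P35_CONTROL = dict(
    LFP_COMMON,
    duration_s=1800.0,
    espw_rate_per_min=2.1,       # published control eSPW rate
    espw_amp_mv=0.2,
    espw_width_ms=150.0,
    espw_ripple_hz=22.0,
    espw_ripple_frac=0.5,        # ripple amplitude relative to the deflection
    espw_polarity=-1.0,
    burst_rate_per_min=0.0,
    burst_carrier_hz=8.0,
    burst_amp_mv=0.1,
    burst_dur_min_s=0.8,
    burst_dur_max_s=2.0,
)

LFP_P35_SILENCED = dict(LFP_P35_CONTROL, espw_rate_per_min=0.0)

#: P10-12: discontinuous theta-beta oscillatory bursts.
LFP_P1012_CONTROL = dict(
    LFP_P35_CONTROL,
    espw_rate_per_min=0.0,
    burst_rate_per_min=4.0,      # published control burst rate
)

LFP_P1012_SILENCED = dict(LFP_P1012_CONTROL, burst_rate_per_min=2.0)


PRESETS = {
    "calcium_control": CALCIUM_CONTROL,
    "calcium_silenced": CALCIUM_SILENCED,
    "mini_control": MINI_CONTROL,
    "mini_silenced": MINI_SILENCED,
    "evoked_control": EVOKED_CONTROL,
    "evoked_silenced": EVOKED_SILENCED,
    "lfp_p35_control": LFP_P35_CONTROL,
    "lfp_p35_silenced": LFP_P35_SILENCED,
    "lfp_p1012_control": LFP_P1012_CONTROL,
    "lfp_p1012_silenced": LFP_P1012_SILENCED,
}
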