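# Methods

This note documents the quantitative procedures the package implements, the
models behind the synthetic-data generator, the defaults that matter, and the
numerical choices made where the procedure was genuinely open.

## Fluorescence pipeline

**Baseline and ΔF/F0.** The baseline F0(t) is obtained by *oversmoothing* the
raw fluorescence with a second-order Savitzky–Golay filter whose window
(default 1,500 frames, reduced to the nearest odd integer) is far longer than
any Ca²⁺ transient, so transients do not survive into the baseline while slow
drift does. At every interior frame F0 therefore equals the least-squares
quadratic over the centered window evaluated at its midpoint, which the test
suite verifies against an independent polynomial regression to 1e−9 relative
tolerance. ΔF/F0 = (F − F0)/F0. Frames flagged as missing (e.g. residual
z-drift epochs) become NaN in ΔF/F0 and are excluded from every downstream
count and duration; the analyzed duration is always the mask-corrected one.

**Transient onsets.** The detector is a deliberately simple threshold device:
per cell the threshold is the larger of `threshold_sd` (default 5) robust
noise SDs — noise estimated as MAD(diff(ΔF/F0))/(0.6745·√2), which is immune
to the transients themselves — and an absolute floor `min_amplitude_dff`
(default 0.1). The onset is the first frame of a suprathreshold excursion.
Two guards prevent double counting: hysteresis (the detector re-arms only
after the trace falls below half the threshold, so noise dips on a decay do
not re-trigger) and a 0.5-s refractory merge. This stand-in is validated
purely against planted synthetic ground truth (recall/precision ≥ 0.97 at the
default conditions); it does not attempt spike-rate deconvolution.

**Network events (GDPs).** A transient is GDP-related if some 500-ms interval
containing it has at least 20% of all recorded cells active (≥ 1 onset inside
the interval, boundary inclusive — exactly 20% qualifies). Because cell
activity changes only at onsets, it suffices to examine windows whose right
edge lies on an onset; the implementation does exactly that, and the test
suite proves equivalence with a brute-force search over every candidate
interval on random rasters. GDP-related transients are chained into one GDP
whenever a pair shares a qualifying interval (union-find over pairs closer
than one window); a GDP spans its first to last member onset. Cells with
masked frames stay in the denominator — the fraction refers to all recorded
cells.

## Current-clamp features

- **RMP**: median of Vm per consecutive 20-s interval at zero holding current;
  test-pulse epochs plus a 100-ms recovery margin are excised first, since a
  −10 pA pulse would bias the median by a known amount. The summary is the
  mean of the interval medians inside a caller-chosen window. Medians make the
  estimate robust to spike-like artifacts (1% contaminated samples shift it by
  nothing, which a test asserts via order statistics).
- **Rm**: ΔV/I per test pulse, with ΔV the mean over the final 100 ms of the
  500-ms pulse minus the mean over the 100 ms before it. mV/pA × 1000 = MΩ.
  A pulse whose mid-pulse deflection differs from the final one by more than
  5% is flagged as not having reached steady state (relevant when τ = RC
  approaches the pulse duration).
- **AP onsets**: the first derivative of Vm (central difference × sampling
  rate) is smoothed with a second-order, 5-sample Savitzky–Golay filter; an
  onset is the first sample where the smoothed derivative is ≥ 20 V/s
  (inclusive), with hysteresis re-arming below half the threshold.
- **Excitability**: per 500-ms current-step series — AP threshold is Vm at the
  onset of the first AP at the lowest spiking amplitude; rheobase that
  amplitude; maximum mean rate the largest per-step count divided by the step
  duration; maximum instantaneous rate the inverse minimal inter-spike
  interval. Metrics aggregate across the three series by the mean, except
  rheobase, which uses the median. Undefined metrics are NaN (never 0) and
  drop out of aggregation.

## Synaptic currents

**Minis.** The trace is baseline-corrected (interpolated 0.5-s block medians),
sign-flipped so inward events are positive, and matched-filtered with the
bi-exponential template (rise 1.5 ms, decay 6 ms); the kernel is scaled by
1/‖template‖² so the filter is amplitude-preserving at alignment while
attenuating white noise by ‖template‖. Candidate peaks must exceed the
amplitude threshold (default 5 robust SDs of the filtered trace) *and* carry
an integrated charge of at least `amp_threshold × τ_decay/2` pA·ms — the
classic dual amplitude/area criterion of semi-automatic mini analysis. On
pure noise the false-positive rate measured over 300 synthetic minutes is
≈ 0.003 min⁻¹.

**Evoked paired-pulse trials.** Amplitudes are peak inward deflections of the
matched-filtered trace inside a 3–20 ms post-stimulus window (the first 2 ms
are blanked for the stimulus artifact); pulse 1 is measured against the
pre-stimulus median, pulse 2 against the 5 ms immediately before its own
stimulus so the decay of response 1 cannot contaminate it. A pulse is a
success when its amplitude exceeds max(k·σ_noise, 1 pA), k = 3 by default;
the absolute floor keeps the rule meaningful in the noiseless limit where
k·σ would be zero. The amplitude correction subtracts, per pulse, the mean
amplitude measured on failure trials from every trial of the condition —
failures estimate the residual contamination (artifact tail plus noise
rectification) in the measurement window. The per-cell mean is reported over
all trials (failures ≈ 0 after correction); a successes-only mean is also
exposed.

## LFP pipeline

**Preprocessing.** Polyphase anti-alias decimation to 500 Hz (stopband
attenuation > 40 dB above the target Nyquist, verified on a 300-Hz tone),
then subtraction of a centered 1-s rolling median, which removes DC and slow
drift while passing 10-Hz content within 5%. Artifact intervals become NaN
and are excised from spectra and subtracted from analyzed durations.

**Noise-normalized bandpower.** Welch PSD (6-s windows, 20% overlap),
integrated over 8–40 Hz, divided by the identical estimate on the electrode's
technical-noise reference (≥ 5 min recorded with the same gain). A value of 1
is the noise floor; the ratio is invariant to any common gain. Timecourses
use non-overlapping 5-min intervals; intervals more than half masked are NaN.

**Spectrogram.** Multitaper with 3 DPSS tapers (NW = 2), 1-s windows stepped
by 0.2 s, 3–100 Hz: a 60-s trace yields ⌊(60−1)/0.2⌋+1 = 296 columns.

**eSPW detection.** Candidates are deflection peaks exceeding 0.05 mV in the
configured polarity (default negative — recorded polarity depends on
electrode depth relative to the reversal) separated by ≥ 200 ms; a candidate
is accepted when the 15–30 Hz spectrogram power within ±0.3 s is at least 3
robust z-scores (median/MAD over a 10-s local baseline) above baseline.
No pre-smoothing is applied to the amplitude trace.

**Burst detection.** The 4–15 Hz band-integrated multitaper power (1-s
windows, 0.05-s steps) is compared against an activity-dependent threshold:
moving median over 120 s plus five times the moving MAD over 360 s, both
centered with shrinking windows at the edges, the MAD taken raw (no
normal-consistency factor). Supra-threshold runs separated by < 200 ms merge.
Because a 1-s analysis window smears an event's power over nearly a window
length on either side, run boundaries are refined on a second power series
with a 0.25-s window (gain-calibrated to the 1-s series by their medians and
held to its own moving median + 5·MAD floor), and the refined time above
threshold is corrected by the residual fine-window support (window − step).
The corrected duration can exceed the true event duration by at most one step,
so the 600-ms minimum-duration criterion tests event length rather than
spectrogram smear: a salient 0.4-s burst is always rejected, a 1-s burst
accepted. The 4–15 Hz band is a fixed default; any per-animal refinement is a
configuration override, not an automatic procedure. On event-free synthetic
recordings the false-positive rate is < 0.01 min⁻¹ and the adaptive threshold
keeps it stable when the background power doubles.

## Statistics layer

`paired_t` is the standard two-tailed paired t-test (error on zero-variance
differences). `holm_bonferroni` is the step-down adjustment implemented
directly (sorted p × (m−i), running maximum, clipped at 1) and cross-checked
against statsmodels in the test suite. `contrast_report` follows the gating
rule of factorial silencing designs: per-group simple contrasts are computed
(and Holm-adjusted, with ∗/∗∗/∗∗∗ at 0.05/0.01/0.001) only when the
condition × group interaction is significant. The interaction stage is either
a Welch two-sample t-test on within-subject differences (reduced mode) or the
Wald test of the interaction term in a random-intercept linear mixed model
fitted by statsmodels (mode "mixed"); full GLMM families beyond the normal
case are intentionally delegated and out of scope. On 10⁴ null simulations
the reduced pipeline's family-wise type-I error stays at the nominal 0.05
(asserted with a three-standard-error Monte-Carlo margin).

## Synthetic-data generator

The generator's role is to plant events with known times, amplitudes, and
rates in realistic noise so that every detector can be scored against ground
truth. Defaults encode the study conditions the package targets: 8-min,
20-cell imaging blocks at 10 Hz with transients at 1.4 min⁻¹; 20-kHz
current-clamp recordings with −10 pA/500-ms test pulses every 20 s around a
−61.3 mV resting potential and 154.5 MΩ input resistance; mEPSCs at
0.13 min⁻¹ (lognormal amplitudes, median 20 pA); 30 paired-pulse trials with
25% failures and 46.5 pA successes (the failure-corrected mean is then
46.5 × 22/30 = 34.1 pA by construction); 30-min LFP sessions at 20 kHz with
eSPWs at 2.1 min⁻¹ or theta-beta bursts at 4.0 min⁻¹, plus a 5-min noise
reference. Key modelling choices:

- **Event trains** are renewal processes with a hard dead time
  (gap = dead + Exp(mean − dead)), which enforces non-overlapping event
  supports without biasing the realized rate; counts stay inside Poisson
  99% intervals. Every event class draws from its own seeded substream, so
  per-class ground truth is independent; identical config + seed is
  bit-identical.
- **Membrane model**: a single-compartment leaky integrator advanced with the
  exact exponential update per constant-current segment, so the noise-free
  step response matches the closed form to machine precision. Spikes are
  integrate-and-fire crossings (threshold −45 mV, putting rheobase ≈ 110 pA
  inside the default 0–120 pA step family) stamped with a 2-ms biphasic
  template whose peak dV/dt ≈ 120 V/s — far above the 20 V/s detection
  criterion. Measurement noise is additive white Gaussian on the voltage.
- **LFP background** is 1/f pink noise with RMS 0.02 mV. With the default
  0.2-mV sharp waves this is a peak SNR of 10; a noisier background would put
  the fixed 0.05-mV amplitude criterion *inside* the noise distribution,
  which is inconsistent with using a fixed threshold at all. Sharp waves are
  Gaussian monophasic deflections (width 150 ms) with a superimposed 22-Hz
  ripple at half the deflection amplitude; bursts are 8-Hz carriers under a
  Tukey(0.25) envelope (sustained amplitude with brief ramps, so the planted
  duration is well-defined), 0.8–2 s long. The reference channel shares the
  noise process but carries no events.
- **Evoked failures** are Bernoulli per pulse, or an exactly planted count
  (permuted across trials) for noiseless worked examples. The stimulus
  artifact is a 200-pA spike with a 0.3-ms tail, negligible by the start of
  the 3-ms response window.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: correlated (pink) noise in patch-clamp traces, mini
kinetics variability, electrode drift beyond a slow sinusoid, movement or
chewing artifacts, non-stationary event rates within a session, and any
pixel-level imaging structure (traces are generated directly, not from
movies). Detector performance numbers quoted here are properties of these
synthetic conditions, not of any particular rig.

## Problem sizes used in the test suite

Rate-recovery checks average a few independent simulated preparations, as
printed population means do: five 8-min slices (Ca²⁺), ten 60-min cells
(minis, pooled), four/three 30-min sessions (eSPWs/bursts, generated at 5 kHz
source rate; the dedicated decimation tests use 20 kHz). Null false-positive
studies use 25–100 short seeds. These sizes keep the full suite to a few
minutes while leaving the statistical margins quoted above.

## Known limitations

- The UFARSA-style spike reconstruction, image registration and ROI drawing
  of upstream imaging pipelines are out of scope; the transient detector is a
  documented threshold stand-in.
- The burst band refinement is configuration, not inference; the duration
  estimate slightly underestimates tapered events (≈ −0.15 s at the default
  envelope).
- The mixed-model mode covers the normal/identity case only; gamma/log-link
  model families should be fitted in a dedicated statistics environment.
- eSPW and burst detection assume the artifact mask has already removed gross
  artifacts; no automatic artifact detection is attempted.
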