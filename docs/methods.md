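# Methods

This note documents the models and estimators implemented in `rsnalab`, the
assumptions behind the synthetic cohort generator, the defaults that matter
and why they were chosen, and what the validation studies do and do not
demonstrate about real recordings.

## Analysis chain

**Rectification and integration.** The raw bipolar nerve signal is full-wave
rectified after removal of a slowly varying DC estimate (sliding mean,
default window 1 s, emulating AC coupling; an explicit DC value can be
supplied instead). Integration uses the rectangular rule (sum × sample
period) over half-open bins anchored at the trace start, with a trailing
partial bin dropped. Rectangular integration matches an analog
integrate-and-dump stage and makes "sum of bins = integral of window" an
exact identity, which the tests exploit. The burst-analysis series uses
100-ms bins; per-beat reflex quantities use 0.5-s windows triggered by the
systolic peak (0.4 s, the usual online-display period, is available via
`trigger_window_s`; the two conventions coexist in the literature and the
choice is recorded in outputs).

**Background correction and normalization.** The residual electrical output
(the signal that survives nerve blockade) is treated as a constant additive
level in the rectified domain: each bin loses `background_uv × bin_width`,
clipped at zero (the handling of negative corrected values is otherwise
undefined). Absolute microvolt levels depend on the electrode and nerve
preparation and are not comparable across animals, so all reflex analyses
express activity in percent of the subject's own control-window mean — a
60-s window ending at the first intervention (length configurable; at least
30 s is enforced). A control window that averages exactly 100 % is asserted
by the tests.

**Systolic peak detection.** The pressure channel is detrended by its
moving median (3-s window, mirror-padded, computed on a decimated grid for
speed) and local maxima of the detrended signal exceeding a fraction
(default 0.4) of the moving pulse range are taken as systoles, with an
80-ms refractory period (rat HR rarely exceeds 500 bpm ⇒ ≥120-ms cycles).
Detrending first matters: during a diltiazem bolus pressure falls ~9 mmHg/s
and a threshold anchored to the raw signal lags the drop and misses beats.
The 0.4 fraction sits between the systolic excursion (+0.7 pulse pressure
above the median for the simulated pulse shape) and diastole (−0.3), with
margin for the range inflation that rapid trends cause in the moving
max−min. Instantaneous HR must stay within 100–700 bpm (guard band);
detection on noise-free simulated pressure matches the generator's beat
times within one sample.

**Per-beat quantities.** Per-beat MBP is the time average of pressure over
`[peak_i, peak_{i+1})` (so the IBI-weighted mean of per-beat MBP equals the
trace time-average exactly); instantaneous HR is 60/IBI; per-beat RSNA is
the rectified integral over `[peak_i, peak_i + window)` with beats whose
window overruns the trace dropped.

**RSNA–HR coupling.** The classifier computes Pearson correlations between
per-beat RSNA and instantaneous HR at integer beat lags in ±10 beats and
takes the value of largest magnitude (ties: smaller |lag|, then the
negative lag). |r| ≥ 0.3 classifies coupling as *intact*, else *altered*.
Both the metric and the threshold are an operationalization of a judgement
that is traditionally made by eye on the beat-triggered display; they are
deliberately simple, configurable, and echoed in every output so a reader
can recalibrate. At the default threshold, 500 beats of independent noise
classify as altered with probability > 0.99 (the null |r| is ≈ 0.045 · 2.5
under the lag scan), while simulated phase-locked subjects score r ≈ 0.4–0.9
depending on window length.

**Baroreflex curve.** Paired per-beat (MBP, RSNA%) samples from the
diltiazem injection to the end of the recording are assigned to half-open
5-mmHg bins anchored at absolute multiples of 5 mmHg (anchoring makes bins
commensurable across subjects); per-subject bin means and SEMs come first,
then the group curve is the unweighted mean of subject bin means with SEM
across subjects, dropping bins present in fewer than two subjects. A curve
must occupy at least 6 bins.

**Slope.** Ordinary least squares on bin centers vs bin means over the
10–90 % band of the curve's RSNA range, requiring at least 4 qualifying
bins and a transition of at least 20 % of the curve top. Reported in % of
control per mmHg (negative = sympathoinhibition). A four-parameter logistic
fit (`fit_logistic_curve`) is provided as a cross-check, not as the primary
estimator: the OLS band slope is insensitive to plateau misspecification on
curves that never reach one plateau.

**Plateau pressure.** No standard estimator exists for "the pressure at
which RSNA reaches its lower plateau", so the one implemented here is
declared in every output. On the median-filtered curve (3-point median:
unbiased on monotone segments), restricted to bins supported by at least
half the median bin count (sweep extremes are erratic), the plateau floor
is the median over the top quartile of the pressure span; the plateau onset
is the lowest-pressure bin from which every higher-pressure bin stays
within 5 % of the curve range above that floor, the run must span ≥ 2 bins,
and a run falling faster than the tolerance per four bins counts as a
continuing descent (no plateau). Two robustness choices deserve note: the
floor is a median rather than the curve minimum because with ~20 plateau
bins the minimum is biased low by about two bin-noise standard deviations,
which systematically delays (or destroys) the detected onset; and the
tolerance is expressed as a fraction of the curve range, which makes the
estimator invariant to the arbitrary %-of-control scale and lets it be
checked against the closed-form sigmoid inversion
p₅₀ + k·ln((1−f)/f) with f = 0.05.

**Drug responses.** Baseline = mean over 60 s pre-event; the response
extremum is taken on a 5-s centered moving average within an agent-specific
search window (120 s diltiazem, 150 s phenylephrine, 60 s CPBG); deltas are
extremum − baseline, signed. The 5-s smoothing suppresses beat-to-beat
noise without masking the CPBG transient (sub-second onset, tens of
seconds recovery). Bezold–Jarisch inhibition is the minimum smoothed RSNA%
minus 100 (−100 = complete silence); subjects whose activity never falls
below control are reported ≥ 0 and flagged `non_responder`.

**Statistics.** One-way ANOVA with Tukey's HSD (scipy/statsmodels), with
unadjusted pooled-variance pairwise p-values reported alongside for
reference; two-way ANOVA of subject-level bin means on pressure bin ×
group over the bins shared by all groups (type II, interaction included).
Treating subject bin means as independent observations ignores the
repeated-measures structure across bins within a subject; this
simplification is stated in the report output and makes the pressure main
effect anti-conservative, so it should be read as descriptive. Dispersion
is reported as SEM throughout. α = 0.05.

## Synthetic cohort generator

The generator produces the study conditions for all validation: it is not
fitted to data but parameterized to the published phenotypes.

**Pressure.** MBP(t) = basal level + intervention kernels +
Ornstein–Uhlenbeck wander (SD 2 mmHg, correlation time 2 s — the slow
hemodynamic variability under barbiturate anesthesia that drives basal
RSNA/HR covariation). The intra-beat pulse is a squared-sine upstroke
occupying 60 % of the cycle (peak at 30 %), scaled so max−min equals the
preset pulse pressure and zero-mean so the time average equals MBP. Beat
periods integrate a linear HR baroreflex: HR = basal + gain ×
(delayed MBP − basal), with the gain attenuated to 15 % below basal MBP
(baroreflex tachycardia is largely saturated under pentobarbital —
visible in the published diltiazem HR responses, which are an order of
magnitude smaller per mmHg than the phenylephrine bradycardia), plus a
direct vagal kernel for CPBG. Baroreflex latency defaults to 0.3 s
(mammalian sympathetic baroreflex range; configurable).

**Nerve signal.** Per-beat burst amplitude follows the inverse logistic of
delayed MBP. Bursts are 80-ms raised-cosine envelopes starting 20 ms after
the systolic peak (sympathetic bursts are diastolic), riding on a constant
tonic activity level, plus a constant residual background; the sum
modulates a zero-mean band-limited noise carrier (30 Hz to 1 kHz or the
available band below Nyquist) normalized to unit mean absolute value, so
the expected rectified signal equals the envelope. A deterministic ±1
carrier is available for analytic checks (rectification then recovers the
envelope exactly). Per-beat amplitude noise is Gaussian (preset SD),
clipped at zero.

The burst component is modeled as fully baroreflex-gated (small sigmoid
floors, 5–8 %), with each phenotype's non-suppressible activity carried by
the tonic level instead. This is a deliberate decomposition: bursts are
cardiac-locked, so any baroreflex-independent burst floor makes
window-cumulated RSNA track heart rate (bursts per fixed window ∝ HR),
i.e. the measured curve would keep creeping down during phenylephrine
bradycardia and have no true plateau. The residual (~1 % of range) rate
confound is within the plateau tolerance. The same rate confound is why
the Bezold–Jarisch kernel-recovery study programs an inhibition-only CPBG
event: with the full kernel, the concurrent bradycardia deepens measured
%RSNA beyond the programmed inhibition — a real property of cumulated
multiunit recordings, not an analysis error.

**Cardiac decoupling.** `coupling_jitter` ∈ [0, 1] degrades coupling two
ways: burst onsets are jittered uniformly within ± 0.45 of the cycle, and
the wander component feeding the amplitude sigmoid is mixed with an
independent surrogate wander in proportion to the jitter. The second
mechanism is what matters quantitatively: a 0.5-s cumulation window spans
~3.5 rat cardiac cycles, so timing jitter alone barely changes per-window
integrals. Deterministic kernels (drug effects) are never decoupled, so
even fully decoupled subjects retain their pharmacological baroreflex
sweep — mirroring the severe phenotype, whose curve is flattened but
present while its beat-to-beat coupling is lost.

**Central sympathoinhibition (CPBG).** The 5-HT3 agonist kernel rises with
a 0.2-s time constant, holds ~8 s, and recovers with a 30-s time constant.
During the transient the burst amplitude is pinned toward
(1 − depth) × its basal value rather than multiplied by (1 − depth): a
multiplicative factor would let the concurrent hypotension disinhibit RSNA
through the sigmoid and invert the reflex's phenomenology (central
inhibition overrides the afferent drive). Dose anchors (1/3/20 µg/kg →
depth 0.60/0.70/0.78, hypotension 19/30/49 mmHg, bradycardia 49/107/257
bpm) interpolate on log dose and are overridable per event.

**Intervention kernels.** Diltiazem: exponential approach to a nadir at
30 s (preset magnitudes 77/89/96 mmHg for WKY/SHR/SHRLN) with 45-s
recovery; phenylephrine: 1 mmHg/s ramp to a preset ceiling (69/79/81 mmHg)
held to the end of the recording; all parameters exposed on
`InterventionSpec.kinetics`.

**Phenotype presets.** Control-state anchors: WKY 126 mmHg / 437 bpm, SHR
142 / 374, SHRLN 156 / 355; sigmoid half-points 110 / 113 / 135 mmHg with
steepness 8 / 7 / 10 mmHg and ranges shrinking with severity; HR gains
−1.55 / −1.16 / −0.32 bpm/mmHg (the published phenylephrine bradycardias
divided by their pressure rises); coupling jitter 0.05 / 0.10 / 0.85
(coupling preserved, preserved, lost); tonic level rising and burst scale
falling with severity (0.10 → 0.60 µV tonic), reproducing the reduced
max/mean and raised min/mean burst ratios. These are calibration anchors
for a plausible testbed, not estimates of ground truth. Burst shape, rate
and noise levels have no published quantitative description; all are free
parameters with the defaults above.

**Randomness.** One master seed per subject; every stochastic component
(wander, surrogate wander, amplitude noise, timing jitter, carriers) draws
from its own counter-derived stream, so runs are bit-reproducible and
cohort generation derives per-subject seeds deterministically from the
cohort seed.

## Validation studies and their scope

`rsnalab.studies` runs replicated desk-scale analogs of the animal
experiments, always through the full analysis path (peak detection onward;
generator ground truth is only ever used as the comparison target):

- *Plateau displacement*: 20 replicate cohorts, 10 subjects per phenotype,
  standard baroreflex protocol at 1 kHz (≈250–260 s per subject). Median
  absolute error of the group plateau vs the analytic sigmoid inversion is
  ≈4 mmHg (WKY-like) and ≈3 mmHg (SHRLN-like); the between-group
  displacement (analytically 30.9 mmHg for the default presets) exceeds
  15 mmHg in 20/20 replicates.
- *Slope ordering*: |group slope| of the severe phenotype is below the
  normotensive one in 20/20 replicates (≈ −0.9 vs ≈ −10.8 %/mmHg).
- *Coupling*: 180-s basal recordings; phase-locked cohorts classify intact
  10/10 and decoupled (jitter 0.85) cohorts altered 10/10 at the default
  threshold.

These cohort sizes and durations were chosen to estimate the group-level
quantities with comfortable margins while keeping a full validation run
within about half a minute.

Passing these studies shows that the estimators recover what the generator
encodes at realistic signal-to-noise, sampling and protocol scales. It does
not certify performance on real recordings: the generator has no
respiratory or Mayer-wave rhythms, no movement or stimulation artifacts, no
electrode drift, stationary noise statistics, a strictly logistic static
baroreflex (no hysteresis or resetting within the sweep), and its burst
morphology is a single stereotyped envelope rather than a population of
units. Artifact rejection and spectral/coherence analyses are out of scope.

## Numerical and degenerate-input conventions

Bins are half-open `[t, t + Δ)`; a pressure value on a 5-mmHg edge belongs
to the upper bin; trailing partial bins are dropped. Background correction
clips at zero and refuses to run twice. Percent-of-control requires a
positive control mean and ≥ 30 s of control. Peak detection requires ≥ 5 s
of signal and ≥ 3 peaks (else a flat-signal error); constant series raise
degenerate-series errors in correlation and burst ratios; curves with < 6
occupied bins, < 4 transition bins, or no terminal flat run raise typed
errors (`InsufficientRangeError`, `NoPlateauError`). Correlation lag ties
prefer the smaller |lag|, then the negative lag. All errors derive from
`RsnaError`.
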