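# Methods

`dualtask` simulates and analyzes a dual-task working-memory (WM)
interference experiment: participants hold temporal or spatial
information about auditory or visual stimulus sequences in WM while, on
some trials, performing an auditory perceptual judgment (the
"Intervening" task) during retention. The package implements both the
generative side (design, stimuli, behavior, pupil, EEG) and the analysis
side (pupil cleaning and averaging, paired sign-flip permutation tests,
ERP/P2 extraction with a repeated-measures ANOVA, Morlet time-frequency
analysis of alpha oscillations, and logistic mixed-effects behavioral
models). This note records the models, the parameters that matter, and
the design choices made where the design was genuinely open.

## Time convention

Trial-relative time is in seconds, zero at the offset of the final WM
encoding stimulus. The baseline window is the 1.5 s before encoding
onset; retention spans [0, 5.5) s; the Intervening sequence starts at
+2.0 s; the probe sequence starts at +5.5 s.

## Experiment generator

**Design.** The 12 condition cells are WM modality {auditory, visual} x
WM domain {temporal, spatial} x Intervening {none, AT, AS}. Trials come
in blocks of 20 (half "same", half "different", randomly ordered) with a
single cell per block; each session (one WM modality) cycles through its
6 cells in random order, once per cycle, with no cell repeated in
adjacent blocks (rejection-resampled, bounded retries); 40 trials per
cell by default (2 cycles). Session order is randomized per participant.

**Stimuli.** WM sequences have 4 stimuli of 50 ms and 3 inter-stimulus
intervals labelled short/long — auditory {200, 340} ms, visual
{200, 580} ms; intervals are offset-to-onset gaps. The first stimulus
location is fixed (central loudspeaker of 5 azimuths / top-center of 12
circular patches). Auditory-spatial WM sequences are isochronous at the
long interval. On "different" trials the attended domain is resampled
until it differs; the unattended domain changes with probability 0.5
(configurable; the probability and magnitude of unattended changes are
free parameters of the original design that were never printed).
Intervening sequences have 3 bursts with one interval drawn uniformly in
370 +- 60 ms and the other in 550 +- 60 ms (independent, order random) —
uniform jitter is bounded, mean-preserving (180 ms expected difference),
and keeps the short/long ranges disjoint so the correct answer is always
decidable. Locations follow an A-B-A pattern over the -4 deg / 0 deg
loudspeakers with the first side equiprobable.

**Behavior.** A logistic observer: per-trial error probability is
`sigmoid(eta)` with `eta` = a fixed log-odds per condition cell plus a
participant random intercept and independent random slopes on the
modality/domain/Intervening indicators (SDs configurable, defaults 0.3
and 0.15 in the "study-like" observer). The study-like cell log-odds
encode the reported interference pattern: lower error in the
modality-domain-matched WM cells (AT, VS), extra WM errors when an
Intervening task runs during auditory-temporal WM, and extra Intervening
errors when WM holds auditory (especially matching-domain) information.
These effect sizes are package choices — the original trial-level data
are not an input.

**Pupil.** Trace = baseline level + dilations + anticipatory ramp +
Gaussian sample noise, at 500 Hz from baseline start to one sample
before probe onset. The dilation impulse response is a gamma kernel
(shape 8, mode 0.7 s, peak normalized to 1) — the mode matches the
observed post-encoding peak latency. The encoding dilation is driven by
a single event at encoding offset, i.e. the moment the WM load is
complete, so the simulated trace peaks 0.7 s after encoding offset as
observed; the Intervening dilation is driven by the three burst onsets.
Blinks are dropouts to zero with steep 8 ms linear flanks (mimicking
eyetracker loss of the pupil), Poisson-arriving at 0.15/s with uniform
durations 0.1–0.3 s by default; the ground-truth occlusion mask is kept
for validation.

**EEG.** Channels are a 15-electrode 10-20 subset plus two mastoids.
Signal = (a) Gaussian-bump ERP components N1 (100 ms, -4 uV), P2
(205 ms, +5 uV, scaled per cell), P3 (320 ms, +2.5 uV) inserted at every
stimulus onset with fronto-central (N1/P2) or parietal (P3)
topographies; (b) a participant-specific alpha sinusoid (integer 8–12
Hz) with random phase per trial, strongest at Pz, and a phase-wise
envelope (auditory WM: elevated in retention, suppressed while the
Intervening task runs; visual WM: suppressed at encoding, rising in
retention); (c) 1/f noise (5 uV per channel by default, reduced on the
mastoids); (d) occasional 160 uV artifacts at a configurable per-epoch
rate. The study-like P2 gains encode the reported effects: smaller P2 to
Intervening onsets under auditory WM (modality main effect) and under
domain-matched WM (domain x Intervening interaction). EEG is synthesized
at 256 Hz by default; a 2048 Hz mode exercises the downsampler.

All generators draw from a single top-level seed through
`numpy.random.SeedSequence` spawning, so every sub-stream is
reproducible.

## Pupil pipeline

Blink detection thresholds the absolute value, first difference and
second difference of the trace. Defaults are data-driven: velocity and
acceleration limits are 10x the median absolute first/second difference
(per second / per second squared), position bounds are median +- 5 MAD.
Each robust scale is floored at a small fraction of the trace's typical
level (5% of the median for the MAD, 0.1% per sample for the
difference scales) so that near-noise-free recordings do not collapse
the thresholds to zero. Detected events are padded by 10 samples
(20 ms) per side and merged. A machine-readable extra mask replaces the
original pipeline's manual review.

Interior masked segments are replaced by the line joining the mean of
the 3 clean samples before to the mean of the 3 after; segments touching
a window edge are filled by projecting a least-squares line fit to the 5
adjacent clean samples. Traces whose segments lack those anchors are
flagged unrecoverable. Trials with more than 25% masked samples
(strictly) are rejected. Eyes are averaged when both are present. All of
a participant's kept trials are concatenated, z-scored with the
population SD (the concatenation is the normalization population), and
split back — so only relative diameter is interpreted, and the output is
invariant to positive affine rescaling of the raw signal.

Known limitation (quantified by the acceptance suite): linear
interpolation across a blink that straddles a dilation peak has an
irreducible chord error of about |f''| L^2 / 8 for masked span L; with
the default kernel and 0.3 s blinks this can reach ~10–20% of the peak
amplitude on a worst-case trace, while the median reconstruction error
on noise-free traces is orders of magnitude smaller.

## Permutation tests

Contrasts are paired across participants; the exchange scheme flips each
participant's condition labels independently (sign-flip of the paired
difference), preserving the within-participant pairing. The pointwise
statistic is the paired t; zero-variance points map to signed infinity
(never NaN). P-values are two-sided on |T| with add-one smoothing,
`p = (#{|T_null| >= |T_obs|} + 1) / (n_iter + 1)`; ties are counted with
a 1e-12 relative slack so that the identity permutation always counts.
An exact mode enumerates all 2^n sign patterns (used as its own oracle
for n <= 10). Two significance criteria are provided: maximal runs of
p < 0.05 lasting >= 15 consecutive samples (pupil traces; reported in
seconds), and the window-restricted pointwise 95th-percentile rule
(alpha time courses; half-open windows [2, 3.5) and [3.5, 5) s). Note
the run-length criterion only suppresses familywise error when the noise
correlation length is shorter than the run length; with very smooth
noise a pointwise false positive persists long enough to qualify as a
run.

## ERP pipeline

Preprocessing: polyphase downsampling to 256 Hz, re-referencing to the
mastoid average, and a zero-phase FIR band-pass 0.5–20 Hz (MNE firwin
design; 0.2 Hz lower transition width as printed, 2 Hz upper transition
as a package choice — the printed filter order pins down only the
aggregate design). Ocular ICA is a pluggable hook defaulting to a no-op:
the generator produces no ocular components and an external
decomposition can be injected. Epochs span -100..500 ms; any channel
exceeding 100 uV peak-to-peak — strictly — rejects the epoch; survivors
are baseline-corrected to the mean of [-100, 0) ms. P2 amplitude is the
mean over 190–220 ms and channels {Fz, FCz, Cz, FC1, FC2} of the
participant-average ERP to Intervening-onset (position 1) stimuli.

The three-way repeated-measures ANOVA (WM modality x WM domain x
Intervening domain) is computed from the full factorial sum-of-squares
decomposition with subject as the blocking factor; each effect is tested
against its interaction with subject. Both classical eta-squared
(SS_effect / SS_total) and generalized eta-squared
(SS_effect / (SS_effect + all subject-involving SS)) are reported, since
the eta-squared variant used originally is not identifiable from the
printed values. Follow-up ANOVAs restricted to one WM modality use a
Bonferroni-style criterion alpha / (n_followups + 1) (0.05 / 3 ≈ 0.017).

## Time-frequency pipeline

Phase/condition/position-matched average ERPs can be subtracted from the
continuous data at each stimulus timestamp before the transform (plain
average subtraction, as described operationally; a regression variant is
out of scope). Signals are mirror-padded with time-reversed copies of
their first and last 5 s. The Morlet wavelet has a fixed 5-cycle
Gaussian envelope at every frequency (sigma_t = 5 / (2 pi f)), +-5 sigma
support, envelope normalized to unit sum (a unit sinusoid yields power
1/4; all dB quantities are normalization-free). Power is expressed as
10 log10(P / P_baseline) with the baseline power per frequency averaged
over the 1.5 s pre-trial window across *all* of a participant's
conditions, so permuting condition labels cannot change the baseline.

The individual alpha frequency (IAF) is the integer frequency in 8–12 Hz
with the largest absolute mean dB change at Pz over the retention window
trimmed by 500 ms at each edge; ties break toward the lower frequency.
The alpha time course is the mean dB power over {IAF-1, IAF, IAF+1} Hz.
Condition contrasts ({none vs AT, none vs AS, AT vs AS}, WM-domain
collapsed, per WM modality) use the windowed percentile permutation
test. A 5-cycle wavelet has a ~2 Hz spectral SD, so the dB-change
spectrum forms a broad plateau around the true oscillation frequency
when baseline alpha is present at the same frequency; the IAF argmax is
then resolved by the 1/f noise floor shaping, which is why IAF recovery
is validated on trial-averaged power with a realistic noise floor rather
than on single noiseless trials.

## Behavioral models

Two logistic mixed-effects models: Intervening errors ~ WMCondition
(4 levels) x Intervening domain (2), and WM errors ~ WM modality x WM
domain x Intervening condition (3), both with per-participant random
intercepts and (optionally) independent random slopes, treatment-coded
with baselines auditory / temporal / none (AT for the Intervening
model). Estimation is pluggable: the `lme4` backend calls R's `glmer`
through `Rscript` (bobyqa, independent-slope `||` terms, `nAGQ=0` — the
fast penalized-least-squares approximation, accurate at this size and
balance) and is the recommended estimator for random-slope inference;
the pure-Python `map` backend uses statsmodels' `BinomialBayesMixedGLM`
at its posterior mode with Laplace covariance (its BFGS optimizer can
terminate short of the optimum on high-dimensional random-slope
posteriors — under-optimized fits are logged and its interval coverage
for slope models is less reliable than glmer's); ordinary logistic
regression with cluster-robust (by participant) covariance serves as
the no-random-effects backend and the final fallback, with every
fallback logged. Omnibus tests per model term are
Wald chi-square statistics on the coefficient blocks — the chi-square
scale matches how the original omnibus results are reported; Satterthwaite
denominator-df corrections are specific to linear mixed models and have
no exact analogue here. Pairwise simple effects are read off by cycling
the treatment-coding baselines (each refit cached; each needed pair
extracted exactly once: the within-cell Intervening contrasts for the WM
model, the within-task WM-condition contrasts for the Intervening
model), and flagged by Holm-Bonferroni step-down at familywise 0.05.
Random-slope fits are the calibrated choice for interval coverage:
intercept-only fits under slope heterogeneity underestimate the simple
effect SEs.

## Problem sizes and validation scope

The test suite validates at desk scale: 1–21 simulated participants,
4–40 trials per cell, 500-sample to 100-time-point permutation grids,
50-replicate calibration and recovery loops. The synthetic data emulate
the statistical structure the pipelines assume — condition-scaled
effects, participant heterogeneity, blinks, 1/f noise, artifacts — but
not ocular EEG artifacts, eyetracker calibration drift, luminance
effects on pupil size, or non-stationary alpha dynamics; passing tests
demonstrate correctness of the pipeline computations and recoverability
of injected effects, not claims about any real recording. The original
study's headline test statistics depend on the unavailable raw
recordings and are deliberately not reproduced.
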