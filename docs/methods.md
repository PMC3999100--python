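# Methods

This note documents the models behind `ctxstop`, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical choices a user extending the package should know about.  No
empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Task design

A session consists of 1152 trials, 384 per context, each context holding
236 go, 48 Stim1 and 100 Stim2 trials (61% / 13% / 26% overall).  A deviant
is a stop signal in context 1 (both deviants), context 2 (Stim1 only) or
context 3 (Stim2 only); 296 trials are therefore stop-relevant and 148 are
stop-irrelevant deviants.  Same-context trials are presented in runs of
13–18; run lengths are drawn uniformly from {13..18} with the remainder
folded into the final run (rejection-sampled so every run stays in range),
and runs are ordered by a seeded greedy scheduler that forbids two
consecutive runs of the same context.  Counts are deterministic under every
seed; only ordering is randomised.

Trial onsets accumulate the 100 ms stimulus presentation, a base
inter-trial interval, and an integer-millisecond jitter uniform on
[0, 2000] ms (uniform because only the range is constrained; a flat jitter
maximises the temporal sampling of the hemodynamic response, its purpose).
The 1350 ms response window is *not* part of the onset increment: responses
run on into the inter-trial fixation period, as they do in the real task.
With the default base ITI of 1088 ms the expected session is ≈ 42 min
(feedback screens and rest pauses are not modelled).  Stimulus identities
(colours/forms) and their counterbalancing are abstracted to
GO/STIM1/STIM2 labels.

Note one bookkeeping subtlety: 296 stop-relevant trials are 25.7% of the
session; all 444 deviants together are 39%.  Summaries therefore
distinguish "stop-relevant" from "deviant" throughout.

## Horse-race behavior and SOA tracking

A subject is an independent race: the go process finishes at an
ex-Gaussian time (defaults mu = 450 ms, sigma = 60 ms, tau = 120 ms) and,
on stop-relevant trials, the stop process finishes at SOA plus a
truncated-normal latency (defaults mean = 200 ms, sd = 30 ms, truncated at
0 by resampling).  A response is emitted iff the go process strictly wins;
finishing times beyond the 1350 ms window count as omissions.  Optional
parameters: trigger-failure probability (stop process never starts),
go-omission probability, per-context go-mu shifts, and an RT penalty on
stop-irrelevant deviant trials (all default 0).  Defaults were chosen to
put go RTs in the 500–700 ms range and SSRTs near 200 ms, typical of
visual stop-signal work; everything is overridable.

The SOA staircase is tracked independently per context (in context 1 both
deviants update the same tracker): +16 ms after a successful stop, −64 ms
after a failure, clamped to [64, 928] ms, initial value 128 ms.  For any
subject whose P(respond | SOA) is continuous and increasing, the
up/down-step balance pins the long-run failure rate at
16/(16+64) = 0.20; because the staircase is a negative-feedback
controller, the realised rate over N stop trials deviates from 0.20 only
by (net SOA displacement)/(80·N), i.e. well under a percentage point at
10⁴ trials.  `p_respond_given_soa` provides a quadrature oracle
(truncated-normal stop density integrated against the ex-Gaussian CDF)
used by the tests to validate the Monte-Carlo race.

## Behavioral statistics

Response rate is failed stops over all stop-relevant trials of a context.
Go RT statistics use correct pure-go trials of the same context;
stop-irrelevant deviant trials are reported separately (their RTs are
slowed in real data).  The integration-method SSRT sorts the context's go
RTs, takes position n = ⌈N·RR⌉ and subtracts the context's mean SOA.
Choices:

* **Rounding of n** — ceiling by default (a "nearest", half-to-even
  variant is available); the convention matters only at small N.
* **Go omissions** — replaced by the maximum observed RT before the
  quantile, the standard guard against omission bias; a no-op at the
  default omission rate of 0.
* **Per-context RR** — the RR entering the SSRT formula is the context's
  own, matching per-context SSRT reporting.
* **SEM** — across trials for single subjects, across subjects for cohort
  tables.

Recovery behaviour (verified in the tests): with a deterministic 200 ms
stop latency the estimator is within ±15 ms at 10⁴ trials and ±50 ms at
500 trials; the small positive bias at finite n comes from SOA variability
under tracking, a known property of the integration method.

## Synthetic EEG and ERSP features

Epochs are 250 Hz, −800 to +1212 ms around stimulus onset (504 samples),
over the 26 electrodes forming the default sites of interest
(frontocentral F1 F2 FC1 FC2 FCz Cz; centroparietal C1 C2 CP1 CP2 CPz Pz;
left/right frontal F7 F5 AF3 AF7 / F6 F4 AF4 AF8; left/right motor C5 C3
CP3 / C4 C6 CP4).  Background noise is 1/f (power ∝ f^−α, α = 1) per
channel, synthesised in the frequency domain.  An *effect* multiplies the
band-limited noise component at its EOI's channels inside its time window
by a power gain, optionally with lognormal trial-to-trial variability
(given as a dB standard deviation); per-trial injected dB are stored as
ground truth.

Time-frequency analysis is a short-time Fourier transform: Hann window of
512 ms, 20 ms hops, evaluated at the exact 100-step linear frequency grid
(0.35–35 Hz; true 0 Hz carries no oscillatory power, so the grid starts
one step up and the delta band uses bins in (0, 4]).  Direct evaluation at
grid frequencies is the infinite-zero-padding limit of a padded FFT.  Only
frames whose window lies fully inside the epoch are kept — edge frames
would mix in zero padding and bias power low — so frame centres span
−546 to +954 ms, which covers the −800..−100 ms baseline frames available
at full window coverage and every default extraction window.

dB conversion is 10·log10 of the power ratio against the across-trial mean
baseline power per channel and frequency (condition-blind).  Two
conventions coexist, differing in when the log is taken:

* **Single-trial features** divide each trial's power by the mean baseline
  and then log.  Under pure noise these centre about a small negative
  offset (Jensen's inequality applied to the log of a noisy power
  estimate, ≈ −2.5 dB for exponential single-bin power); this offset is
  constant across conditions and disappears when the features are z-scored
  as GLM modulators, their intended use.
* **Condition-averaged features** average power across the condition's
  trials *before* the log; pure noise then yields ≈ 0 dB (residual bias
  ≈ −4.34/n dB at n trials) and condition differences estimate the
  injected power ratio without bias.  All calibration and recovery checks
  use this convention.

Features are means of dB values over the band's frequency bins, the
window's frames and the EOI's electrodes (log first, then averaging over
bins and electrodes).

Two generator design choices make injected effects recoverable exactly
rather than approximately:

* **Temporal padding** — the gain is applied over the extraction window
  padded by half the analysis window (plus a 32 ms cosine ramp), so every
  frame centred inside the window sees the full gain instead of a smeared
  fraction.
* **Kernel calibration and edge guards** — the 512 ms Hann window has an
  equivalent noise bandwidth of ≈ 2.9 Hz, so a raw band gain is both
  diluted within its own band and smeared into neighbours.  The generator
  therefore (a) solves, through the known window kernel and noise
  spectrum, for the gain whose *measured* mean dB over the band's bins
  equals the requested dB, and (b) keeps the scaled region 1.5 Hz inside
  any band edge shared with another analysis band.  Residual leakage into
  adjacent bands (delta↔theta share the 4 Hz edge) stays within sampling
  noise at 200 trials/condition; bands separated by ≥ 4 Hz (theta vs the
  betas) are unaffected beyond sidelobe level.  Without these choices the
  same tests would measure ~2.3 dB for a 3 dB injection — the smearing is
  physics of the window, not an estimator defect.

What the generator does *not* emulate: scanner gradient/ballistocardiogram
artifacts, ocular or muscle artifacts, volume conduction between channels
(channels are independent), evoked (phase-locked) components, and
non-stationary background spectra.  Passing recovery tests therefore show
the *estimators* are correct, not that real-data preprocessing is solved.

## EEG-informed fMRI GLM

The canonical HRF is the double-gamma difference g(t; 6, 1) − g(t; 16, 1)/6
(peak ≈ 5 s, undershoot ≈ 16 s, 32 s support), peak-normalised to 1.
Event regressors are unit sticks on a 100 ms microtime grid convolved with
the HRF and sampled at scan times (TR = 2 s).  Parametric modulators are
z-scored across the trials of their condition (global mean-centring per
regressor), convolved the same way, then serially residualised against the
condition's unmodulated regressor, the constant, and any earlier modulators
of that condition (order delta → theta → high beta by default,
configurable).  Including the constant in the projection makes each
modulated column exactly mean-free, so its Pearson correlation with its
companion is 0 to machine precision.  A modulator that is constant across
a condition's trials is an error; one whose column carries no unique
variance after orthogonalisation (e.g. a two-event condition, where all
z-scored weight patterns coincide) is skipped with a logged warning rather
than allowed to make the design singular.  Drift is a discrete-cosine
basis with periods above 128 s; movement regressors are accepted as
optional nuisance columns but never generated.

Synthetic BOLD is y = Xβ + ε with ε a stationary AR(1) Gaussian process
(stationary sd `sigma`, lag-1 correlation `rho`, stationary start).
Fitting is OLS with optional one-step Cochrane–Orcutt prewhitening: the
AR(1) coefficient is the lag-1 autocorrelation of OLS residuals, y and X
are quasi-differenced once (first row scaled by √(1−ρ²)) and refit.  This
is a deliberately simple, testable stand-in for pooled restricted
maximum-likelihood AR modelling; its null calibration is verified by
simulation (two-sided 5% rejection of the null modulator in [0.03, 0.07]
with prewhitening at ρ = 0.4, inflated without it — which is why serial
correlations must be modelled at all).  The module operates on single time
series (or small sets of independent synthetic voxels); there is no
spatial model, smoothing, or group level.

## Pipeline

One master seed feeds a seed tree (`numpy.random.SeedSequence`) for
subjects, EEG and GLM stages; identical configs produce byte-identical
outputs (content hashes are recorded in the run log).  Default scale is a
5-subject cohort with full 1152-trial sessions for behavior, and one
subject's session (capped at 300 trials, deviants preferentially retained)
for the EEG and GLM stages — enough for stable features while keeping a
full run under ~15 s on one core.  The EEG-informed design uses
frontocentral delta and theta and left-motor high beta as the three
modulators, modelled together in one design, mirroring common practice
for this paradigm.  `validate_config` flags unpartitionable trial counts,
extraction windows outside the epoch, degenerate distributions, and
staircase step overrides (reporting the implied equilibrium rate
step_up/(step_up + step_down)).

## Known limitations

* The behavioral model assumes go/stop independence; dependent races and
  context effects beyond a go-mu shift are out of scope.
* ERSP features from adjacent bands are coupled at the scale of the
  analysis window's bandwidth; conclusions about delta vs theta at a
  shared 4 Hz edge inherit that resolution limit.
* The AR(1) prewhitener is global and one-step; strongly non-AR(1) noise
  (e.g. physiological oscillations) would need a richer noise model.
* No real-data I/O beyond events TSV and the epochs array container; no
  artifact correction, ICA, spatial preprocessing or group inference.
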