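# ctxstop

Simulation and analysis toolkit for the **contextual stop-signal task**: a
three-context variant of the stop-signal paradigm in which a frequent go
signal is occasionally followed by one of two deviant stimuli (Stim1 on 13%
of trials, Stim2 on 26%), and a context cue determines which deviant is a
stop signal (context 1: both; context 2: Stim1 only; context 3: Stim2
only).  The package is aimed at researchers who want a tested, fully
synthetic reference pipeline for this paradigm — from trial schedules and
horse-race behavior through EEG time-frequency features to EEG-informed
fMRI GLMs — with every stage's ground truth known, so estimators can be
validated by parameter recovery.

## What it implements

**Task design** (`ctxstop.task_design`) — schedules of 1152 trials (384 per
context: 236 go / 48 Stim1 / 100 Stim2), presented in same-context runs of
13–18 trials, with uniform 0–2000 ms onset jitter; BIDS-style events TSV
export.

**Behavior** (`ctxstop.race`) — the independent horse-race model: a trial's
response is emitted iff the go process (ex-Gaussian finishing time,
`mu + sigma·Z + tau·E`) beats the stop process (SOA + truncated-normal stop
latency).  The stop-signal onset asynchrony (SOA) is tracked per context by
an asymmetric staircase — +16 ms after successful inhibition, −64 ms after
a failure, clamped to [64, 928] ms from an initial 128 ms — which converges
to a stop-failure rate of `16/(16+64) = 0.20` for any subject whose
inhibition function is monotone in SOA.

**Behavioral statistics** (`ctxstop.metrics`) — per-context response rate
(failed stops / all stop trials), go RT, mean SOA, and the
integration-method stop-signal reaction time:

    SSRT = goRT(n) − mean SOA,   n = ⌈N · RR⌉

with goRT(n) the n-th fastest of the N go RTs.

**EEG / ERSP** (`ctxstop.ersp`) — synthetic stimulus-locked epochs (250 Hz,
−800 to +1212 ms) of 1/f noise with condition-dependent band-limited power
effects injected at chosen electrode sites; short-time Fourier
time-frequency power (Hann 512 ms, 20 ms hops, 100 linear frequency steps
up to 35 Hz), baseline normalisation (−800 to −100 ms) to dB, and
event-related spectral perturbation features averaged over band × window ×
electrode-site-of-interest — delta (0–4 Hz, 300–400 ms), theta (4–8 Hz,
150–250 ms), low/high beta (12–21 / 21–30 Hz, 220–500 ms) over
frontocentral, centroparietal, frontal and motor sites.

**EEG-informed fMRI GLM** (`ctxstop.glm`) — canonical double-gamma HRF,
event regressors at 100 ms microtime resolution resampled to TR = 2 s,
parametric modulators (z-scored single-trial EEG features, serially
orthogonalised against the unmodulated regressor), discrete-cosine 128 s
high-pass drift, AR(1) Cochrane–Orcutt prewhitening, and a synthetic BOLD
generator with known coupling for recovery tests.

**Pipeline** (`ctxstop.pipeline`, `ctxstop` CLI) — runs all stages from one
config and master seed and writes TSV/CSV report tables plus a JSON run log
with content hashes.

## Worked example

```bash
ctxstop run --seed 1 --out demo_out
```

or equivalently in Python:

```python
from ctxstop.pipeline import PipelineConfig, run_pipeline
run_pipeline(PipelineConfig(master_seed=1), "demo_out")
```

`demo_out/behavior_summary.csv` then holds the cohort behavioral table
(5 simulated subjects, means across subjects; values in ms unless noted):

```
                 context1_mean  context2_mean  context3_mean
GoRT                   568.343        568.476        572.045
SSRT                   226.156        219.940        213.933
RR                       0.191          0.162          0.186
mean_SOA               239.135        242.333        247.680
FailedStopRT           426.736        437.255        440.381
```

Reading the table: the staircase holds every context's response rate (RR)
near its 0.20 equilibrium; SSRT estimates sit near the simulated 200 ms
stop latency; and failed-stop RTs are ~130 ms faster than go RTs — the
race-model censoring signature (failed stops oversample fast go finishes).

`demo_out/ersp_condition.csv` holds condition-averaged ERSP features.  With
the default effect spec (stop trials: +2 dB delta / +3 dB theta
frontocentral, attenuated for Stim1 in context 2), the frontocentral
features show the configured ordering — e.g. theta: Stim1-context1 2.43 dB
vs go-context1 −0.21 dB, and Stim1-context2 1.27 dB < Stim1-context1.
`demo_out/glm_results.csv` shows the EEG-informed fit: the theta-modulated
regressors recover the configured coupling (true 0.5, e.g. estimate 0.57
for Stim1-context1) while delta and high-beta modulators stay near zero.

## Layout

```
src/ctxstop/
  task_design.py   # schedules, events TSV I/O
  race.py          # horse-race trials, staircase, sessions, cohorts
  metrics.py       # RR, goRT, integration-method SSRT, summaries
  ersp.py          # synthetic EEG, STFT power, dB baseline, EOI features
  glm.py           # HRF, parametric-modulation designs, AR(1) GLM
  pipeline.py      # orchestration, config, validation
  cli.py           # `ctxstop` command-line interface
docs/methods.md    # modelling assumptions, parameter choices, limitations
```
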