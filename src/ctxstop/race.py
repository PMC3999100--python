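"""Horse-race behavior with adaptive stop-signal delay tracking.

A subject is modelled as an independent race between a go process with
ex-Gaussian finishing times and a stop process that, on stop-relevant
trials, starts at the stop-signal onset (go onset + SOA) and finishes after
a truncated-normal latency.  A response is emitted iff the go process wins
(or the stop process fails to trigger).  The SOA is tracked per context by
an asymmetric staircase: +16 ms after a successful stop, -64 ms after a
failed one, clamped to [64, 928] ms.  Because the inhibition function
P(respond | SOA) is monotone, the staircase equilibrates where
P(respond) = step_up / (step_up + step_down) = 16/80 = 0.20, the design's
intended ~20% stop-failure rate.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate, stats

from .task_design import CONTEXTS, DesignConfig, Schedule, Stimulus, generate_schedule

logger = logging.getLogger(__name__)

__all__ = [
    "Outcome",
    "SubjectParams",
    "StaircaseState",
    "BehavioralRecord",
    "race_trial",
    "p_respond_given_soa",
    "update_staircase",
    "simulate_session",
    "simulate_stop_series",
    "simulate_cohort",
    "records_to_frame",
]


class Outcome(str, enum.Enum):
    GO_CORRECT = "go_correct"
    GO_OMISSION = "go_omission"
    STOP_SUCCESS = "stop_success"
    STOP_FAIL = "stop_fail"
    IRRELEVANT_RESPONSE = "irrelevant_response"
    IRRELEVANT_OMISSION = "irrelevant_omission"


@dataclass(frozen=True)
class SubjectParams:
    """Free parameters of one simulated subject.

    go_mu/go_sigma/go_tau are the ex-Gaussian go-RT parameters (ms); the
    stop latency is normal(mean, sd) truncated at 0.  go_mu_context_shift_ms
    applies an optional per-context shift of go_mu (index by context).
    irrelevant_slowing_ms shifts go finishing times on stop-irrelevant
    deviant trials (responding through a deviant is slower in practice).
    Defaults give go RTs and stop latencies in the range typical of visual
    stop-signal studies.
    """

    go_mu: float = 450.0
    go_sigma: float = 60.0
    go_tau: float = 120.0
    stop_mean: float = 200.0
    stop_sd: float = 30.0
    p_trigger_failure: float = 0.0
    p_go_omission: float = 0.0
    go_mu_context_shift_ms: dict[int, float] = field(default_factory=dict)
    irrelevant_slowing_ms: float = 0.0
    response_window_ms: float = 1350.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.go_sigma < 0 or self.go_tau < 0 or self.stop_sd < 0:
            raise ValueError("go_sigma, go_tau and stop_sd must be >= 0")
        for name in ("p_trigger_failure", "p_go_omission"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {p}")


@dataclass
class StaircaseState:
    """Per-context SOA trackers with the asymmetric 1-up/1-down rule."""

    soa_ms: dict[int, float] = field(default_factory=lambda: {c: 128.0 for c in CONTEXTS})
    step_up_ms: float = 16.0
    step_down_ms: float = 64.0
    bounds_ms: tuple[float, float] = (64.0, 928.0)
    init_ms: float = 128.0

    def __post_init__(self) -> None:
        lo, hi = self.bounds_ms
        for c, soa in self.soa_ms.items():
            if not (lo <= soa <= hi):
                raise ValueError(f"SOA {soa} for context {c} outside [{lo}, {hi}]")

    @property
    def equilibrium_rate(self) -> float:
        """Stop-failure rate at which up- and down-steps balance."""
        return self.step_up_ms / (self.step_up_ms + self.step_down_ms)


@dataclass(frozen=True)
class BehavioralRecord:
    """One simulated trial's behavior."""

    index: int
    context: int
    stimulus: Stimulus
    stop_relevant: bool
    soa_ms: float | None
    responded: bool
    rt_ms: float | None
    outcome: Outcome

    def __post_init__(self) -> None:
        if self.responded != (self.rt_ms is not None):
            raise ValueError("rt_ms must be present iff responded")


def _sample_go_ft(params: SubjectParams, rng: np.random.Generator, mu: float) -> float:
    """One ex-Gaussian go finishing time (ms)."""
    ft = mu + params.go_tau * rng.exponential()
    if params.go_sigma > 0:
        ft += params.go_sigma * rng.standard_normal()
    return ft


def _sample_stop_latency(params: SubjectParams, rng: np.random.Generator) -> float:
    """One stop-process latency (ms), normal truncated at 0 by resampling."""
    if params.stop_sd == 0:
        return max(params.stop_mean, 0.0)
    while True:
        lat = params.stop_mean + params.stop_sd * rng.standard_normal()
        if lat >= 0:
            return lat


def race_trial(
    params: SubjectParams,
    soa_ms: float,
    stop_relevant: bool,
    rng: np.random.Generator,
    context: int | None = None,
    irrelevant_deviant: bool = False,
) -> tuple[bool, float | None]:
    """Race one trial; return (responded, rt_ms).

    The go process finishes at an ex-Gaussian time; on stop-relevant trials
    the stop process (if triggered) finishes at soa + stop latency, and the
    response is emitted iff the go process is strictly first.  Responses
    beyond the response window count as omissions.
    """
    if soa_ms < 0:
        raise ValueError(f"soa_ms must be >= 0, got {soa_ms}")
    mu = params.go_mu + params.go_mu_context_shift_ms.get(context, 0.0)
    if irrelevant_deviant:
        mu += params.irrelevant_slowing_ms
    go_ft = _sample_go_ft(params, rng, mu)

    if params.p_go_omission > 0 and rng.random() < params.p_go_omission:
        return False, None

    if stop_relevant:
        triggered = params.p_trigger_failure == 0 or rng.random() >= params.p_trigger_failure
        if triggered:
            stop_ft = soa_ms + _sample_stop_latency(params, rng)
            if go_ft >= stop_ft:
                return False, None

    if go_ft > params.response_window_ms:
        return False, None
    return True, float(go_ft)


def p_respond_given_soa(params: SubjectParams, soa_ms: float, context: int | None = None) -> float:
    """Numerically integrate P(respond | SOA) under the race model.

    P = p_tf + (1 - p_tf) * P(goFT < soa + stopFT), with the go finishing
    time ex-Gaussian and the stop latency truncated-normal; the response
    window and go omissions are ignored (pure race probability).
    """
    mu = params.go_mu + (params.go_mu_context_shift_ms.get(context, 0.0) if context else 0.0)
    if params.go_sigma > 0 and params.go_tau > 0:
        k = params.go_tau / params.go_sigma
        go_cdf = lambda t: stats.exponnorm.cdf(t, K=k, loc=mu, scale=params.go_sigma)
    elif params.go_sigma > 0:
        go_cdf = lambda t: stats.norm.cdf(t, loc=mu, scale=params.go_sigma)
    elif params.go_tau > 0:
        go_cdf = lambda t: stats.expon.cdf(t, loc=mu, scale=params.go_tau)
    else:
        go_cdf = lambda t: np.asarray(t >= mu, dtype=float)
    if params.stop_sd == 0:
        p_win = go_cdf(soa_ms + max(params.stop_mean, 0.0))
    else:
        a = (0.0 - params.stop_mean) / params.stop_sd
        dist = stats.truncnorm(a, np.inf, loc=params.stop_mean, scale=params.stop_sd)
        p_win, _ = integrate.quad(
            lambda s: dist.pdf(s) * go_cdf(soa_ms + s),
            max(0.0, params.stop_mean - 8 * params.stop_sd),
            params.stop_mean + 8 * params.stop_sd,
        )
    return params.p_trigger_failure + (1.0 - params.p_trigger_failure) * p_win


def update_staircase(state: StaircaseState, context: int, stop_success: bool) -> StaircaseState:
    """Return a new state with the context's SOA stepped and clamped.

    +step_up on a successful stop, -step_down on a failed one; other
    contexts' trackers are untouched.
    """
    if context not in state.soa_ms:
        raise ValueError(f"unknown context {context!r}")
    lo, hi = state.bounds_ms
    delta = state.step_up_ms if stop_success else -state.step_down_ms
    new_soa = dict(state.soa_ms)
    new_soa[context] = float(np.clip(new_soa[context] + delta, lo, hi))
    return replace(state, soa_ms=new_soa)


def simulate_session(
    params: SubjectParams,
    schedule: Schedule,
    staircase: StaircaseState | None = None,
    rng: np.random.Generator | None = None,
) -> list[BehavioralRecord]:
    """Simulate one subject running *schedule* trial by trial.

    Deviant trials receive the current per-context SOA; the staircase is
    updated only on stop-relevant trials.  Fully reproducible from
    params.rng_seed unless an explicit rng is passed.
    """
    rng = rng if rng is not None else np.random.default_rng(params.rng_seed)
    state = staircase if staircase is not None else StaircaseState()
    records: list[BehavioralRecord] = []
    for trial in schedule.trials:
        is_deviant = trial.stimulus is not Stimulus.GO
        soa = state.soa_ms[trial.context] if is_deviant else None
        responded, rt = race_trial(
            params,
            soa_ms=soa if soa is not None else 0.0,
            stop_relevant=trial.stop_relevant,
            rng=rng,
            context=trial.context,
            irrelevant_deviant=is_deviant and not trial.stop_relevant,
        )
        if trial.stop_relevant:
            outcome = Outcome.STOP_FAIL if responded else Outcome.STOP_SUCCESS
            state = update_staircase(state, trial.context, stop_success=not responded)
        elif is_deviant:
            outcome = Outcome.IRRELEVANT_RESPONSE if responded else Outcome.IRRELEVANT_OMISSION
        else:
            outcome = Outcome.GO_CORRECT if responded else Outcome.GO_OMISSION
        records.append(
            BehavioralRecord(
                index=trial.index,
                context=trial.context,
                stimulus=trial.stimulus,
                stop_relevant=trial.stop_relevant,
                soa_ms=soa,
                responded=responded,
                rt_ms=rt,
                outcome=outcome,
            )
        )
    return records


def simulate_stop_series(
    params: SubjectParams,
    n_trials: int,
    context: int = 1,
    staircase: StaircaseState | None = None,
    rng: np.random.Generator | None = None,
) -> list[BehavioralRecord]:
    """Simulate *n_trials* consecutive stop-relevant trials under tracking.

    A convenience for studying the staircase in isolation (equilibrium
    checks, SOA distributions) without interleaved go trials.
    """
    rng = rng if rng is not None else np.random.default_rng(params.rng_seed)
    state = staircase if staircase is not None else StaircaseState()
    records: list[BehavioralRecord] = []
    for i in range(n_trials):
        soa = state.soa_ms[context]
        responded, rt = race_trial(params, soa, stop_relevant=True, rng=rng, context=context)
        state = update_staircase(state, context, stop_success=not responded)
        records.append(
            BehavioralRecord(
                index=i,
                context=context,
                stimulus=Stimulus.STIM1,
                stop_relevant=True,
                soa_ms=soa,
                responded=responded,
                rt_ms=rt,
                outcome=Outcome.STOP_FAIL if responded else Outcome.STOP_SUCCESS,
            )
        )
    return records


def simulate_cohort(
    params_list: list[SubjectParams],
    schedule_config: DesignConfig | None = None,
) -> list[tuple[Schedule, list[BehavioralRecord]]]:
    """Simulate independent subjects, each on a freshly randomised schedule.

    Each subject's schedule uses a seed derived from the subject's own seed
    so subjects are mutually independent; duplicate subject seeds are
    allowed but logged as a warning.
    """
    if not params_list:
        raise ValueError("need at least one subject")
    seeds = [p.rng_seed for p in params_list]
    if len(set(seeds)) != len(seeds):
        warnings.warn("duplicate subject seeds: subjects will be identical", stacklevel=2)
        logger.warning("duplicate subject seeds in cohort: %s", seeds)
    base_config = schedule_config or DesignConfig()
    out = []
    for p in params_list:
        cfg = replace(base_config, rng_seed=np.random.SeedSequence(p.rng_seed).spawn(1)[0].generate_state(1)[0] % (2**31))
        schedule = generate_schedule(cfg)
        out.append((schedule, simulate_session(p, schedule)))
    return out


def records_to_frame(records: list[BehavioralRecord]):
    """Tabulate records (one row per trial) for export or metrics."""
    import pandas as pd

    return pd.DataFrame(
        {
            "index": [r.index for r in records],
            "context": [r.context for r in records],
            "stimulus": [r.stimulus.value for r in records],
            "stop_relevant": [r.stop_relevant for r in records],
            "soa_ms": [r.soa_ms if r.soa_ms is not None else np.nan for r in records],
            "responded": [r.responded for r in records],
            "rt_ms": [r.rt_ms if r.rt_ms is not None else np.nan for r in records],
            "outcome": [r.outcome.value for r in records],
        }
    )
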