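"""Three-context stop-signal trial schedules.

The task presents a frequent go signal and two infrequent deviant stimuli
(Stim1 at 13% of trials, Stim2 at 26%).  A context cue (1, 2 or 3) defines
the stimulus-response mapping in force: in context 1 both deviants are stop
signals, in context 2 only Stim1 requires stopping, in context 3 only Stim2.
Trials of the same context are presented in consecutive runs of 13-18
trials, and trial onsets carry a uniform 0-2000 ms jitter so the
hemodynamic response is sampled densely relative to the scanner's TR.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Stimulus",
    "TrialSpec",
    "Schedule",
    "DesignConfig",
    "ConfigError",
    "ValidationError",
    "relevance",
    "generate_schedule",
    "write_events",
    "read_events",
]

RUN_LENGTH_MIN = 13
RUN_LENGTH_MAX = 18
CONTEXTS = (1, 2, 3)


class Stimulus(str, enum.Enum):
    """Trial stimulus category."""

    GO = "go"
    STIM1 = "stim1"
    STIM2 = "stim2"


class ConfigError(ValueError):
    """Raised when a design configuration cannot be realised."""


class ValidationError(ValueError):
    """Raised when a schedule or events table violates an invariant."""


#: context -> set of stimuli that are stop signals under that mapping
_STOP_MAP = {
    1: {Stimulus.STIM1, Stimulus.STIM2},
    2: {Stimulus.STIM1},
    3: {Stimulus.STIM2},
}


def relevance(context: int, stimulus: Stimulus | str) -> bool:
    """Return whether *stimulus* is a stop signal under *context*.

    The go signal is never stop-relevant; the deviants' relevance follows
    the context's stimulus-response mapping (context 1: both; context 2:
    Stim1 only; context 3: Stim2 only).
    """
    if context not in CONTEXTS:
        raise ValueError(f"context must be one of {CONTEXTS}, got {context!r}")
    stimulus = Stimulus(stimulus)
    return stimulus in _STOP_MAP[context]


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial: what is shown, when, and whether it is a stop trial."""

    index: int
    context: int
    stimulus: Stimulus
    stop_relevant: bool
    onset_s: float
    jitter_ms: float

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValidationError(f"invalid context {self.context!r}")
        if not (0.0 <= self.jitter_ms <= 2000.0):
            raise ValidationError(f"jitter_ms {self.jitter_ms} outside [0, 2000]")
        if self.stop_relevant != relevance(self.context, self.stimulus):
            raise ValidationError(
                f"stop_relevant={self.stop_relevant} inconsistent with "
                f"context {self.context} / stimulus {self.stimulus.value}"
            )


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the experimental design.

    Defaults reproduce the study design: 1152 trials split equally over
    three contexts, each context comprising 236 go, 48 Stim1 and 100 Stim2
    trials; 100 ms stimuli; a 1350 ms response window that runs on into the
    inter-trial fixation; onset jitter uniform on [0, 2000] ms.  The default
    base ITI of 1088 ms makes the expected session length about 42 minutes.
    """

    n_trials_total: int = 1152
    n_go_per_context: int = 236
    n_stim1_per_context: int = 48
    n_stim2_per_context: int = 100
    stimulus_duration_ms: float = 100.0
    response_window_ms: float = 1350.0
    jitter_range_ms: tuple[float, float] = (0.0, 2000.0)
    base_iti_ms: float = 1088.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        per_context = (
            self.n_go_per_context + self.n_stim1_per_context + self.n_stim2_per_context
        )
        if per_context * len(CONTEXTS) != self.n_trials_total:
            raise ConfigError(
                f"per-context counts sum to {per_context}, but n_trials_total/3 "
                f"= {self.n_trials_total / len(CONTEXTS):g}"
            )
        for name in ("stimulus_duration_ms", "response_window_ms"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.base_iti_ms < 0:
            raise ConfigError("base_iti_ms must be non-negative")
        lo, hi = self.jitter_range_ms
        if not (0 <= lo <= hi):
            raise ConfigError(f"invalid jitter range [{lo}, {hi}]")

    @property
    def n_per_context(self) -> int:
        return self.n_go_per_context + self.n_stim1_per_context + self.n_stim2_per_context


@dataclass
class Schedule:
    """An ordered trial plan plus its per-condition tallies and block runs."""

    trials: list[TrialSpec]
    counts: dict[tuple[int, Stimulus], int] = field(default_factory=dict)
    block_runs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = self._tally()
        if not self.block_runs:
            self.block_runs = self._runs()

    def _tally(self) -> dict[tuple[int, Stimulus], int]:
        counts: dict[tuple[int, Stimulus], int] = {}
        for t in self.trials:
            key = (t.context, t.stimulus)
            counts[key] = counts.get(key, 0) + 1
        return counts

    def _runs(self) -> list[tuple[int, int]]:
        runs: list[tuple[int, int]] = []
        for t in self.trials:
            if runs and runs[-1][0] == t.context:
                runs[-1] = (t.context, runs[-1][1] + 1)
            else:
                runs.append((t.context, 1))
        return runs

    def __len__(self) -> int:
        return len(self.trials)

    def validate(self) -> None:
        """Check ordering and run-length invariants; raise ValidationError."""
        onsets = [t.onset_s for t in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValidationError("trial onsets are not strictly increasing")
        bad = [r for _, r in self.block_runs if not (RUN_LENGTH_MIN <= r <= RUN_LENGTH_MAX)]
        if bad:
            raise ValidationError(
                f"context run lengths {bad} outside [{RUN_LENGTH_MIN}, {RUN_LENGTH_MAX}]"
            )
        per_context = {c: 0 for c in CONTEXTS}
        for t in self.trials:
            per_context[t.context] += 1
        if len(set(per_context.values())) != 1:
            raise ValidationError(f"unequal per-context totals {per_context}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset": [t.onset_s for t in self.trials],
                "duration": [np.nan] * len(self.trials),
                "trial_type": [t.stimulus.value for t in self.trials],
                "context": [t.context for t in self.trials],
                "stop_relevant": [t.stop_relevant for t in self.trials],
                "jitter_ms": [t.jitter_ms for t in self.trials],
            }
        )


def _partition_runs(n: int, rng: np.random.Generator, max_draws: int = 10_000) -> list[int]:
    """Partition *n* trials into run lengths drawn uniformly from 13..18.

    Lengths are sampled until the remainder is below 13; the remainder is
    folded into the final run when the result stays <= 18, otherwise the
    partition is re-drawn (rejection sampling).
    """
    if n < RUN_LENGTH_MIN:
        raise ConfigError(
            f"{n} trials per context cannot form a run of >= {RUN_LENGTH_MIN}"
        )
    for _ in range(max_draws):
        lengths: list[int] = []
        remaining = n
        while remaining >= RUN_LENGTH_MIN:
            lengths.append(int(rng.integers(RUN_LENGTH_MIN, RUN_LENGTH_MAX + 1)))
            remaining -= lengths[-1]
        if remaining < 0:
            lengths[-1] += remaining  # overshoot: shrink last run
            remaining = 0
            if lengths[-1] < RUN_LENGTH_MIN:
                continue
        if remaining == 0:
            return lengths
        if lengths and lengths[-1] + remaining <= RUN_LENGTH_MAX:
            lengths[-1] += remaining
            return lengths
    raise ConfigError(
        f"could not partition {n} trials into runs of "
        f"[{RUN_LENGTH_MIN}, {RUN_LENGTH_MAX}] after {max_draws} draws"
    )


def _interleave_runs(
    runs: list[tuple[int, int]], rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Order runs pseudo-randomly so no two consecutive runs share a context.

    Greedy randomized scheduling: at each step pick a context other than the
    previous one, weighting the context with the most remaining runs when a
    tie-free choice is needed to stay feasible.
    """
    remaining: dict[int, list[int]] = {}
    for c, length in runs:
        remaining.setdefault(c, []).append(length)
    for lengths in remaining.values():
        rng.shuffle(lengths)

    ordered: list[tuple[int, int]] = []
    prev = None
    total = len(runs)
    for _ in range(total):
        counts = {c: len(v) for c, v in remaining.items() if v}
        candidates = [c for c in counts if c != prev]
        if not candidates:
            raise ConfigError("could not interleave context runs without adjacency")
        n_left = sum(counts.values())
        # a context holding at least half of the remaining runs must be
        # scheduled now or adjacency becomes unavoidable later
        forced = [c for c in candidates if 2 * counts[c] >= n_left and n_left > 1]
        pool = forced if forced else candidates
        context = int(pool[rng.integers(len(pool))])
        ordered.append((context, remaining[context].pop()))
        prev = context
    return ordered


def generate_schedule(config: DesignConfig | None = None) -> Schedule:
    """Generate a pseudo-randomised schedule realising *config* exactly.

    Tallies per (context, stimulus) always equal the configured counts; only
    the order of stimuli within runs and the order of runs across contexts
    are randomised.  Onsets accumulate stimulus duration + base ITI +
    uniform jitter per trial.
    """
    config = config or DesignConfig()
    rng = np.random.default_rng(config.rng_seed)

    pools: dict[int, list[Stimulus]] = {}
    run_lengths: dict[int, list[int]] = {}
    for c in CONTEXTS:
        pool = (
            [Stimulus.GO] * config.n_go_per_context
            + [Stimulus.STIM1] * config.n_stim1_per_context
            + [Stimulus.STIM2] * config.n_stim2_per_context
        )
        order = rng.permutation(len(pool))
        pools[c] = [pool[i] for i in order]
        run_lengths[c] = _partition_runs(config.n_per_context, rng)

    runs = [(c, length) for c in CONTEXTS for length in run_lengths[c]]
    runs = _interleave_runs(runs, rng)

    jitter_lo, jitter_hi = config.jitter_range_ms
    trials: list[TrialSpec] = []
    cursor = {c: 0 for c in CONTEXTS}
    onset = 0.0
    index = 0
    for context, length in runs:
        for _ in range(length):
            stimulus = pools[context][cursor[context]]
            cursor[context] += 1
            # integer-ms jitter; onsets kept at ms resolution in seconds
            jitter_ms = float(rng.integers(int(jitter_lo), int(jitter_hi) + 1))
            onset += (config.stimulus_duration_ms + config.base_iti_ms + jitter_ms) / 1000.0
            trials.append(
                TrialSpec(
                    index=index,
                    context=context,
                    stimulus=stimulus,
                    stop_relevant=relevance(context, stimulus),
                    onset_s=round(onset, 3),
                    jitter_ms=jitter_ms,
                )
            )
            index += 1

    schedule = Schedule(trials=trials)
    schedule.validate()
    return schedule


_EVENT_COLUMNS = ["onset", "duration", "trial_type", "context", "stop_relevant", "jitter_ms"]


def write_events(
    schedule: Schedule,
    path,
    soa_ms: dict[int, float] | None = None,
    stimulus_duration_ms: float = 100.0,
) -> None:
    """Write *schedule* as a BIDS-events-style TSV.

    Columns: onset (s), duration (s), trial_type, context, stop_relevant,
    jitter_ms, plus soa_ms when per-trial SOAs are supplied.
    """
    onsets = [t.onset_s for t in schedule.trials]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise ValidationError("trial onsets are not strictly increasing")
    frame = schedule.to_frame()
    frame["duration"] = stimulus_duration_ms / 1000.0
    if soa_ms is not None:
        frame["soa_ms"] = [soa_ms.get(t.index, np.nan) for t in schedule.trials]
    frame.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events(path) -> Schedule:
    """Read a TSV written by :func:`write_events` back into a Schedule."""
    frame = pd.read_csv(path, sep="\t", na_values=["n/a"])
    missing = [c for c in _EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"events table missing columns {missing}")
    trials = [
        TrialSpec(
            index=i,
            context=int(row.context),
            stimulus=Stimulus(row.trial_type),
            stop_relevant=bool(row.stop_relevant),
            onset_s=float(row.onset),
            jitter_ms=float(row.jitter_ms),
        )
        for i, row in enumerate(frame.itertuples(index=False))
    ]
    schedule = Schedule(trials=trials)
    onsets = [t.onset_s for t in trials]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise ValidationError("trial onsets are not strictly increasing")
    return schedule
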