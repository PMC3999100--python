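"""Behavioral statistics: response rate, go RT, mean SOA and integration-method SSRT.

The stop-signal reaction time (SSRT) is the latent latency of the stop
process.  Under the horse-race model the integration method estimates it by
treating the stop process as finishing at the go-RT quantile matching the
response rate: with N go RTs sorted ascending and response rate RR, the
stop process's finishing time corresponds to the go RT at position
n = ceil(N * RR), and SSRT = RT(n) - mean SOA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .race import BehavioralRecord, Outcome
from .task_design import CONTEXTS

__all__ = [
    "UndefinedStatisticError",
    "BehaviorSummary",
    "response_rate",
    "ssrt_integration",
    "summarize",
    "summary_to_frame",
]


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given records (e.g. RR with no stop trials)."""


@dataclass
class BehaviorSummary:
    """Per-context behavioral measures; absent measures are None."""

    go_rt_mean: dict[int, float | None] = field(default_factory=dict)
    go_rt_sem: dict[int, float | None] = field(default_factory=dict)
    response_rate: dict[int, float | None] = field(default_factory=dict)
    mean_soa: dict[int, float | None] = field(default_factory=dict)
    ssrt: dict[int, float | None] = field(default_factory=dict)
    failed_stop_rt_mean: dict[int, float | None] = field(default_factory=dict)
    irrelevant_accuracy: dict[int, float | None] = field(default_factory=dict)
    irrelevant_rt_mean: dict[int, float | None] = field(default_factory=dict)


def response_rate(records: list[BehavioralRecord], context: int) -> float:
    """Failed stop trials / all stop-relevant trials in *context*."""
    stop = [r for r in records if r.context == context and r.stop_relevant]
    if not stop:
        raise UndefinedStatisticError(f"no stop-relevant trials in context {context}")
    failed = sum(r.outcome is Outcome.STOP_FAIL for r in stop)
    return failed / len(stop)


def ssrt_integration(
    go_rts,
    rr: float,
    mean_soa: float,
    rounding: str = "ceiling",
    n_omissions: int = 0,
) -> float:
    """Integration-method SSRT: nth-fastest go RT minus mean SOA.

    n = ceil(N * rr) by default ("nearest" rounds half to even instead).  Go
    omissions, if any, are appended as copies of the maximum observed RT
    before taking the quantile, the standard guard against omission bias.
    """
    go_rts = np.asarray(list(go_rts), dtype=float)
    if go_rts.size == 0:
        raise ValueError("go_rts must be non-empty")
    if not (0.0 < rr < 1.0):
        raise UndefinedStatisticError(f"SSRT undefined for response rate {rr}")
    if n_omissions:
        go_rts = np.concatenate([go_rts, np.full(n_omissions, go_rts.max())])
    go_rts = np.sort(go_rts)
    n_float = go_rts.size * rr
    if rounding == "ceiling":
        n = math.ceil(n_float)
    elif rounding == "nearest":
        n = round(n_float)
    else:
        raise ValueError(f"rounding must be 'ceiling' or 'nearest', got {rounding!r}")
    n = min(max(n, 1), go_rts.size)
    return float(go_rts[n - 1] - mean_soa)


def _mean_sem(values: list[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    arr = np.asarray(values, dtype=float)
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return float(arr.mean()), sem


def summarize(records: list[BehavioralRecord], rounding: str = "ceiling") -> BehaviorSummary:
    """Compute all per-context behavioral measures from trial records.

    Go RT uses correct pure-go trials only; mean SOA averages the SOAs of
    stop-relevant trials; SSRT uses the context's own go-RT distribution and
    response rate.  Missing conditions leave fields as None.
    """
    summary = BehaviorSummary()
    for c in CONTEXTS:
        ctx = [r for r in records if r.context == c]
        go_rts = [r.rt_ms for r in ctx if r.outcome is Outcome.GO_CORRECT]
        n_go_omit = sum(r.outcome is Outcome.GO_OMISSION for r in ctx)
        stop = [r for r in ctx if r.stop_relevant]
        failed_rts = [r.rt_ms for r in ctx if r.outcome is Outcome.STOP_FAIL]
        irrel = [r for r in ctx if not r.stop_relevant and r.stimulus.value != "go"]
        irrel_rts = [r.rt_ms for r in irrel if r.outcome is Outcome.IRRELEVANT_RESPONSE]

        summary.go_rt_mean[c], summary.go_rt_sem[c] = _mean_sem(go_rts)
        summary.failed_stop_rt_mean[c], _ = _mean_sem(failed_rts)
        summary.irrelevant_rt_mean[c], _ = _mean_sem(irrel_rts)
        summary.irrelevant_accuracy[c] = (len(irrel_rts) / len(irrel)) if irrel else None

        if stop:
            rr = sum(r.outcome is Outcome.STOP_FAIL for r in stop) / len(stop)
            summary.response_rate[c] = rr
            soas = [r.soa_ms for r in stop if r.soa_ms is not None]
            summary.mean_soa[c], _ = _mean_sem(soas)
            if go_rts and 0.0 < rr < 1.0 and summary.mean_soa[c] is not None:
                summary.ssrt[c] = ssrt_integration(
                    go_rts, rr, summary.mean_soa[c], rounding=rounding, n_omissions=n_go_omit
                )
            else:
                summary.ssrt[c] = None
        else:
            summary.response_rate[c] = None
            summary.mean_soa[c] = None
            summary.ssrt[c] = None
    return summary


def summary_to_frame(summary: BehaviorSummary) -> pd.DataFrame:
    """One row per measure, one column per context (report-table shape)."""
    measures = {
        "GoRT": summary.go_rt_mean,
        "GoRT_SEM": summary.go_rt_sem,
        "SSRT": summary.ssrt,
        "RR": summary.response_rate,
        "mean_SOA": summary.mean_soa,
        "FailedStopRT": summary.failed_stop_rt_mean,
        "IrrelevantAccuracy": summary.irrelevant_accuracy,
        "IrrelevantRT": summary.irrelevant_rt_mean,
    }
    return pd.DataFrame(
        {f"context{c}": [m.get(c) for m in measures.values()] for c in CONTEXTS},
        index=list(measures.keys()),
    )
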