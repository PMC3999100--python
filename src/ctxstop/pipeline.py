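"""End-to-end orchestration: schedule -> behavior -> metrics -> EEG -> GLM.

A single PipelineConfig (YAML/JSON serialisable) drives every stage; all
randomness derives from one master seed.  Outputs are plain TSV/CSV tables
plus a JSON run log with stage seeds and content hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ersp import (
    BASELINE_S,
    DEFAULT_BANDS,
    EPOCH_N_SAMPLES,
    EPOCH_TMIN_S,
    SRATE,
    Effect,
    EffectSpec,
    baseline_normalize,
    baseline_power,
    compute_ersp,
    condition_ersp,
    extract_features,
    synthesize_epochs,
)
from .glm import build_design, fit_glm, synthesize_bold
from .metrics import summarize, summary_to_frame
from .race import StaircaseState, SubjectParams, records_to_frame, simulate_session
from .task_design import CONTEXTS, DesignConfig, Stimulus, generate_schedule, write_events

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "Finding", "run_pipeline", "validate_config", "load_config"]


@dataclass
class PipelineConfig:
    """Everything one run needs; master_seed derives all stage seeds."""

    design: DesignConfig = field(default_factory=DesignConfig)
    subject: SubjectParams = field(default_factory=SubjectParams)
    n_subjects: int = 5
    staircase_init_ms: float = 128.0
    staircase_step_up_ms: float = 16.0
    staircase_step_down_ms: float = 64.0
    staircase_bounds_ms: tuple[float, float] = (64.0, 928.0)
    effects: EffectSpec = field(default_factory=lambda: EffectSpec(
        effects=[
            Effect.make({"stop_relevant": True}, "delta", "frontocentral", 2.0),
            Effect.make({"stop_relevant": True}, "delta", "centroparietal", 1.7),
            Effect.make({"stop_relevant": True}, "theta", "frontocentral", 3.0),
            Effect.make({"stimulus": "stim1", "context": 2}, "theta", "frontocentral", -1.0),
            Effect.make({"stimulus": "stim1", "context": 2}, "delta", "frontocentral", -0.5),
            Effect.make({"stop_relevant": True}, "high_beta", "left_motor", 1.0),
        ],
        trial_db_sd=1.0,
    ))
    eeg_subject_index: int = 0
    eeg_max_trials: int = 300
    glm_tr_s: float = 2.0
    glm_highpass_s: float = 128.0
    glm_prewhiten: bool = True
    glm_noise_sigma: float = 1.0
    glm_noise_ar1: float = 0.3
    glm_event_beta: float = 1.0
    glm_coupling: dict[str, float] = field(default_factory=lambda: {"theta": 0.5})
    master_seed: int = 0

    def staircase(self) -> StaircaseState:
        return StaircaseState(
            soa_ms={c: self.staircase_init_ms for c in CONTEXTS},
            step_up_ms=self.staircase_step_up_ms,
            step_down_ms=self.staircase_step_down_ms,
            bounds_ms=tuple(self.staircase_bounds_ms),
            init_ms=self.staircase_init_ms,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effects"]["effects"] = [
            {"where": dict(e.where), "band": e.band, "eoi": e.eoi, "db": e.db}
            for e in self.effects.effects
        ]
        d["effects"].pop("bands", None)
        d["effects"].pop("eois", None)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "design" in d:
            d["design"] = DesignConfig(**{
                k: tuple(v) if k == "jitter_range_ms" else v for k, v in d["design"].items()
            })
        if "subject" in d:
            d["subject"] = SubjectParams(**{
                k: {int(c): s for c, s in v.items()} if k == "go_mu_context_shift_ms" else v
                for k, v in d["subject"].items()
            })
        if "effects" in d:
            eff = dict(d["effects"])
            eff["effects"] = [
                Effect.make(e["where"], e["band"], e["eoi"], e["db"]) for e in eff.get("effects", [])
            ]
            d["effects"] = EffectSpec(**eff)
        if "staircase_bounds_ms" in d:
            d["staircase_bounds_ms"] = tuple(d["staircase_bounds_ms"])
        return cls(**d)


def load_config(path) -> PipelineConfig:
    """Read a YAML or JSON pipeline config."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise IOError(f"could not parse config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise IOError(f"config {path} does not contain a mapping")
    return PipelineConfig.from_dict(data)


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    message: str


def validate_config(config: PipelineConfig) -> list[Finding]:
    """Static checks; returns findings rather than raising."""
    findings: list[Finding] = []
    try:
        from .task_design import _partition_runs

        _partition_runs(config.design.n_per_context, np.random.default_rng(0))
    except Exception as exc:
        findings.append(Finding("error", f"schedule counts not partitionable: {exc}"))

    epoch_end_ms = (EPOCH_TMIN_S + (EPOCH_N_SAMPLES - 1) / SRATE) * 1000.0
    for name, bw in config.effects.bands.items():
        if bw.t_hi_ms > epoch_end_ms or bw.t_lo_ms < EPOCH_TMIN_S * 1000.0:
            findings.append(Finding(
                "error",
                f"band window {name!r} [{bw.t_lo_ms:g}, {bw.t_hi_ms:g}] ms lies outside "
                f"the epoch (ends at {epoch_end_ms:.0f} ms)",
            ))

    ratio = config.staircase_step_up_ms / (config.staircase_step_up_ms + config.staircase_step_down_ms)
    if abs(ratio - 0.20) > 1e-9:
        findings.append(Finding(
            "warning",
            f"staircase steps imply an equilibrium response rate of {ratio:.3f}, "
            "not the documented 0.20",
        ))

    if config.subject.go_sigma == 0 and config.subject.go_tau == 0:
        findings.append(Finding("warning", "degenerate go-RT distribution (sigma = tau = 0)"))
    if config.subject.stop_sd == 0:
        findings.append(Finding("warning", "degenerate stop-latency distribution (sd = 0)"))
    if config.n_subjects < 1:
        findings.append(Finding("error", "n_subjects must be >= 1"))
    return findings


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _select_eeg_trials(records, max_trials: int, rng: np.random.Generator):
    """Balanced trial subset: deviants and go trials, capped at max_trials."""
    if len(records) <= max_trials:
        return list(records)
    deviants = [r for r in records if r.stimulus is not Stimulus.GO]
    gos = [r for r in records if r.stimulus is Stimulus.GO]
    n_dev = min(len(deviants), max_trials // 2)
    n_go = min(len(gos), max_trials - n_dev)
    chosen = [deviants[i] for i in rng.choice(len(deviants), size=n_dev, replace=False)]
    chosen += [gos[i] for i in rng.choice(len(gos), size=n_go, replace=False)]
    chosen.sort(key=lambda r: r.index)
    return chosen


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage and write the report bundle into *out_dir*.

    Returns the run log (also written as run_log.json).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(config.master_seed)
    subj_seeds, eeg_ss, glm_ss = root_ss.spawn(3)
    subject_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in subj_seeds.spawn(config.n_subjects)]

    written: list[Path] = []
    logger.info("stage schedule+simulate: %d subjects", config.n_subjects)

    cohort = []
    for i, seed in enumerate(subject_seeds):
        params = replace(config.subject, rng_seed=seed)
        schedule = generate_schedule(replace(config.design, rng_seed=seed))
        records = simulate_session(params, schedule, staircase=config.staircase())
        cohort.append((schedule, records))
        soa_by_index = {r.index: r.soa_ms for r in records if r.soa_ms is not None}
        events_path = out / f"sub-{i + 1:02d}_events.tsv"
        write_events(schedule, events_path, soa_ms=soa_by_index,
                     stimulus_duration_ms=config.design.stimulus_duration_ms)
        records_path = out / f"sub-{i + 1:02d}_records.tsv"
        records_to_frame(records).to_csv(records_path, sep="\t", index=False, na_rep="n/a")
        written += [events_path, records_path]

    logger.info("stage metrics")
    per_subject = [summary_to_frame(summarize(records)) for _, records in cohort]
    stacked = pd.concat(per_subject, keys=range(len(per_subject)), names=["subject"])
    cohort_mean = stacked.groupby(level=1, sort=False).mean()
    cohort_sem = stacked.groupby(level=1, sort=False).sem()
    summary = cohort_mean.join(cohort_sem, lsuffix="_mean", rsuffix="_sem")
    summary_path = out / "behavior_summary.csv"
    summary.to_csv(summary_path)
    written.append(summary_path)

    logger.info("stage eeg: synthesis + ERSP features")
    eeg_rng = np.random.default_rng(eeg_ss.generate_state(1)[0] % (2**31))
    schedule, records = cohort[config.eeg_subject_index]
    eeg_records = _select_eeg_trials(records, config.eeg_max_trials, eeg_rng)
    epochs = synthesize_epochs(eeg_records, config.effects, eeg_rng)
    tfp = compute_ersp(epochs)
    base = baseline_power(tfp, BASELINE_S)
    single_db = baseline_normalize(tfp, base=base)
    trial_feats = extract_features(single_db, tfp.freqs, tfp.times, tfp.ch_names,
                                   config.effects.bands, config.effects.eois)
    meta = epochs.metadata.rename(columns={"trial": "trial"})
    trial_feats = trial_feats.merge(meta, on="trial")
    trial_path = out / "ersp_single_trial.csv"
    trial_feats.to_csv(trial_path, index=False)
    written.append(trial_path)

    cond_rows = []
    for (stim, ctx), grp in meta.groupby(["stimulus", "context"]):
        mask = np.zeros(len(eeg_records), dtype=bool)
        mask[grp["trial"].to_numpy()] = True
        cond_db = condition_ersp(tfp, mask, base=base)
        feats = extract_features(cond_db, tfp.freqs, tfp.times, tfp.ch_names,
                                 config.effects.bands, config.effects.eois)
        feats.insert(0, "context", ctx)
        feats.insert(0, "stimulus", stim)
        cond_rows.append(feats)
    cond_feats = pd.concat(cond_rows, ignore_index=True)
    cond_path = out / "ersp_condition.csv"
    cond_feats.to_csv(cond_path, index=False)
    written.append(cond_path)

    logger.info("stage glm: EEG-informed design + recovery fit")
    glm_rng = np.random.default_rng(glm_ss.generate_state(1)[0] % (2**31))
    trial_onsets = {t.index: t.onset_s for t in schedule.trials}
    events = pd.DataFrame(
        {
            "onset": [trial_onsets[r.index] for r in eeg_records],
            "condition": [f"{r.stimulus.value}_c{r.context}" for r in eeg_records],
        }
    )
    modulators = {}
    for band in ("delta", "theta", "high_beta"):
        feat = trial_feats[(trial_feats["band"] == band)
                           & (trial_feats["eoi"] == ("left_motor" if band == "high_beta" else "frontocentral"))]
        modulators[band] = feat.sort_values("trial")["db"].to_numpy()
    n_scans = int(np.ceil((events["onset"].max() + 40.0) / config.glm_tr_s))
    design = build_design(events, modulators, n_scans=n_scans, tr_s=config.glm_tr_s,
                          highpass_s=config.glm_highpass_s)
    true_betas = np.zeros(len(design.columns))
    for j, name in enumerate(design.columns):
        if name.startswith("drift") or name == "constant":
            continue
        if "*" in name:
            band = name.split("*")[1]
            true_betas[j] = config.glm_coupling.get(band, 0.0)
        else:
            true_betas[j] = config.glm_event_beta
    y = synthesize_bold(design, true_betas,
                        {"sigma": config.glm_noise_sigma, "ar1_rho": config.glm_noise_ar1},
                        glm_rng)
    result = fit_glm(y, design, prewhiten=config.glm_prewhiten)
    glm_table = pd.DataFrame(
        {
            "column": design.columns,
            "true_beta": true_betas,
            "beta_hat": result.beta,
            "t": [result.t_value(c) for c in design.columns],
        }
    )
    glm_path = out / "glm_results.csv"
    glm_table.to_csv(glm_path, index=False)
    written.append(glm_path)

    run_log = {
        "package_version": __version__,
        "master_seed": config.master_seed,
        "subject_seeds": subject_seeds,
        "ar1_rho_estimated": result.ar1_rho,
        "config": config.to_dict(),
        "outputs": {p.name: _sha256(p) for p in written},
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(run_log, indent=2, default=str))
    logger.info("pipeline complete: %d files in %s", len(written) + 1, out)
    return run_log
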