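"""Synthetic stimulus-locked EEG and event-related spectral perturbations.

Epochs are synthesised as 1/f background noise with condition-dependent,
band-limited power modulations injected at chosen electrode sites and time
windows.  Time-frequency power is computed with a short-time Fourier
transform (Hann window, 512 ms, 20 ms hops, zero-padded), normalised by the
across-trial mean baseline power per frequency and channel (baseline -800
to -100 ms), and log-transformed to dB (10*log10).  Features are means of
dB values over a frequency band, a post-stimulus time window and an
electrode site of interest (EOI).

Two dB conventions coexist and differ in when the log is taken:

* single-trial features divide each trial's power by the across-trial mean
  baseline and then take the log; pure-noise trials then centre about a
  small negative offset (Jensen's inequality on the log of a noisy power
  estimate), which is harmless for modulators that are z-scored downstream;
* condition-averaged features average power over the condition's trials
  *before* the log, so pure noise yields ~0 dB, and condition differences
  estimate the injected power ratio without bias.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import irfft, rfftfreq
from scipy.optimize import brentq
from scipy.signal.windows import hann

from .race import BehavioralRecord

__all__ = [
    "SRATE",
    "BandWindow",
    "DEFAULT_BANDS",
    "DEFAULT_EOIS",
    "EEGEpochs",
    "Effect",
    "EffectSpec",
    "TFPower",
    "default_freq_grid",
    "synthesize_epochs",
    "compute_ersp",
    "baseline_power",
    "baseline_normalize",
    "condition_ersp",
    "extract_features",
]

SRATE = 250.0
EPOCH_TMIN_S = -0.800
EPOCH_N_SAMPLES = 504  # covers -800 .. +1212 ms at 250 Hz
BASELINE_S = (-0.800, -0.100)

STFT_WIN_MS = 512.0
STFT_HOP_MS = 20.0


class EEGConfigError(ValueError):
    """Raised for inconsistent EEG synthesis or analysis configuration."""


@dataclass(frozen=True)
class BandWindow:
    """A frequency band paired with its extraction time window."""

    name: str
    f_lo: float
    f_hi: float
    t_lo_ms: float
    t_hi_ms: float

    def __post_init__(self) -> None:
        if not (self.f_lo < self.f_hi):
            raise EEGConfigError(f"{self.name}: f_lo must be < f_hi")
        if not (self.t_lo_ms < self.t_hi_ms):
            raise EEGConfigError(f"{self.name}: t_lo must be < t_hi")


DEFAULT_BANDS: dict[str, BandWindow] = {
    bw.name: bw
    for bw in (
        BandWindow("delta", 0.0, 4.0, 300.0, 400.0),
        BandWindow("theta", 4.0, 8.0, 150.0, 250.0),
        BandWindow("low_beta", 12.0, 21.0, 220.0, 500.0),
        BandWindow("high_beta", 21.0, 30.0, 220.0, 500.0),
    )
}

DEFAULT_EOIS: dict[str, tuple[str, ...]] = {
    "frontocentral": ("F1", "F2", "FC1", "FC2", "FCz", "Cz"),
    "centroparietal": ("C1", "C2", "CP1", "CP2", "CPz", "Pz"),
    "left_frontal": ("F7", "F5", "AF3", "AF7"),
    "right_frontal": ("F6", "F4", "AF4", "AF8"),
    "left_motor": ("C5", "C3", "CP3"),
    "right_motor": ("C4", "C6", "CP4"),
}

DEFAULT_CHANNELS: tuple[str, ...] = tuple(
    dict.fromkeys(ch for chans in DEFAULT_EOIS.values() for ch in chans)
)


def default_freq_grid(n_steps: int = 100, f_max: float = 35.0) -> np.ndarray:
    """Linear analysis grid up to 35 Hz in 100 steps.

    True 0 Hz carries no oscillatory power, so the grid starts at f_max /
    n_steps (0.35 Hz) rather than 0.
    """
    return np.linspace(f_max / n_steps, f_max, n_steps)


@dataclass
class EEGEpochs:
    """Stimulus-locked epochs: trials x channels x samples in microvolts."""

    data: np.ndarray
    ch_names: tuple[str, ...]
    srate: float = SRATE
    tmin: float = EPOCH_TMIN_S
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise EEGConfigError("epoch data must be trials x channels x samples")
        if self.data.shape[1] != len(self.ch_names):
            raise EEGConfigError("channel axis does not match ch_names")

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.srate

    def save(self, path_prefix: str) -> None:
        """Write `<prefix>.npy` (data) and `<prefix>.json` (sidecar)."""
        np.save(f"{path_prefix}.npy", self.data)
        sidecar = {
            "ch_names": list(self.ch_names),
            "srate": self.srate,
            "tmin": self.tmin,
            "n_trials": int(self.data.shape[0]),
            "n_samples": int(self.data.shape[2]),
            "units": "uV",
        }
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)
        if self.metadata is not None:
            self.metadata.to_csv(f"{path_prefix}_trials.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, path_prefix: str) -> "EEGEpochs":
        with open(f"{path_prefix}.json") as fh:
            sidecar = json.load(fh)
        data = np.load(f"{path_prefix}.npy")
        return cls(
            data=data,
            ch_names=tuple(sidecar["ch_names"]),
            srate=sidecar["srate"],
            tmin=sidecar["tmin"],
        )


@dataclass(frozen=True)
class Effect:
    """A condition-dependent band-power modulation to inject.

    ``where`` matches trial records by attribute equality, e.g.
    ``{"stop_relevant": True}`` or ``{"stimulus": "stim1", "context": 1}``.
    ``db`` is the mean power increment in dB over the band's extraction
    window at the EOI's electrodes.
    """

    where: tuple[tuple[str, object], ...]
    band: str = "theta"
    eoi: str = "frontocentral"
    db: float = 3.0

    @staticmethod
    def make(where: dict[str, object], band: str, eoi: str, db: float) -> "Effect":
        return Effect(tuple(sorted(where.items())), band, eoi, db)

    def matches(self, record: BehavioralRecord) -> bool:
        for attr, value in self.where:
            got = getattr(record, attr)
            got = got.value if hasattr(got, "value") else got
            if got != value:
                return False
        return True


@dataclass
class EffectSpec:
    """All injected effects plus generator-level noise settings.

    With ``calibrate`` on (default), each effect's band gain is solved so
    that the mean dB measured over the band's analysis bins equals the
    requested dB despite the spectral smearing of the analysis window;
    without it, the raw noise power in the band is scaled by 10**(db/10).
    """

    effects: list[Effect] = field(default_factory=list)
    trial_db_sd: float = 0.0  # lognormal trial-to-trial power variability, in dB
    noise_alpha: float = 1.0  # background PSD ~ 1/f^alpha
    noise_scale: float = 10.0  # overall amplitude, uV (arbitrary; ERSP is a ratio)
    calibrate: bool = True
    bands: dict[str, BandWindow] = field(default_factory=lambda: dict(DEFAULT_BANDS))
    eois: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_EOIS))


def _window_response_sq(deltas_hz: np.ndarray, win_n: int, srate: float) -> np.ndarray:
    """|W(df)|^2 of the Hann analysis window at frequency offsets df."""
    w = hann(win_n, sym=False)
    n = np.arange(win_n)
    ph = np.exp(-2j * np.pi * np.outer(deltas_hz.ravel(), n) / srate)
    return (np.abs(ph @ w) ** 2).reshape(deltas_hz.shape)


EDGE_GUARD_HZ = 1.5


def _synthesis_band(bw: BandWindow, bands: dict[str, BandWindow]) -> tuple[float, float]:
    """The sub-band actually scaled by the generator for band *bw*.

    Where another analysis band adjoins an edge, the scaled region is
    pulled 1.5 Hz inside the band so the analysis window's kernel does not
    carry the injected power into the neighbour's bins.
    """
    lo, hi = bw.f_lo, bw.f_hi
    for other in bands.values():
        if other.name == bw.name:
            continue
        if abs(other.f_hi - lo) < 1.0:
            lo += EDGE_GUARD_HZ
        if abs(other.f_lo - hi) < 1.0:
            hi -= EDGE_GUARD_HZ
    if not (lo < hi):
        raise EEGConfigError(f"band {bw.name!r} too narrow for edge guards")
    return lo, hi


def _calibrated_power_gain(
    bw: BandWindow,
    synth_band: tuple[float, float],
    target_db: float,
    comp_freqs: np.ndarray,
    amp2: np.ndarray,
    analysis_freqs: np.ndarray,
    win_n: int,
    srate: float,
) -> float:
    """Band power gain whose measured mean dB over the band's bins is target_db.

    The expected power at an analysis bin is the noise power spectrum seen
    through the squared window response; the gain is solved by root finding
    on the mean over the band's bins of 10*log10(scaled / unscaled power).
    """
    eval_f = analysis_freqs[(analysis_freqs > bw.f_lo) & (analysis_freqs <= bw.f_hi)]
    if eval_f.size == 0:
        raise EEGConfigError(f"band {bw.name!r} covers no analysis frequencies")
    m = amp2[None, :] * (
        _window_response_sq(eval_f[:, None] - comp_freqs[None, :], win_n, srate)
        + _window_response_sq(eval_f[:, None] + comp_freqs[None, :], win_n, srate)
    )
    in_band = (comp_freqs > synth_band[0]) & (comp_freqs <= synth_band[1])
    band_part = m[:, in_band].sum(axis=1)
    rest_part = m[:, ~in_band].sum(axis=1)

    def measured_db(log10_gain: float) -> float:
        g = 10.0**log10_gain
        return float(np.mean(10.0 * np.log10((g * band_part + rest_part) / (band_part + rest_part))))

    target = float(target_db)
    if abs(target) < 1e-12:
        return 1.0
    lo, hi = -8.0, 8.0
    return 10.0 ** brentq(lambda x: measured_db(x) - target, lo, hi, xtol=1e-10)


def _gain_envelope(
    times: np.ndarray, t_lo_s: float, t_hi_s: float, gain_amp: float, pad_s: float, ramp_s: float
) -> np.ndarray:
    """Amplitude envelope: 1 outside, gain_amp inside the padded window.

    The modulated support is the extraction window padded by half the STFT
    analysis window plus the ramp, so every analysis frame centred inside
    the extraction window sees the full gain (injected dB are recovered
    undiluted rather than smeared by the window).
    """
    t0, t1 = t_lo_s - pad_s - ramp_s, t_hi_s + pad_s + ramp_s
    ramp_up = np.clip((times - t0) / ramp_s, 0.0, 1.0)
    ramp_down = np.clip((t1 - times) / ramp_s, 0.0, 1.0)
    shape = 0.5 - 0.5 * np.cos(np.pi * np.minimum(ramp_up, ramp_down))
    return 1.0 + (gain_amp - 1.0) * shape


def synthesize_epochs(
    records: list[BehavioralRecord],
    effect_spec: EffectSpec | None = None,
    rng: np.random.Generator | None = None,
    ch_names: tuple[str, ...] = DEFAULT_CHANNELS,
    srate: float = SRATE,
    tmin: float = EPOCH_TMIN_S,
    n_samples: int = EPOCH_N_SAMPLES,
) -> EEGEpochs:
    """Generate one epoch per trial record with the configured effects.

    Background noise is 1/f; each effect multiplies the band-limited noise
    component at its EOI's channels by a gain of ``10**(db/20)`` (power
    gain ``10**(db/10)``) inside its padded time window.  Per-trial injected
    dB (ground truth) are stored in the epoch metadata.
    """
    spec = effect_spec or EffectSpec()
    rng = rng if rng is not None else np.random.default_rng(0)

    for eff in spec.effects:
        if eff.band not in spec.bands:
            raise EEGConfigError(f"effect references unknown band {eff.band!r}")
        if eff.eoi not in spec.eois:
            raise EEGConfigError(f"effect references unknown EOI {eff.eoi!r}")
        for ch in spec.eois[eff.eoi]:
            if ch not in ch_names:
                raise EEGConfigError(f"effect electrode {ch!r} not in channel set")

    n_trials, n_ch = len(records), len(ch_names)
    times = tmin + np.arange(n_samples) / srate
    freqs = rfftfreq(n_samples, 1.0 / srate)
    amp = np.zeros_like(freqs)
    amp[1:] = spec.noise_scale * freqs[1:] ** (-spec.noise_alpha / 2.0)

    # frequency partition induced by the effects' synthesis sub-bands
    synth_bands = {
        eff.band: _synthesis_band(spec.bands[eff.band], spec.bands) for eff in spec.effects
    }
    edges = sorted({0.0, srate / 2.0} | {f for sb in synth_bands.values() for f in sb})
    segments = list(zip(edges, edges[1:]))
    seg_masks = [((freqs > lo) & (freqs <= hi)) for lo, hi in segments]

    ch_index = {ch: i for i, ch in enumerate(ch_names)}
    pad_s = (STFT_WIN_MS / 1000.0) / 2.0
    ramp_s = 0.032

    win_n = int(round(STFT_WIN_MS / 1000.0 * srate))
    analysis_freqs = default_freq_grid()
    amp2 = amp**2
    gain_cache: dict[tuple[str, float], float] = {}

    def power_gain(band: str, db: float) -> float:
        if not spec.calibrate:
            return 10.0 ** (db / 10.0)
        key = (band, round(db, 9))
        if key not in gain_cache:
            gain_cache[key] = _calibrated_power_gain(
                spec.bands[band], synth_bands[band], db, freqs, amp2, analysis_freqs, win_n, srate
            )
        return gain_cache[key]

    data = np.empty((n_trials, n_ch, n_samples), dtype=np.float64)
    truth_rows: list[dict] = []

    for ti, rec in enumerate(records):
        # complex spectrum of this trial's noise, shared across band components
        z = (rng.standard_normal((n_ch, freqs.size)) + 1j * rng.standard_normal((n_ch, freqs.size))) * amp
        x = irfft(z, n=n_samples, axis=-1)

        active = [eff for eff in spec.effects if eff.matches(rec)]
        if active:
            # per-segment, per-channel amplitude envelopes (product over effects)
            env: dict[tuple[int, int], np.ndarray] = {}
            for eff in active:
                bw = spec.bands[eff.band]
                jitter_db = spec.trial_db_sd * rng.standard_normal() if spec.trial_db_sd else 0.0
                truth_rows.append(
                    {"trial": ti, "band": eff.band, "eoi": eff.eoi, "db_injected": eff.db + jitter_db}
                )
                g_power = power_gain(eff.band, eff.db) * 10.0 ** (jitter_db / 10.0)
                gain_amp = np.sqrt(g_power)
                e = _gain_envelope(times, bw.t_lo_ms / 1000.0, bw.t_hi_ms / 1000.0, gain_amp, pad_s, ramp_s)
                s_lo, s_hi = synth_bands[eff.band]
                for si, (lo, hi) in enumerate(segments):
                    if lo >= s_lo and hi <= s_hi:
                        for ch in spec.eois[eff.eoi]:
                            key = (si, ch_index[ch])
                            env[key] = env[key] * e if key in env else e.copy()
            for (si, ci), e in env.items():
                x_seg = irfft(z[ci] * seg_masks[si], n=n_samples)
                x[ci] += (e - 1.0) * x_seg
        data[ti] = x

    metadata = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "context": [r.context for r in records],
            "stimulus": [r.stimulus.value for r in records],
            "stop_relevant": [r.stop_relevant for r in records],
            "outcome": [r.outcome.value for r in records],
        }
    )
    epochs = EEGEpochs(data=data, ch_names=tuple(ch_names), srate=srate, tmin=tmin, metadata=metadata)
    epochs.truth = pd.DataFrame(truth_rows, columns=["trial", "band", "eoi", "db_injected"])
    return epochs


@dataclass
class TFPower:
    """Time-frequency power: trials x channels x freqs x frames."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray  # frame centres, s relative to stimulus onset
    ch_names: tuple[str, ...]


def _dft_atoms(freqs: np.ndarray, win_n: int, srate: float) -> tuple[np.ndarray, np.ndarray]:
    """Hann-windowed DFT atoms evaluated at exact analysis frequencies."""
    w = hann(win_n, sym=False)
    n = np.arange(win_n)
    phase = -2.0 * np.pi * np.outer(n, freqs) / srate
    atoms = w[:, None] * np.exp(1j * phase)
    return atoms.real.astype(np.float32), atoms.imag.astype(np.float32)


def compute_ersp(
    epochs: EEGEpochs,
    freqs: np.ndarray | None = None,
    win_ms: float = STFT_WIN_MS,
    hop_ms: float = STFT_HOP_MS,
    chunk: int = 32,
) -> TFPower:
    """Short-time Fourier power on the analysis frequency grid.

    Hann window (default 512 ms) sliding in 20 ms hops; the windowed DFT is
    evaluated at the exact grid frequencies (the limit of a zero-padded
    FFT).  Only frames whose window lies fully inside the epoch are kept,
    so edge frames never dilute baseline or feature power.
    """
    freqs = default_freq_grid() if freqs is None else np.asarray(freqs, dtype=float)
    srate = epochs.srate
    n_samples = epochs.data.shape[2]
    win_n = int(round(win_ms / 1000.0 * srate))
    if win_n > n_samples:
        raise EEGConfigError(
            f"epoch ({n_samples} samples) shorter than the {win_ms:g} ms analysis window"
        )
    hop_n = max(int(round(hop_ms / 1000.0 * srate)), 1)
    atoms_re, atoms_im = _dft_atoms(freqs, win_n, srate)

    starts = np.arange(0, n_samples - win_n + 1, hop_n)
    times = epochs.tmin + (starts + (win_n - 1) / 2.0) / srate
    n_trials, n_ch = epochs.data.shape[:2]
    flat = epochs.data.reshape(n_trials * n_ch, n_samples)
    frames = np.lib.stride_tricks.sliding_window_view(flat, win_n, axis=-1)[:, ::hop_n, :]

    power = np.empty((n_trials * n_ch, starts.size, freqs.size), dtype=np.float32)
    for lo in range(0, flat.shape[0], chunk):
        seg = frames[lo : lo + chunk].astype(np.float32)
        sh = seg.shape
        seg = seg.reshape(-1, win_n)
        power[lo : lo + chunk] = ((seg @ atoms_re) ** 2 + (seg @ atoms_im) ** 2).reshape(
            sh[0], sh[1], freqs.size
        )
    power = power.transpose(0, 2, 1).reshape(n_trials, n_ch, freqs.size, starts.size)
    return TFPower(power=power, freqs=freqs, times=times, ch_names=epochs.ch_names)


def baseline_power(tfp: TFPower, baseline: tuple[float, float] = BASELINE_S) -> np.ndarray:
    """Across-trial mean power per channel and frequency in the baseline window."""
    lo, hi = baseline
    mask = (tfp.times >= lo) & (tfp.times <= hi)
    if not mask.any():
        raise EEGConfigError(f"baseline window {baseline} outside epoch frames")
    base = tfp.power[..., mask].mean(axis=(0, 3))  # (ch, freqs)
    if np.any(base <= 0):
        raise EEGConfigError("zero baseline power: degenerate input")
    return base


def baseline_normalize(
    tfp: TFPower,
    baseline: tuple[float, float] = BASELINE_S,
    base: np.ndarray | None = None,
) -> np.ndarray:
    """Single-trial dB: 10*log10(power / across-trial mean baseline power)."""
    base = baseline_power(tfp, baseline) if base is None else base
    with np.errstate(divide="raise"):
        return 10.0 * np.log10(tfp.power / base[None, :, :, None])


def condition_ersp(
    tfp: TFPower,
    trial_mask: np.ndarray | None = None,
    baseline: tuple[float, float] = BASELINE_S,
    base: np.ndarray | None = None,
) -> np.ndarray:
    """Condition-averaged dB: power averaged over trials before the log.

    Returns a (channels, freqs, frames) array; pure noise yields ~0 dB.
    """
    base = baseline_power(tfp, baseline) if base is None else base
    sel = tfp.power if trial_mask is None else tfp.power[np.asarray(trial_mask)]
    if sel.shape[0] == 0:
        raise EEGConfigError("condition mask selects no trials")
    mean_power = sel.mean(axis=0)
    return 10.0 * np.log10(mean_power / base[:, :, None])


def extract_features(
    ersp_db: np.ndarray,
    freqs: np.ndarray,
    times: np.ndarray,
    ch_names: tuple[str, ...],
    band_windows: dict[str, BandWindow] | None = None,
    eois: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Mean dB over each band's bins, window's frames and EOI's electrodes.

    Accepts single-trial dB (trials, ch, f, t) -> one row per (trial, band,
    eoi), or condition-averaged dB (ch, f, t) -> one row per (band, eoi).
    """
    band_windows = band_windows or DEFAULT_BANDS
    eois = eois or DEFAULT_EOIS
    ch_index = {ch: i for i, ch in enumerate(ch_names)}
    per_trial = ersp_db.ndim == 4
    if ersp_db.ndim not in (3, 4):
        raise ValueError("ersp_db must be (trials, ch, f, t) or (ch, f, t)")

    rows = []
    for bname, bw in band_windows.items():
        fmask = (freqs > bw.f_lo) & (freqs <= bw.f_hi)
        tmask = (times * 1000.0 >= bw.t_lo_ms) & (times * 1000.0 <= bw.t_hi_ms)
        if not fmask.any():
            raise EEGConfigError(f"band {bname!r} selects no frequency bins")
        if not tmask.any():
            raise EEGConfigError(f"band {bname!r} window selects no time frames")
        for ename, electrodes in eois.items():
            missing = [ch for ch in electrodes if ch not in ch_index]
            if missing:
                raise EEGConfigError(f"EOI {ename!r} electrodes missing from data: {missing}")
            cidx = [ch_index[ch] for ch in electrodes]
            block = ersp_db[..., cidx, :, :][..., fmask, :][..., tmask]
            value = block.mean(axis=(-3, -2, -1))
            if per_trial:
                for t, v in enumerate(value):
                    rows.append({"trial": t, "band": bname, "eoi": ename, "db": float(v)})
            else:
                rows.append({"band": bname, "eoi": ename, "db": float(value)})
    return pd.DataFrame(rows)
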