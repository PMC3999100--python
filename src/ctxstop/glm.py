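"""EEG-informed first-level fMRI GLMs with single-trial parametric modulation.

Event regressors are stick functions convolved with the canonical
double-gamma HRF at 100 ms microtime resolution and resampled to the scan
grid (TR = 2 s).  Each condition may carry parametric modulators (per-trial
EEG band power): sticks weighted by the z-scored modulator, convolved, then
residualised against the condition's unmodulated regressor (and against any
earlier modulators of the same condition, serially), so the modulated
column captures only trial-to-trial amplitude variation.  Discrete-cosine
drift columns implement a 128 s high-pass filter; serial correlations are
handled with one-step Cochrane-Orcutt AR(1) prewhitening estimated from the
OLS residuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import lfilter
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "HRFModel",
    "DesignMatrix",
    "GLMResult",
    "DesignError",
    "hrf",
    "build_design",
    "synthesize_bold",
    "fit_glm",
]


class DesignError(ValueError):
    """Raised when a design matrix cannot be built or is rank deficient."""


@dataclass(frozen=True)
class HRFModel:
    """Canonical double-gamma HRF parameters (SPM convention)."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    peak_undershoot_ratio: float = 6.0
    length_s: float = 32.0


def hrf(t_grid, model: HRFModel = HRFModel()) -> np.ndarray:
    """Evaluate the canonical double-gamma HRF, peak-normalised to 1.

    h(t) = g(t; 6, 1) - g(t; 16, 1)/6 with gamma-density components; zero
    beyond the 32 s support.
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("HRF is defined for t >= 0 only")

    def gamma_pdf(x, shape, scale):
        x = np.maximum(x, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            logpdf = (shape - 1) * np.log(x) - x / scale - gammaln(shape) - shape * np.log(scale)
        out = np.where(x > 0, np.exp(logpdf), 0.0)
        return out

    def raw(x):
        p = gamma_pdf(x, model.peak_delay_s / model.peak_dispersion_s, model.peak_dispersion_s)
        u = gamma_pdf(
            x, model.undershoot_delay_s / model.undershoot_dispersion_s, model.undershoot_dispersion_s
        )
        return p - u / model.peak_undershoot_ratio

    fine = np.arange(0.0, model.length_s, 0.001)
    peak = raw(fine).max()
    values = raw(t) / peak
    values[t > model.length_s] = 0.0
    return values


@dataclass
class DesignMatrix:
    """Scan-resolution design: values (n_scans x n_cols) plus column labels."""

    values: np.ndarray
    columns: list[str]
    tr_s: float = 2.0
    frame_times: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns)

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]


def _dct_drift(n_scans: int, tr_s: float, highpass_s: float) -> np.ndarray:
    """Discrete-cosine drift columns with periods longer than highpass_s."""
    order = int(np.floor(2.0 * n_scans * tr_s / highpass_s))
    t = np.arange(n_scans)
    cols = [np.cos(np.pi * k * (t + 0.5) / n_scans) for k in range(1, order + 1)]
    return np.column_stack(cols) if cols else np.empty((n_scans, 0))


def _convolved_regressor(
    onsets_s: np.ndarray,
    weights: np.ndarray,
    n_scans: int,
    tr_s: float,
    dt_s: float,
    hrf_model: HRFModel,
) -> np.ndarray:
    """Weighted sticks on the microtime grid, convolved, sampled at scan times."""
    n_micro = int(round(n_scans * tr_s / dt_s))
    sticks = np.zeros(n_micro)
    idx = np.round(onsets_s / dt_s).astype(int)
    np.add.at(sticks, idx, weights)
    kernel = hrf(np.arange(0.0, hrf_model.length_s + dt_s, dt_s), hrf_model)
    conv = np.convolve(sticks, kernel)[:n_micro]
    scan_idx = np.round(np.arange(n_scans) * tr_s / dt_s).astype(int)
    return conv[scan_idx]


def _residualize(y: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Residual of y after projection onto the columns of basis."""
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    return y - basis @ coef


def build_design(
    events: pd.DataFrame,
    modulators: dict[str, pd.DataFrame | pd.Series | np.ndarray] | None = None,
    n_scans: int = 600,
    tr_s: float = 2.0,
    highpass_s: float = 128.0,
    microtime_s: float = 0.1,
    hrf_model: HRFModel = HRFModel(),
    nuisance: pd.DataFrame | None = None,
) -> DesignMatrix:
    """Build the first-level design matrix.

    ``events`` needs columns ``onset`` (s) and ``condition``; ``modulators``
    maps modulator names (e.g. ``theta``) to one value per event (aligned
    with ``events`` rows; NaN rows are excluded from that modulator).  Each
    condition gets one unmodulated column plus one column per modulator,
    z-scored and serially orthogonalised (unmodulated first, then modulators
    in the given order).  Drift columns and a constant close the design.
    """
    if modulators is None:
        modulators = {}
    if len(events) and "onset" not in events.columns:
        raise DesignError("events must have an 'onset' column")
    if len(events):
        onsets = np.asarray(events["onset"], dtype=float)
        if onsets.min() < 0 or onsets.max() >= n_scans * tr_s:
            raise DesignError("event onsets fall outside the scan span")

    cols: list[np.ndarray] = []
    names: list[str] = []
    conditions = list(dict.fromkeys(events["condition"])) if len(events) else []
    for cond in conditions:
        mask = np.asarray(events["condition"] == cond)
        onsets = np.asarray(events.loc[mask, "onset"], dtype=float)
        base_col = _convolved_regressor(
            onsets, np.ones(onsets.size), n_scans, tr_s, microtime_s, hrf_model
        )
        cols.append(base_col)
        names.append(str(cond))
        # include the constant so the modulated column is mean-free, making
        # its Pearson correlation with the companion exactly zero
        ortho_basis = [base_col, np.ones(n_scans)]
        for mod_name, values in modulators.items():
            vals = np.asarray(values, dtype=float)[mask]
            ok = ~np.isnan(vals)
            if ok.sum() < 2:
                continue  # too few events to carry trial-to-trial variation
            v = vals[ok]
            if np.ptp(v) == 0:
                raise DesignError(
                    f"modulator {mod_name!r} is constant across {cond!r} trials: "
                    "z-score undefined"
                )
            z = (v - v.mean()) / v.std(ddof=0)
            mod_col = _convolved_regressor(onsets[ok], z, n_scans, tr_s, microtime_s, hrf_model)
            pre_norm = float(np.linalg.norm(mod_col))
            mod_col = _residualize(mod_col, np.column_stack(ortho_basis))
            if np.linalg.norm(mod_col) <= 1e-8 * max(pre_norm, 1.0):
                logger.warning(
                    "modulator %r adds no unique variance for condition %r "
                    "(too few events); column skipped", mod_name, cond,
                )
                continue
            cols.append(mod_col)
            names.append(f"{cond}*{mod_name}")
            ortho_basis.append(cols[-1])

    if nuisance is not None:
        for c in nuisance.columns:
            cols.append(np.asarray(nuisance[c], dtype=float))
            names.append(str(c))

    drift = _dct_drift(n_scans, tr_s, highpass_s)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append(f"drift_{k + 1}")
    cols.append(np.ones(n_scans))
    names.append("constant")

    X = np.column_stack(cols)
    if not np.all(np.isfinite(X)):
        raise DesignError("design matrix contains non-finite entries")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy rank check
        bad = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            sub = X[:, kept + [j]]
            if np.linalg.matrix_rank(sub) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(names[j])
        raise DesignError(f"design is rank deficient; collinear columns: {bad}")
    return DesignMatrix(values=X, columns=names, tr_s=tr_s,
                        frame_times=np.arange(n_scans) * tr_s)


def synthesize_bold(
    design: DesignMatrix,
    true_betas: np.ndarray,
    noise: dict | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """y = X @ beta + AR(1) Gaussian noise with stationary sd ``sigma``.

    ``noise`` keys: ``sigma`` (stationary noise sd, default 1.0) and
    ``ar1_rho`` (lag-1 autocorrelation, default 0).
    """
    noise = noise or {}
    sigma = float(noise.get("sigma", 1.0))
    rho = float(noise.get("ar1_rho", 0.0))
    if not (0.0 <= rho < 1.0):
        raise ValueError("ar1_rho must lie in [0, 1)")
    rng = rng if rng is not None else np.random.default_rng(0)
    true_betas = np.asarray(true_betas, dtype=float)
    if true_betas.size != design.values.shape[1]:
        raise ValueError("one beta per design column required")
    n = design.n_scans
    y = design.values @ true_betas
    if sigma > 0:
        eps = np.empty(n)
        eps[0] = rng.standard_normal() * sigma  # stationary start
        if n > 1:
            innov = rng.standard_normal(n - 1) * sigma * np.sqrt(1.0 - rho**2)
            eps[1:] = lfilter([1.0], [1.0, -rho], innov, zi=[rho * eps[0]])[0]
        y = y + eps
    return y


@dataclass
class GLMResult:
    """Estimated effects for one time series."""

    beta: np.ndarray
    columns: list[str]
    residual_var: float
    df_resid: float
    ar1_rho: float
    cov_unscaled: np.ndarray = field(repr=False, default=None)

    def contrast(self, c: np.ndarray) -> tuple[float, float]:
        """Return (effect, t) for contrast vector c."""
        c = np.asarray(c, dtype=float)
        effect = float(c @ self.beta)
        se = float(np.sqrt(self.residual_var * c @ self.cov_unscaled @ c))
        return effect, effect / se if se > 0 else np.inf

    def t_value(self, column: str) -> float:
        c = np.zeros(len(self.columns))
        c[self.columns.index(column)] = 1.0
        return self.contrast(c)[1]

    def p_value(self, column: str) -> float:
        t = self.t_value(column)
        return float(2.0 * stats.t.sf(abs(t), self.df_resid))


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    return beta, resid, xtx_inv


def fit_glm(y: np.ndarray, design: DesignMatrix, prewhiten: bool = True) -> GLMResult:
    """OLS fit with optional one-step Cochrane-Orcutt AR(1) prewhitening.

    The AR coefficient is the lag-1 autocorrelation of the OLS residuals;
    y and X are quasi-differenced once (first row scaled by sqrt(1-rho^2))
    and refit.  t-values use the whitened residual variance.
    """
    y = np.asarray(y, dtype=float)
    X = design.values
    if y.shape[0] != X.shape[0]:
        raise ValueError("y and design have different numbers of scans")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design is rank deficient")

    beta, resid, xtx_inv = _ols(y, X)
    rho = 0.0
    if prewhiten:
        denom = float(resid @ resid)
        if denom > 0:
            rho = float(resid[1:] @ resid[:-1] / denom)
        rho = float(np.clip(rho, -0.99, 0.99))
        if abs(rho) > 1e-12:
            scale0 = np.sqrt(1.0 - rho**2)
            yw = np.empty_like(y)
            Xw = np.empty_like(X)
            yw[0], Xw[0] = y[0] * scale0, X[0] * scale0
            yw[1:] = y[1:] - rho * y[:-1]
            Xw[1:] = X[1:] - rho * X[:-1]
            beta, resid, xtx_inv = _ols(yw, Xw)

    df = y.size - X.shape[1]
    return GLMResult(
        beta=beta,
        columns=list(design.columns),
        residual_var=float(resid @ resid / df),
        df_resid=df,
        ar1_rho=rho,
        cov_unscaled=xtx_inv,
    )
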