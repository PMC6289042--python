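"""First-level GLM: design matrices, canonical HRF, high-pass drift basis,
AR(1) prewhitened estimation, contrasts, and Gaussian smoothing.

Three design variants are supported:

* ``univariate`` — one regressor per condition (positive / negative / now),
  each trial modelled as a boxcar over the cue plus image epoch;
* ``mvpa`` — one regressor per strategy x cue combination (4 columns), with
  the control condition collapsed into a single nuisance column;
* ``beta_series`` — one regressor per regulation trial (least-squares-all),
  control condition as one nuisance column.

All variants share the nuisance set: rating-period and inter-trial-interval
regressors, six motion regressors, discrete-cosine drift columns below the
high-pass cutoff, and a constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import gamma as gamma_dist
from scipy.stats import t as t_dist

from .io import CONDITIONS, Volume4D

DESIGN_MODES = ("univariate", "mvpa", "beta_series")

REGULATION = ("positive", "negative")


class GlmError(ValueError):
    pass


def canonical_hrf(time_grid: np.ndarray) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at ``time_grid``.

    Difference of two gamma densities (response peak delay 6 s, undershoot
    delay 16 s, unit dispersions, undershoot ratio 1/6), rescaled so that the
    kernel peak equals 1.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.size and t.min() < 0:
        raise GlmError("time_grid must be nonnegative")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise GlmError("time_grid must be strictly increasing")
    h = gamma_dist.pdf(t, a=6.0, scale=1.0) - gamma_dist.pdf(t, a=16.0, scale=1.0) / 6.0
    # normalize against a dense reference so scaling is grid-independent
    dense = np.arange(0, 32.0, 0.01)
    peak = np.max(gamma_dist.pdf(dense, a=6.0, scale=1.0)
                  - gamma_dist.pdf(dense, a=16.0, scale=1.0) / 6.0)
    return h / peak


def epoch_regressor(onsets: np.ndarray, durations: np.ndarray,
                    frame_times: np.ndarray, dt: float = 0.1,
                    amplitudes: np.ndarray | None = None) -> np.ndarray:
    """Boxcar epochs convolved with the canonical HRF, sampled at frame times."""
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.atleast_1d(np.asarray(durations, dtype=float))
    if amplitudes is None:
        amplitudes = np.ones_like(onsets)
    n_hi = int(np.ceil((frame_times[-1] + dt) / dt)) + 1
    hi = np.zeros(n_hi)
    for onset, dur, amp in zip(onsets, durations, amplitudes):
        i0 = int(np.round(onset / dt))
        i1 = int(np.round((onset + dur) / dt))
        hi[i0:min(i1, n_hi)] += amp
    kernel = canonical_hrf(np.arange(0, 32.0 + dt, dt))
    conv = np.convolve(hi, kernel)[:n_hi] * dt
    idx = np.clip(np.round(frame_times / dt).astype(int), 0, n_hi - 1)
    return conv[idx]


def highpass_basis(n_frames: int, tr: float, cutoff_hz: float = 1.0 / 128.0) -> np.ndarray:
    """Discrete-cosine drift columns spanning frequencies below the cutoff.

    Column count is ``floor(2 * n_frames * tr * cutoff_hz)`` (constant term
    excluded); for 380 frames at TR 2 s and a 1/128 Hz cutoff this gives 11.
    """
    if n_frames < 2:
        raise GlmError("n_frames must be >= 2")
    if cutoff_hz <= 0:
        raise GlmError("cutoff_hz must be positive")
    n_cols = int(np.floor(2.0 * n_frames * tr * cutoff_hz))
    i = np.arange(n_frames)
    cols = [np.cos(np.pi * k * (2 * i + 1) / (2.0 * n_frames)) * np.sqrt(2.0 / n_frames)
            for k in range(1, n_cols + 1)]
    return np.column_stack(cols) if cols else np.empty((n_frames, 0))


@dataclass
class DesignMatrix:
    """Named design matrix for one run, plus bookkeeping of column roles."""

    matrix: pd.DataFrame           # frames x columns
    frame_times: np.ndarray
    condition_columns: list[str]   # task columns of interest for the mode
    mode: str
    trial_conditions: dict[str, str] | None = None  # beta_series: column -> condition

    @property
    def n_frames(self) -> int:
        return len(self.matrix)

    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)


def build_design_matrix(events: pd.DataFrame, mode: str, motion: np.ndarray,
                        tr: float, n_frames: int, highpass_hz: float = 1.0 / 128.0,
                        rating_duration_s: float = 3.0, dt: float = 0.1) -> DesignMatrix:
    """Build the first-level design matrix for one run in the given mode."""
    if mode not in DESIGN_MODES:
        raise GlmError(f"mode must be one of {DESIGN_MODES}, got {mode!r}")
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise GlmError("motion must have six columns")
    if motion.shape[0] != n_frames:
        raise GlmError("motion rows must equal n_frames")
    frame_times = np.arange(n_frames) * tr
    run_end = n_frames * tr
    onsets = events["onset"].to_numpy(dtype=float)
    durations = events["duration"].to_numpy(dtype=float)
    if np.any(onsets + durations > run_end):
        raise GlmError("events extend beyond run end")

    cols: dict[str, np.ndarray] = {}
    conditions = events["condition"].to_numpy()
    condition_columns: list[str] = []
    trial_conditions: dict[str, str] | None = None

    if mode == "univariate":
        for cond in CONDITIONS:
            sel = conditions == cond
            cols[cond] = epoch_regressor(onsets[sel], durations[sel], frame_times, dt)
            condition_columns.append(cond)
    elif mode == "mvpa":
        cues = events["cue_id"].to_numpy()
        for strat in REGULATION:
            for cue in (1, 2):
                sel = (conditions == strat) & (cues == cue)
                name = f"{strat}_cue{cue}"
                cols[name] = epoch_regressor(onsets[sel], durations[sel], frame_times, dt)
                condition_columns.append(name)
        sel = conditions == "now"
        cols["now"] = epoch_regressor(onsets[sel], durations[sel], frame_times, dt)
    else:  # beta_series: one column per regulation trial, control as nuisance
        trial_conditions = {}
        reg_idx = np.flatnonzero(np.isin(conditions, REGULATION))
        for j, i in enumerate(reg_idx):
            name = f"trial_{j + 1:03d}"
            cols[name] = epoch_regressor(onsets[i], durations[i], frame_times, dt)
            condition_columns.append(name)
            trial_conditions[name] = str(conditions[i])
        sel = conditions == "now"
        cols["now"] = epoch_regressor(onsets[sel], durations[sel], frame_times, dt)

    # nuisance: rating period and inter-trial interval
    rating_on = onsets + durations
    cols["rating"] = epoch_regressor(rating_on, np.full_like(rating_on, rating_duration_s),
                                     frame_times, dt)
    iti_on = rating_on + rating_duration_s
    next_on = np.append(onsets[1:], run_end)
    iti_dur = np.maximum(next_on - iti_on, dt)
    cols["iti"] = epoch_regressor(iti_on, iti_dur, frame_times, dt)

    for j in range(6):
        m = motion[:, j]
        cols[f"motion_{j + 1}"] = m - m.mean()
    drift = highpass_basis(n_frames, tr, highpass_hz)
    for j in range(drift.shape[1]):
        cols[f"drift_{j + 1}"] = drift[:, j]
    cols["constant"] = np.ones(n_frames)

    matrix = pd.DataFrame(cols)
    return DesignMatrix(matrix=matrix, frame_times=frame_times,
                        condition_columns=condition_columns, mode=mode,
                        trial_conditions=trial_conditions)


@dataclass
class BetaMaps:
    """Fitted first-level model: coefficient maps plus error model state."""

    betas: np.ndarray              # columns x voxels (flattened over mask)
    sigma2: np.ndarray             # residual variance per voxel
    rho: float                     # pooled AR(1) coefficient
    df: int
    columns: list[str]
    cov_unscaled: np.ndarray       # (X'X)^-1 of the whitened design
    mask: np.ndarray | None        # 3D boolean, None for 2D input
    grid_shape: tuple[int, int, int] | None

    def beta_map(self, name: str) -> np.ndarray:
        j = self.columns.index(name)
        return self._unflatten(self.betas[j])

    def _unflatten(self, flat: np.ndarray) -> np.ndarray:
        if self.mask is None:
            return flat
        out = np.full(self.grid_shape, np.nan)
        out[self.mask] = flat
        return out


def _ar1_whiten(y: np.ndarray, rho: float) -> np.ndarray:
    """Apply the AR(1) square-root (Prais-Winsten) transform along axis 0."""
    out = np.empty_like(y, dtype=float)
    out[0] = y[0] * np.sqrt(1.0 - rho ** 2)
    out[1:] = y[1:] - rho * y[:-1]
    return out


def fit_glm(volume: Volume4D | np.ndarray, design: DesignMatrix,
            mask: np.ndarray | None = None) -> BetaMaps:
    """Two-pass AR(1)-prewhitened least squares.

    Pass one fits OLS and pools the lag-1 autocorrelation of the residuals
    over in-mask voxels; pass two whitens data and design with the AR(1)
    square-root transform and re-estimates.
    """
    grid_shape = None
    if isinstance(volume, Volume4D):
        grid_shape = volume.grid_shape
        if mask is None:
            mask = np.ones(grid_shape, dtype=bool)
        y = volume.data[mask].T  # frames x voxels
    else:
        y = np.asarray(volume, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        mask = None
    x = design.values()
    n, p = x.shape
    if y.shape[0] != n:
        raise GlmError(f"data has {y.shape[0]} frames but design has {n}")
    if n <= p:
        raise GlmError("fewer frames than design columns")
    if np.linalg.matrix_rank(x) < p:
        raise GlmError("design matrix is rank deficient")

    pinv = np.linalg.pinv(x)
    beta = pinv @ y
    resid = y - x @ beta
    num = float(np.sum(resid[1:] * resid[:-1]))
    den = float(np.sum(resid * resid))
    if den > 1e-12 * float(np.sum(y * y)):
        # first-order bias correction: projection onto the design (drift
        # columns especially) pushes residual lag-1 autocorrelation down by
        # ~tr(H S)/(n - p) where H is the hat matrix and S the lag operator
        xtx_inv_ols = np.linalg.inv(x.T @ x)
        h1 = float(np.sum((x[:-1] @ xtx_inv_ols) * x[1:]))
        rho = num / den + h1 / (n - p)
    else:
        # residuals at numerical-noise scale carry no autocorrelation signal
        rho = 0.0
    rho = float(np.clip(rho, -0.99, 0.99))

    xw = _ar1_whiten(x, rho)
    yw = _ar1_whiten(y, rho)
    xtx_inv = np.linalg.inv(xw.T @ xw)
    beta_w = xtx_inv @ xw.T @ yw
    resid_w = yw - xw @ beta_w
    df = n - p
    sigma2 = np.sum(resid_w ** 2, axis=0) / df
    return BetaMaps(betas=beta_w, sigma2=sigma2, rho=rho, df=df,
                    columns=list(design.matrix.columns), cov_unscaled=xtx_inv,
                    mask=mask, grid_shape=grid_shape)


@dataclass
class ContrastMap:
    effect: np.ndarray
    t: np.ndarray
    df: int

    def p_values(self) -> np.ndarray:
        return t_dist.sf(self.t, self.df)


def compute_contrast(betas: BetaMaps, weights: dict[str, float] | np.ndarray) -> ContrastMap:
    """Linear contrast of coefficients with its t map under the whitened model."""
    if isinstance(weights, dict):
        unknown = set(weights) - set(betas.columns)
        if unknown:
            raise GlmError(f"contrast references unknown columns: {sorted(unknown)}")
        w = np.array([weights.get(c, 0.0) for c in betas.columns])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(betas.columns),):
            raise GlmError("weight vector length must equal design column count")
    effect = w @ betas.betas
    var = betas.sigma2 * float(w @ betas.cov_unscaled @ w)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, effect / np.sqrt(var), 0.0)
    return ContrastMap(effect=betas._unflatten(effect), t=betas._unflatten(t), df=betas.df)


def smooth_volume(data: np.ndarray, fwhm_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Separable Gaussian smoothing; sigma = FWHM / (2 sqrt(2 ln 2)) per axis.

    Circular boundary handling keeps the global mean exact; synthetic grids
    carry a zero margin so no meaningful signal wraps.
    """
    if fwhm_mm < 0:
        raise GlmError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return np.asarray(data, dtype=float).copy()
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    data = np.asarray(data, dtype=float)
    nan_mask = ~np.isfinite(data)
    if nan_mask.any():
        filled = np.where(nan_mask, 0.0, data)
        sm = ndimage.gaussian_filter(filled, sigma=sigma_vox, mode="wrap")
        weight = ndimage.gaussian_filter((~nan_mask).astype(float), sigma=sigma_vox,
                                         mode="wrap")
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(weight > 1e-12, sm / weight, np.nan)
        out[nan_mask] = np.nan
        return out
    return ndimage.gaussian_filter(data, sigma=sigma_vox, mode="wrap")
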