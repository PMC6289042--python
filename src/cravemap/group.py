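"""Second-level inference: one-sample t maps (optional covariate),
sign-flip max-statistic permutation FWE correction (whole-mask or small
volume), and cluster/peak reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage


class GroupError(ValueError):
    pass


def _stack(maps) -> np.ndarray:
    arr = np.stack([np.asarray(m, dtype=float) for m in maps]) \
        if not isinstance(maps, np.ndarray) else np.asarray(maps, dtype=float)
    if arr.shape[0] < 3:
        raise GroupError("insufficient subjects: need at least 3 maps")
    return arr


def one_sample_map(maps, null_value: float = 0.0,
                   covariate: np.ndarray | None = None,
                   mask: np.ndarray | None = None) -> tuple[np.ndarray, int]:
    """Per-voxel one-sample t of (map - null_value) against zero.

    With a covariate the t statistic is that of the intercept in a per-voxel
    regression of (map - null_value) on the centred covariate, so the tested
    mean is covariate-adjusted.
    Returns (t map, degrees of freedom).
    """
    arr = _stack(maps) - null_value
    n = arr.shape[0]
    flat = arr.reshape(n, -1)
    if covariate is None:
        mean = flat.mean(axis=0)
        sd = flat.std(axis=0, ddof=1)
        df = n - 1
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    else:
        c = np.asarray(covariate, dtype=float)
        if c.shape != (n,):
            raise GroupError("covariate length must equal number of subjects")
        c = c - c.mean()
        if np.allclose(c, 0):
            return one_sample_map(arr + null_value, null_value, None, mask)
        z = np.column_stack([np.ones(n), c])
        ztz_inv = np.linalg.inv(z.T @ z)
        beta = ztz_inv @ z.T @ flat
        resid = flat - z @ beta
        df = n - 2
        sigma2 = np.sum(resid ** 2, axis=0) / df
        se = np.sqrt(sigma2 * ztz_inv[0, 0])
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(se > 0, beta[0] / se, 0.0)
    t = t.reshape(arr.shape[1:])
    if mask is not None:
        t = np.where(mask, t, np.nan)
    return t, df


@dataclass
class FwePeakResult:
    t_map: np.ndarray
    threshold: float                # t value at the alpha quantile of max-null
    null_max: np.ndarray            # permutation distribution of the mask max
    peaks: pd.DataFrame             # voxel indices, t, corrected p
    df: int
    alpha: float

    def corrected_p(self, t_value: float) -> float:
        return float((1 + np.sum(self.null_max >= t_value)) / (1 + len(self.null_max)))


def fwe_peak_correct(maps, mask_or_roi: np.ndarray, alpha: float = 0.05,
                     n_perm: int = 1000, seed: int | np.random.Generator = 0,
                     null_value: float = 0.0,
                     covariate: np.ndarray | None = None) -> FwePeakResult:
    """Peak-level FWE by sign-flipping permutation of the subject maps.

    The null distribution is the maximum t within ``mask_or_roi`` over random
    per-subject sign flips of the (map - null_value) images; the corrected p
    of a peak is the proportion of null maxima at or above it (add-one rule).
    """
    mask = np.asarray(mask_or_roi, dtype=bool)
    if not mask.any():
        raise GroupError("empty ROI mask")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = _stack(maps) - null_value
    n = arr.shape[0]
    flat = arr.reshape(n, -1)[:, mask.ravel()]
    flat = np.nan_to_num(flat, nan=0.0)

    t_obs, df = one_sample_map(arr + null_value, null_value, covariate)
    t_obs_masked = np.where(mask, np.nan_to_num(t_obs, nan=-np.inf), -np.inf)

    null_max = np.empty(n_perm)
    for b in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)
        t_b, _ = one_sample_map(flat * signs[:, None] + null_value, null_value, covariate)
        null_max[b] = t_b.max()

    threshold = float(np.quantile(null_max, 1 - alpha))
    # local maxima above threshold: peaks of connected supra-threshold clusters
    supra = t_obs_masked >= threshold
    rows = []
    if supra.any():
        labels, n_clust = ndimage.label(supra, structure=ndimage.generate_binary_structure(3, 1))
        for k in range(1, n_clust + 1):
            in_k = labels == k
            peak_flat = np.argmax(np.where(in_k, t_obs_masked, -np.inf))
            idx = np.unravel_index(peak_flat, mask.shape)
            t_peak = float(t_obs_masked[idx])
            p = float((1 + np.sum(null_max >= t_peak)) / (1 + n_perm))
            rows.append({"i": idx[0], "j": idx[1], "k": idx[2],
                         "cluster_size": int(in_k.sum()), "t": t_peak, "p_fwe": p})
    peaks = pd.DataFrame(rows, columns=["i", "j", "k", "cluster_size", "t", "p_fwe"])
    return FwePeakResult(t_map=t_obs, threshold=threshold, null_max=null_max,
                         peaks=peaks, df=df, alpha=alpha)


def report_clusters(t_map: np.ndarray, threshold: float,
                    atlas: np.ndarray | None = None,
                    atlas_names: list[str] | None = None,
                    affine: np.ndarray | None = None) -> pd.DataFrame:
    """Connected supra-threshold clusters (face connectivity) with peak info.

    Returns one row per cluster: region label (atlas majority label at the
    peak), cluster size in voxels, peak coordinates (world mm if an affine is
    given, else voxel indices), and peak t.
    """
    if not np.isfinite(threshold):
        raise GroupError("threshold must be finite")
    t = np.nan_to_num(np.asarray(t_map, dtype=float), nan=-np.inf)
    supra = t > threshold
    rows = []
    if supra.any():
        labels, n_clust = ndimage.label(supra, structure=ndimage.generate_binary_structure(3, 1))
        for k in range(1, n_clust + 1):
            in_k = labels == k
            peak_flat = np.argmax(np.where(in_k, t, -np.inf))
            idx = np.unravel_index(peak_flat, t.shape)
            if affine is not None:
                world = (affine @ np.array([*idx, 1.0]))[:3]
            else:
                world = np.asarray(idx, dtype=float)
            region = ""
            if atlas is not None:
                lab = int(atlas[idx])
                if lab > 0 and atlas_names is not None and lab <= len(atlas_names):
                    region = atlas_names[lab - 1]
                elif lab > 0:
                    region = str(lab)
                else:
                    region = "background"
            rows.append({"region": region, "cluster_size": int(in_k.sum()),
                         "x": float(world[0]), "y": float(world[1]),
                         "z": float(world[2]), "t": float(t[idx])})
    out = pd.DataFrame(rows, columns=["region", "cluster_size", "x", "y", "z", "t"])
    return out.sort_values("cluster_size", ascending=False, ignore_index=True)
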