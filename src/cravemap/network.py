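"""Beta-series functional connectivity and network inference.

Condition-wise ROI x ROI Pearson correlation matrices are compared between
paired conditions with an edge-wise paired t on Fisher-z values.  Edge-level
p values come from within-subject condition-flip permutations; the NBS
(network-based statistic) then thresholds edges at ``link_alpha``, takes
connected components, and corrects the maximal component size against the
permutation null of the same draws.  A link-wise Benjamini-Hochberg variant
is provided as the less conservative alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata


class NetworkError(ValueError):
    pass


def extract_beta_series(trial_betas: np.ndarray, trial_conditions: list[str],
                        atlas: np.ndarray) -> dict[str, np.ndarray]:
    """ROI-mean beta series grouped by condition.

    ``trial_betas``: (n_trials, x, y, z) trial coefficient maps in trial
    order (runs concatenated); returns condition -> (n_trials_cond, n_rois).
    """
    trial_betas = np.asarray(trial_betas, dtype=float)
    if trial_betas.shape[0] != len(trial_conditions):
        raise NetworkError("trial betas and condition labels differ in length")
    atlas = np.asarray(atlas)
    n_rois = int(atlas.max())
    if n_rois < 1:
        raise NetworkError("atlas contains no regions")
    flat = trial_betas.reshape(trial_betas.shape[0], -1)
    roi_flat = atlas.ravel()
    roi_means = np.empty((trial_betas.shape[0], n_rois))
    for lab in range(1, n_rois + 1):
        sel = roi_flat == lab
        if not sel.any():
            raise NetworkError(f"ROI {lab} is empty")
        roi_means[:, lab - 1] = np.nanmean(flat[:, sel], axis=1)
    conds = np.asarray(trial_conditions)
    return {c: roi_means[conds == c] for c in dict.fromkeys(trial_conditions)}


def connectivity_matrix(series: np.ndarray) -> np.ndarray:
    """Pearson correlation over ROI beta-series (trials x ROIs).

    Zero-variance series yield NaN entries (flagged missing, not zero);
    the diagonal is fixed at 1.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise NetworkError("series must be 2D (trials x ROIs)")
    if series.shape[0] < 3:
        raise NetworkError("need at least 3 trials for a correlation")
    sd = series.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(series.T)
    bad = sd == 0
    corr[bad, :] = np.nan
    corr[:, bad] = np.nan
    np.fill_diagonal(corr, 1.0)
    return corr


def fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -0.999999, 0.999999))


def _edge_index(n_rois: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n_rois, k=1)


def _paired_t(d: np.ndarray) -> np.ndarray:
    """Paired t per column of the subject x edge difference matrix (NaN-aware)."""
    n = np.sum(np.isfinite(d), axis=0)
    mean = np.nanmean(d, axis=0)
    sd = np.nanstd(d, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where((sd > 0) & (n >= 2), mean / (sd / np.sqrt(n)), 0.0)
    return t


def _stack_edges(matrices_a, matrices_b) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    a = np.asarray(matrices_a, dtype=float)
    b = np.asarray(matrices_b, dtype=float)
    if a.shape != b.shape or a.ndim != 3 or a.shape[1] != a.shape[2]:
        raise NetworkError("conditions must be paired stacks of square matrices")
    n_subj, n_rois = a.shape[0], a.shape[1]
    if n_subj < 6:
        raise NetworkError("need at least 6 subjects for paired inference")
    iu, ju = _edge_index(n_rois)
    d = fisher_z(a[:, iu, ju]) - fisher_z(b[:, iu, ju])  # subjects x edges
    return d, iu, ju, n_rois


def edge_permutation_pvalues(matrices_a, matrices_b, n_perm: int = 1000,
                             seed: int | np.random.Generator = 0
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Edge-wise paired t stats and two-sided permutation p values.

    Permutations flip each subject's condition pair independently (sign flip
    of the within-subject difference).  Returns (t_obs, p_obs, t_perm) where
    ``t_perm`` is the (n_perm x n_edges) permutation statistic matrix, so NBS
    and link-FDR share one machinery and one set of draws.
    """
    if n_perm < 100:
        raise NetworkError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d, _, _, _ = _stack_edges(matrices_a, matrices_b)
    n_subj = d.shape[0]
    t_obs = _paired_t(d)
    t_perm = np.empty((n_perm, d.shape[1]))
    for bb in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_subj)
        t_perm[bb] = _paired_t(d * signs[:, None])
    p_obs = (1 + np.sum(np.abs(t_perm) >= np.abs(t_obs)[None, :], axis=0)) / (1 + n_perm)
    return t_obs, p_obs, t_perm


def _components(edges_i: np.ndarray, edges_j: np.ndarray, n_rois: int
                ) -> list[tuple[list[tuple[int, int]], list[int]]]:
    """Connected components of an edge set; returns (edges, nodes) per
    component with 1-based ROI labels."""
    if len(edges_i) == 0:
        return []
    graph = coo_matrix((np.ones(len(edges_i)), (edges_i, edges_j)),
                       shape=(n_rois, n_rois))
    n_comp, labels = connected_components(graph, directed=False)
    comps = []
    for c in range(n_comp):
        nodes = np.flatnonzero(labels == c)
        if len(nodes) < 2:
            continue
        sel = labels[edges_i] == c
        edges = [(int(i) + 1, int(j) + 1) for i, j in
                 zip(edges_i[sel], edges_j[sel])]
        if edges:
            comps.append((edges, [int(v) + 1 for v in nodes]))
    return comps


@dataclass
class NetworkComponent:
    edges: list[tuple[int, int]]   # 1-based ROI pairs
    nodes: list[int]
    n_edges: int
    p: float


@dataclass
class NbsResult:
    components: list[NetworkComponent]          # significant at alpha
    all_components: list[NetworkComponent]
    null_max_size: np.ndarray
    t_obs: np.ndarray
    p_obs: np.ndarray
    supra_edges: list[tuple[int, int]]
    alpha: float
    link_alpha: float


def nbs(matrices_a, matrices_b, link_alpha: float = 0.001, n_perm: int = 1000,
        alpha: float = 0.05, seed: int | np.random.Generator = 0) -> NbsResult:
    """Network-based statistic on paired condition connectivity matrices.

    Edges whose permutation p falls below ``link_alpha`` form the
    supra-threshold graph; the size (edge count) of its connected components
    is corrected against the permutation null of the maximal component size,
    computed from the same permutation draws via rank-based edge p values.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d, iu, ju, n_rois = _stack_edges(matrices_a, matrices_b)
    t_obs, p_obs, t_perm = edge_permutation_pvalues(matrices_a, matrices_b,
                                                    n_perm=n_perm, seed=rng)
    supra = p_obs < link_alpha
    obs_comps = _components(iu[supra], ju[supra], n_rois)

    # null of the maximal component size: rank each permutation statistic
    # within its edge's permutation distribution (count of >= includes self)
    abs_perm = np.abs(t_perm)
    rank_min = rankdata(abs_perm, axis=0, method="min")
    p_perm = (abs_perm.shape[0] - rank_min + 1) / (1 + n_perm)
    null_max = np.zeros(n_perm, dtype=int)
    for bb in range(n_perm):
        sel = p_perm[bb] < link_alpha
        if not sel.any():
            continue
        comps = _components(iu[sel], ju[sel], n_rois)
        if comps:
            null_max[bb] = max(len(e) for e, _ in comps)

    all_components = []
    for edges, nodes in obs_comps:
        size = len(edges)
        p = float((1 + np.sum(null_max >= size)) / (1 + n_perm))
        all_components.append(NetworkComponent(edges=edges, nodes=nodes,
                                               n_edges=size, p=p))
    all_components.sort(key=lambda comp: comp.p)
    significant = [c for c in all_components if c.p < alpha]
    supra_edges = [(int(i) + 1, int(j) + 1) for i, j in zip(iu[supra], ju[supra])]
    return NbsResult(components=significant, all_components=all_components,
                     null_max_size=null_max, t_obs=t_obs, p_obs=p_obs,
                     supra_edges=supra_edges, alpha=alpha, link_alpha=link_alpha)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


@dataclass
class LinkFdrResult:
    edges: list[tuple[int, int]]
    components: list[NetworkComponent]          # p field = NaN (descriptive)
    p_obs: np.ndarray
    p_adjusted: np.ndarray
    q: float


def link_fdr(matrices_a, matrices_b, q: float = 0.001, n_perm: int = 1000,
             seed: int | np.random.Generator = 0) -> LinkFdrResult:
    """Link-wise FDR: BH step-up over edge permutation p values at level q.

    Returns the surviving edges plus the connected components they form.
    """
    _, iu, ju, n_rois = _stack_edges(matrices_a, matrices_b)
    _, p_obs, _ = edge_permutation_pvalues(matrices_a, matrices_b,
                                           n_perm=n_perm, seed=seed)
    p_adj = bh_adjust(p_obs)
    sel = p_adj < q
    edges = [(int(i) + 1, int(j) + 1) for i, j in zip(iu[sel], ju[sel])]
    comps = [NetworkComponent(edges=e, nodes=n, n_edges=len(e), p=float("nan"))
             for e, n in _components(iu[sel], ju[sel], n_rois)]
    return LinkFdrResult(edges=edges, components=comps, p_obs=p_obs,
                         p_adjusted=p_adj, q=q)


def matrices_to_frame(matrix: np.ndarray, roi_names: list[str]) -> pd.DataFrame:
    return pd.DataFrame(matrix, index=roi_names, columns=roi_names)
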