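"""Searchlight decoding of strategy with cross-classification over cues.

For every sphere centre, a linear support vector classifier (C = 1) is
trained on the per-run beta patterns of one cue and tested on the other cue's
patterns of a held-out run (leave-one-run-out; both cue-role assignments
averaged), so only cue-invariant strategy information scores above chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .glm import BetaMaps

STRATEGIES = ("positive", "negative")
CUES = (1, 2)


class SearchlightError(ValueError):
    pass


def sphere_offsets(radius: int) -> np.ndarray:
    """Integer offsets (dx, dy, dz) with Euclidean norm <= radius."""
    if radius < 0:
        raise SearchlightError("radius must be >= 0")
    r = int(radius)
    grid = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(grid, grid, grid, indexing="ij")
    keep = dx ** 2 + dy ** 2 + dz ** 2 <= radius ** 2
    return np.column_stack([dx[keep], dy[keep], dz[keep]])


@dataclass
class SearchlightSpec:
    mask: np.ndarray
    radius_voxels: int = 3
    min_voxels: int = 10
    svc_c: float = 1.0

    def __post_init__(self) -> None:
        if self.radius_voxels < 0:
            raise SearchlightError("radius must be >= 0")
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class PatternSet:
    """Per run x strategy x cue voxel patterns over the in-mask voxels."""

    patterns: np.ndarray            # (n_runs, 2 strategies, 2 cues, n_voxels)
    mask: np.ndarray                # 3D boolean
    voxel_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    # flat position within the mask for each 3D in-mask voxel

    def __post_init__(self) -> None:
        if self.patterns.ndim != 4 or self.patterns.shape[1:3] != (2, 2):
            raise SearchlightError("patterns must have shape (runs, 2, 2, voxels)")
        if self.patterns.shape[3] != int(self.mask.sum()):
            raise SearchlightError("pattern length must equal mask voxel count")
        lut = np.full(self.mask.shape, -1, dtype=np.int64)
        lut[self.mask] = np.arange(int(self.mask.sum()))
        self.voxel_index = lut

    @property
    def n_runs(self) -> int:
        return self.patterns.shape[0]


def build_pattern_set(beta_maps_by_run: list[BetaMaps], mask: np.ndarray) -> PatternSet:
    """Stack per-run MVPA beta maps into a PatternSet.

    Expects each run's fit to carry the four strategy x cue columns named
    ``positive_cue1`` .. ``negative_cue2``.
    """
    mask = np.asarray(mask, dtype=bool)
    stacked = []
    for bm in beta_maps_by_run:
        per_run = np.empty((2, 2, int(mask.sum())))
        for i, strat in enumerate(STRATEGIES):
            for j, cue in enumerate(CUES):
                name = f"{strat}_cue{cue}"
                if name not in bm.columns:
                    raise SearchlightError(f"missing beta map {name!r} in run fit")
                per_run[i, j] = bm.beta_map(name)[mask]
        stacked.append(per_run)
    return PatternSet(patterns=np.stack(stacked), mask=mask)


def _fold_accuracy(pat: np.ndarray, c: float) -> float:
    """Mean cross-classification accuracy over folds and cue-role assignments.

    ``pat``: (n_runs, 2 strategies, 2 cues, n_features).
    """
    n_runs = pat.shape[0]
    y_train = np.repeat([0, 1], n_runs - 1)
    correct = 0
    total = 0
    for test_run in range(n_runs):
        train_runs = [r for r in range(n_runs) if r != test_run]
        for train_cue, test_cue in ((0, 1), (1, 0)):
            x_train = np.concatenate([pat[train_runs, 0, train_cue],
                                      pat[train_runs, 1, train_cue]])
            x_test = pat[test_run, :, test_cue]
            clf = SVC(kernel="linear", C=c)
            clf.fit(x_train, y_train)
            pred = clf.predict(x_test)
            correct += int(np.sum(pred == np.array([0, 1])))
            total += 2
    return correct / total


@dataclass
class AccuracyMap:
    accuracy: np.ndarray            # 3D, NaN outside mask / at skipped centres
    n_folds: int
    skipped: np.ndarray             # 3D boolean: centres with too few voxels
    chance: np.ndarray | None = None

    def mean_accuracy(self) -> float:
        return float(np.nanmean(self.accuracy))


def cross_classify_searchlight(patterns: PatternSet,
                               spec: SearchlightSpec) -> AccuracyMap:
    """Cross-cue leave-one-run-out searchlight decoding of strategy."""
    if patterns.n_runs < 2:
        raise SearchlightError("need at least two runs for leave-one-run-out")
    offsets = sphere_offsets(spec.radius_voxels)
    mask = spec.mask
    shape = mask.shape
    accuracy = np.full(shape, np.nan)
    skipped = np.zeros(shape, dtype=bool)
    centers = np.argwhere(mask)
    lut = patterns.voxel_index
    for center in centers:
        pos = center + offsets
        ok = np.all((pos >= 0) & (pos < shape), axis=1)
        pos = pos[ok]
        idx = lut[pos[:, 0], pos[:, 1], pos[:, 2]]
        idx = idx[idx >= 0]
        if len(idx) < spec.min_voxels:
            skipped[tuple(center)] = True
            continue
        pat = patterns.patterns[..., idx]
        accuracy[tuple(center)] = _fold_accuracy(pat, spec.svc_c)
    return AccuracyMap(accuracy=accuracy, n_folds=patterns.n_runs, skipped=skipped)


def permutation_chance_map(patterns: PatternSet, spec: SearchlightSpec,
                           n_perm: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Voxel-wise empirical chance: mean accuracy over within-run label flips.

    Each permutation flips the strategy labels of a random subset of runs
    (both cues of a run flip together, preserving the cue structure), then
    the full cross-cue searchlight decoding is rerun.
    """
    if n_perm < 1:
        raise SearchlightError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    acc_sum = np.zeros(spec.mask.shape)
    count = np.zeros(spec.mask.shape)
    for _b in range(n_perm):
        flips = rng.integers(0, 2, patterns.n_runs).astype(bool)
        perm = patterns.patterns.copy()
        perm[flips] = perm[flips][:, ::-1]
        pset = PatternSet(patterns=perm, mask=spec.mask)
        amap = cross_classify_searchlight(pset, spec)
        good = np.isfinite(amap.accuracy)
        acc_sum[good] += amap.accuracy[good]
        count[good] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        chance = np.where(count > 0, acc_sum / count, np.nan)
    return chance
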