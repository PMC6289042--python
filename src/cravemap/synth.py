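"""Synthetic experiment generator.

Emulates the study design so every downstream stage is testable without any
acquisition: 3 conditions x 12 trials per run over 5 runs, two visual cues
per condition balanced within run, 2 s cue + 6 +/- 1 s image epochs,
10 +/- 4 s inter-trial intervals, TR 2 s and 380 frames per run.  Jitters use
balanced discrete multisets (image duration over {5,6,7} s, ITI over
{6..14} s) so run timing is exactly reproducible and never overflows the run.

Also provides phantom parcellations (BFS-Voronoi growth from spread seeds),
a BOLD simulator whose signal model mirrors the first-level GLM, rating
generators, and a direct beta-series generator for connectivity tests.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import glm
from .config import PipelineConfig
from .io import CONDITIONS, Volume4D

RATING_DURATION_S = 3.0
CUE_DURATION_S = 2.0


class DesignError(ValueError):
    pass


@dataclass
class TrialEvent:
    onset_s: float
    image_duration_s: float
    iti_s: float
    condition: str
    cue_id: int
    stimulus_id: int
    cue_duration_s: float = CUE_DURATION_S

    @property
    def epoch_duration_s(self) -> float:
        """Duration of the modelled task epoch (cue + image)."""
        return self.cue_duration_s + self.image_duration_s


@dataclass
class ExperimentDesign:
    subject_id: int
    runs: list[list[TrialEvent]]
    stimulus_condition: dict[int, str]

    def events_frame(self) -> pd.DataFrame:
        rows = []
        for r, run in enumerate(self.runs, start=1):
            for ev in run:
                rows.append({"onset": ev.onset_s, "duration": ev.epoch_duration_s,
                             "condition": ev.condition, "cue_id": ev.cue_id,
                             "stimulus_id": ev.stimulus_id, "run": r})
        return pd.DataFrame(rows)


def _constrained_condition_order(per_cond: int, rng: np.random.Generator,
                                 max_run: int = 3, max_tries: int = 2000) -> list[str]:
    """Shuffle condition labels with no more than ``max_run`` consecutive repeats."""
    labels = np.repeat(np.array(CONDITIONS, dtype=object), per_cond)
    for _ in range(max_tries):
        order = rng.permutation(labels)
        run_len, worst = 1, 1
        for a, b in zip(order[:-1], order[1:]):
            run_len = run_len + 1 if a == b else 1
            worst = max(worst, run_len)
        if worst <= max_run:
            return list(order)
    raise DesignError("could not satisfy pseudorandomization constraint")


def _balanced_multiset(values: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` draws cycling through ``values`` equally, then shuffled (fixed sum)."""
    if n % len(values) != 0:
        raise DesignError(f"{n} trials cannot balance over {len(values)} jitter values")
    return rng.permutation(np.tile(values, n // len(values)))


def generate_design(config: PipelineConfig, seed: int | None = None) -> list[ExperimentDesign]:
    """Generate one ``ExperimentDesign`` per subject.

    The stimulus-to-condition assignment rotates cyclically across subjects;
    within a subject every stimulus appears once per run under its assigned
    condition, and each condition's two cues are balanced within run.
    """
    per_cond = config.trials_per_run // 3
    if per_cond % 2 != 0:
        raise DesignError("per-condition trial count must be even for cue balance")
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    subject_seeds = ss.spawn(config.n_subjects)

    n_stimuli = config.trials_per_run  # one trial per stimulus per run
    designs = []
    for s in range(config.n_subjects):
        rng = np.random.default_rng(subject_seeds[s])
        rotation = s % 3
        stim_cond: dict[int, str] = {}
        for c, cond in enumerate(CONDITIONS):
            block = (c + rotation) % 3
            for stim in range(block * per_cond, (block + 1) * per_cond):
                stim_cond[stim] = cond

        runs = []
        for _r in range(config.n_runs):
            order = _constrained_condition_order(per_cond, rng)
            image_durs = _balanced_multiset(np.array([5.0, 6.0, 7.0]),
                                            config.trials_per_run, rng)
            itis = _balanced_multiset(np.arange(6.0, 15.0),
                                      config.trials_per_run, rng)
            cues: dict[str, list[int]] = {}
            stims: dict[str, list[int]] = {}
            for cond in CONDITIONS:
                cues[cond] = list(rng.permutation([1, 2] * (per_cond // 2)))
                pool = [k for k, v in stim_cond.items() if v == cond]
                stims[cond] = list(rng.permutation(pool))
            t = 0.0
            trials = []
            for i, cond in enumerate(order):
                ev = TrialEvent(onset_s=t, image_duration_s=float(image_durs[i]),
                                iti_s=float(itis[i]), condition=cond,
                                cue_id=cues[cond].pop(), stimulus_id=stims[cond].pop())
                trials.append(ev)
                t += ev.epoch_duration_s + RATING_DURATION_S + ev.iti_s
            if t > config.run_length_s:
                raise DesignError(
                    f"run timing {t:.1f}s overflows run length {config.run_length_s:.1f}s")
            runs.append(trials)
        designs.append(ExperimentDesign(subject_id=s, runs=runs,
                                        stimulus_condition=stim_cond))
    assert n_stimuli == len(designs[0].stimulus_condition)
    return designs


# ---------------------------------------------------------------------------
# phantom atlas

def brain_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoid 'brain' mask inscribed in the grid (background = False)."""
    axes = [(np.arange(n) - (n - 1) / 2.0) / max((n - 1) / 2.0, 1e-9)
            for n in grid_shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return xx ** 2 + yy ** 2 + zz ** 2 <= 1.0 + 1e-12


_NEIGHBORS = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                       [0, -1, 0], [0, 0, 1], [0, 0, -1]])


def generate_phantom_atlas(n_regions: int, grid_shape: tuple[int, int, int],
                           seed: int | np.random.Generator = 0,
                           min_voxels: int = 4) -> tuple[np.ndarray, list[str]]:
    """Partition the interior mask into ``n_regions`` contiguous parcels.

    Seeds are spread through the mask and regions grown by multi-source BFS,
    so every parcel is face-connected.  Returns the integer label volume
    (0 = background) and region names ``R001..``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = brain_mask(grid_shape)
    coords = np.argwhere(mask)
    m = len(coords)
    if n_regions < 1:
        raise DesignError("n_regions must be >= 1")
    if n_regions * min_voxels > m:
        raise DesignError(
            f"grid too small: {m} mask voxels cannot hold {n_regions} regions "
            f"of >= {min_voxels} voxels")

    for _attempt in range(30):
        # stratified seed picks along the lexicographic voxel order
        u = rng.random(n_regions)
        pos = np.unique(((np.arange(n_regions) + u) * m / n_regions).astype(int))
        if len(pos) < n_regions:
            continue
        labels = np.zeros(grid_shape, dtype=np.int64)
        queue: deque = deque()
        for lab, p in enumerate(pos, start=1):
            c = coords[p]
            labels[tuple(c)] = lab
            queue.append(c)
        while queue:
            c = queue.popleft()
            lab = labels[tuple(c)]
            for d in _NEIGHBORS:
                nb = c + d
                if np.any(nb < 0) or np.any(nb >= grid_shape):
                    continue
                tnb = tuple(nb)
                if mask[tnb] and labels[tnb] == 0:
                    labels[tnb] = lab
                    queue.append(nb)
        sizes = np.bincount(labels[mask], minlength=n_regions + 1)[1:]
        if np.all(sizes >= min_voxels):
            names = [f"R{j:03d}" for j in range(1, n_regions + 1)]
            return labels, names
    raise DesignError("failed to grow regions of the requested minimum size")


# ---------------------------------------------------------------------------
# effect specification and BOLD simulation

@dataclass
class EffectSpec:
    """Planted signal structure for the BOLD simulator.

    ``univariate_regions`` maps condition -> (3D mask, amplitude); ``pattern``
    is a 3D per-voxel weight map applied with opposite sign to the two
    regulation strategies (identical for both cues, i.e. cue-invariant);
    ``connectivity`` optionally plants trial-amplitude correlations between
    atlas regions (edges get ``base_r + delta_r`` in the positive condition).
    """

    noise_sd: float = 1.0
    ar1_rho: float = 0.3
    drift_amplitude: float = 0.0
    baseline: float = 100.0
    univariate_regions: dict[str, tuple[np.ndarray, float]] = field(default_factory=dict)
    pattern: np.ndarray | None = None
    connectivity: tuple[np.ndarray, list[tuple[int, int]], float, float, float] | None = None
    # (atlas labels, subnetwork edges (1-based), base_r, delta_r, jitter_sd)

    def __post_init__(self) -> None:
        if not (0 <= self.ar1_rho < 1):
            raise DesignError("ar1_rho must lie in [0, 1)")
        if self.noise_sd < 0:
            raise DesignError("noise_sd must be nonnegative")


def _target_correlation(n_rois: int, edges: list[tuple[int, int]], base_r: float,
                        delta_r: float) -> tuple[np.ndarray, np.ndarray]:
    """Target trial-amplitude correlation matrices (negative, positive)."""
    c_neg = np.full((n_rois, n_rois), base_r)
    np.fill_diagonal(c_neg, 1.0)
    c_pos = c_neg.copy()
    for i, j in edges:
        a, b = i - 1, j - 1
        if a == b:
            raise DesignError("self-edge in connectivity subnetwork")
        c_pos[a, b] += delta_r
        c_pos[b, a] += delta_r
    for c in (c_neg, c_pos):
        try:
            np.linalg.cholesky(c + 1e-10 * np.eye(n_rois))
        except np.linalg.LinAlgError as exc:
            raise DesignError("target correlation matrix is not positive "
                              "semidefinite") from exc
    return c_neg, c_pos


def ar1_noise(shape: tuple[int, ...], rho: float, sd: float,
              rng: np.random.Generator) -> np.ndarray:
    """AR(1) Gaussian noise along the last axis with marginal SD ``sd``."""
    white = rng.standard_normal(shape)
    if rho == 0 or sd == 0:
        return white * sd
    out = np.empty_like(white)
    out[..., 0] = white[..., 0]
    for t in range(1, shape[-1]):
        out[..., t] = rho * out[..., t - 1] + np.sqrt(1 - rho ** 2) * white[..., t]
    return out * sd


def simulate_motion(n_frames: int, rng: np.random.Generator,
                    scale: float = 0.05) -> np.ndarray:
    """Six slow, smooth motion-parameter traces (random walk, low-passed)."""
    from scipy.ndimage import uniform_filter1d
    steps = rng.standard_normal((n_frames, 6)) * scale
    walk = np.cumsum(steps, axis=0)
    return uniform_filter1d(walk, size=min(11, n_frames), axis=0, mode="nearest")


def simulate_bold(run_events: pd.DataFrame, effect_spec: EffectSpec,
                  config: PipelineConfig, rng: np.random.Generator) -> Volume4D:
    """Simulate one run of 4D BOLD data under the first-level signal model.

    signal = baseline + sum_c amplitude_map_c * HRF-convolved condition boxcar
             + pattern * (positive - negative regressor)
             + optional per-trial connectivity jitter + cosine drift
             + AR(1) Gaussian noise.
    """
    shape = config.grid_shape
    n_frames = config.n_volumes
    frame_times = np.arange(n_frames) * config.tr_s
    n_vox = int(np.prod(shape))
    sig = np.zeros((n_vox, n_frames))

    onsets = run_events["onset"].to_numpy(dtype=float)
    durations = run_events["duration"].to_numpy(dtype=float)
    conditions = run_events["condition"].to_numpy()
    for cond, (mask, amp) in effect_spec.univariate_regions.items():
        if mask.shape != shape:
            raise DesignError("effect region mask does not match the grid")
        sel = conditions == cond
        reg = glm.epoch_regressor(onsets[sel], durations[sel], frame_times,
                                  config.glm.hrf_dt)
        sig += np.outer(mask.ravel() * amp, reg)

    if effect_spec.pattern is not None:
        if effect_spec.pattern.shape != shape:
            raise DesignError("pattern map does not match the grid")
        reg_p = glm.epoch_regressor(onsets[conditions == "positive"],
                                    durations[conditions == "positive"],
                                    frame_times, config.glm.hrf_dt)
        reg_n = glm.epoch_regressor(onsets[conditions == "negative"],
                                    durations[conditions == "negative"],
                                    frame_times, config.glm.hrf_dt)
        sig += np.outer(effect_spec.pattern.ravel(), reg_p - reg_n)

    if effect_spec.connectivity is not None:
        atlas, edges, base_r, delta_r, jitter_sd = effect_spec.connectivity
        n_rois = int(atlas.max())
        c_neg, c_pos = _target_correlation(n_rois, edges, base_r, delta_r)
        chol = {"negative": np.linalg.cholesky(c_neg + 1e-10 * np.eye(n_rois)),
                "positive": np.linalg.cholesky(c_pos + 1e-10 * np.eye(n_rois))}
        roi_flat = atlas.ravel()
        indicator = np.zeros((n_rois, n_vox))
        for rlab in range(1, n_rois + 1):
            indicator[rlab - 1, roi_flat == rlab] = 1.0
        for cond in ("positive", "negative"):
            idx = np.flatnonzero(conditions == cond)
            amps = (rng.standard_normal((len(idx), n_rois)) @ chol[cond].T) * jitter_sd
            regs = np.column_stack([
                glm.epoch_regressor(onsets[i], durations[i], frame_times,
                                    config.glm.hrf_dt) for i in idx])
            sig += (amps @ indicator).T @ regs.T

    if effect_spec.drift_amplitude > 0:
        basis = glm.highpass_basis(n_frames, config.tr_s, 1.0 / 256.0)
        if basis.shape[1]:
            coef = rng.standard_normal((n_vox, basis.shape[1])) * effect_spec.drift_amplitude
            sig += coef @ basis.T

    noise = ar1_noise((n_vox, n_frames), effect_spec.ar1_rho, effect_spec.noise_sd, rng)
    data = (effect_spec.baseline + sig + noise).reshape(*shape, n_frames)
    return Volume4D(data=data, voxel_size_mm=config.voxel_size_mm, tr_s=config.tr_s)


def default_effect_spec(config: PipelineConfig, atlas: np.ndarray | None = None,
                        seed: int | np.random.Generator = 0) -> EffectSpec:
    """Desk-scale default planted effects.

    One interior block carries a univariate regulation amplitude (positive and
    negative conditions), a disjoint block carries the cue-invariant strategy
    pattern, and (when an atlas is given) a 5-ROI clique gains correlated
    trial amplitudes in the positive condition.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eff = config.effects
    mask = brain_mask(config.grid_shape)
    nx, ny, nz = config.grid_shape
    uni_mask = np.zeros(config.grid_shape, dtype=bool)
    uni_mask[nx // 4: nx // 2, ny // 4: ny // 2, nz // 4: nz // 2] = True
    uni_mask &= mask
    pat_mask = np.zeros(config.grid_shape, dtype=bool)
    pat_mask[nx // 2: 3 * nx // 4, ny // 2: 3 * ny // 4, nz // 2: 3 * nz // 4] = True
    pat_mask &= mask
    pattern = np.zeros(config.grid_shape)
    pattern[pat_mask] = rng.choice([-1.0, 1.0], size=int(pat_mask.sum())) \
        * eff.pattern_amplitude
    connectivity = None
    if atlas is not None and atlas.max() >= 5:
        hub = [1, 2, 3, 4, 5]
        edges = [(a, b) for i, a in enumerate(hub) for b in hub[i + 1:]]
        connectivity = (atlas, edges, config.nbs.base_r,
                        eff.connectivity_delta_r, eff.beta_jitter_sd)
    return EffectSpec(
        noise_sd=eff.noise_sd, ar1_rho=eff.ar1_rho,
        drift_amplitude=eff.drift_amplitude,
        univariate_regions={"positive": (uni_mask, eff.univariate_amplitude),
                            "negative": (uni_mask, eff.univariate_amplitude)},
        pattern=pattern, connectivity=connectivity)


# ---------------------------------------------------------------------------
# ratings

def simulate_ratings(design: ExperimentDesign, condition_means: dict[str, float],
                     sd: float, rng: np.random.Generator) -> pd.DataFrame:
    """Per-trial 5-point craving ratings: Gaussian around the condition mean,
    rounded and clipped to {1..5}."""
    for cond, mu in condition_means.items():
        if not (1.0 <= mu <= 5.0):
            raise DesignError(f"condition mean {mu} for {cond!r} outside [1, 5]")
    table = design.events_frame()
    mus = table["condition"].map(condition_means).to_numpy(dtype=float)
    raw = mus + rng.standard_normal(len(table)) * sd
    table["rating"] = np.clip(np.round(raw), 1, 5).astype(int)
    table["subject"] = design.subject_id
    return table


def simulate_baseline_ratings(design: ExperimentDesign, sd: float,
                              rng: np.random.Generator,
                              grand_mean: float = 3.0) -> pd.DataFrame:
    """Pre-experiment per-stimulus craving ratings (no condition effect)."""
    rows = []
    for stim, cond in sorted(design.stimulus_condition.items()):
        raw = grand_mean + rng.standard_normal() * sd
        rows.append({"subject": design.subject_id, "stimulus_id": stim,
                     "condition": cond,
                     "rating": int(np.clip(np.round(raw), 1, 5))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# direct beta-series generator (fast path for network tests)

def simulate_beta_series(n_subjects: int, n_rois: int, trials_per_condition: int,
                         subnetwork: list[tuple[int, int]], delta_r: float,
                         seed: int | np.random.Generator = 0,
                         base_r: float = 0.2) -> dict[str, np.ndarray]:
    """Trial x ROI beta-series per subject and condition.

    Off-subnetwork ROI pairs share the same expected correlation ``base_r``
    in both conditions; subnetwork edges (1-based ROI pairs) gain ``delta_r``
    in the positive condition.  Returns ``{"positive": A, "negative": B}``
    with arrays of shape (n_subjects, trials_per_condition, n_rois).
    """
    if n_rois < 2:
        raise DesignError("need at least two ROIs to form edges")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c_neg, c_pos = _target_correlation(n_rois, subnetwork, base_r, delta_r)
    chol_neg = np.linalg.cholesky(c_neg + 1e-10 * np.eye(n_rois))
    chol_pos = np.linalg.cholesky(c_pos + 1e-10 * np.eye(n_rois))
    out = {}
    for cond, chol in (("positive", chol_pos), ("negative", chol_neg)):
        z = rng.standard_normal((n_subjects, trials_per_condition, n_rois))
        out[cond] = z @ chol.T
    return out
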