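"""End-to-end orchestration: simulate -> glm -> mvpa -> group ->
connectivity -> behavior, each stage consuming only files written by prior
stages plus the config, so stages can be rerun in isolation.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as behavior_mod
from . import glm, group, network, searchlight, synth
from .config import PipelineConfig
from .io import (CONDITIONS, default_affine, read_events, read_label_volume,
                 read_map, read_volume, write_events, write_label_volume,
                 write_map, write_volume)

log = logging.getLogger("cravemap")

CONTRASTS = {
    "regulation-gt-now": {"positive": 0.5, "negative": 0.5, "now": -1.0},
    "negative-gt-positive": {"negative": 1.0, "positive": -1.0},
    "positive-gt-negative": {"positive": 1.0, "negative": -1.0},
}

STAGES = ("simulate", "glm", "mvpa", "group", "connectivity", "behavior")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _setup_logging(out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)


def _rng_for(config: PipelineConfig, stage: str) -> np.random.Generator:
    # stable per-stage substream derived from the one pipeline seed
    key = sum(ord(c) for c in stage)
    return np.random.default_rng(np.random.SeedSequence([config.seed, key]))


def _sub(i: int) -> str:
    return f"sub-{i + 1:02d}"


def stage_simulate(config: PipelineConfig, out: Path) -> None:
    """Designs, events, motion, ratings, atlas and BOLD volumes."""
    design_dir = out / "design"
    bold_dir = out / "bold"
    design_dir.mkdir(parents=True, exist_ok=True)
    bold_dir.mkdir(parents=True, exist_ok=True)
    log.info("simulate: seed=%d subjects=%d grid=%s", config.seed,
             config.n_subjects, config.grid_shape)

    designs = synth.generate_design(config)
    atlas_rng = _rng_for(config, "atlas")
    atlas, names = synth.generate_phantom_atlas(config.nbs.n_rois,
                                                config.grid_shape, atlas_rng)
    write_label_volume(atlas, config.voxel_size_mm, design_dir / "atlas.nii")
    pd.DataFrame({"label": np.arange(1, len(names) + 1), "name": names}) \
        .to_csv(design_dir / "atlas_labels.tsv", sep="\t", index=False)

    spec = synth.default_effect_spec(config, atlas, _rng_for(config, "effects"))
    snap = {"noise_sd": spec.noise_sd, "ar1_rho": spec.ar1_rho,
            "drift_amplitude": spec.drift_amplitude,
            "univariate_amplitude": config.effects.univariate_amplitude,
            "pattern_amplitude": config.effects.pattern_amplitude,
            "connectivity_delta_r": config.effects.connectivity_delta_r}
    (design_dir / "effect_spec.yaml").write_text(yaml.safe_dump(snap))

    ratings_rng = _rng_for(config, "ratings")
    baseline_rng = _rng_for(config, "baseline")
    bold_rng = _rng_for(config, "bold")
    motion_rng = _rng_for(config, "motion")

    all_ratings, all_baseline = [], []
    for s, design in enumerate(designs):
        events = design.events_frame()
        for r in range(1, config.n_runs + 1):
            run_events = events[events["run"] == r].reset_index(drop=True)
            write_events(run_events, design_dir / f"{_sub(s)}_run-{r}_events.tsv")
            motion = synth.simulate_motion(config.n_volumes, motion_rng)
            pd.DataFrame(motion, columns=[f"motion_{k}" for k in range(1, 7)]) \
                .to_csv(design_dir / f"{_sub(s)}_run-{r}_motion.tsv",
                        sep="\t", index=False)
            vol = synth.simulate_bold(run_events, spec, config, bold_rng)
            write_volume(vol, bold_dir / f"{_sub(s)}_run-{r}_bold.nii")
        all_ratings.append(synth.simulate_ratings(
            design, config.behavior.condition_means, config.behavior.rating_sd,
            ratings_rng))
        all_baseline.append(synth.simulate_baseline_ratings(
            design, config.behavior.rating_sd, baseline_rng))
    pd.concat(all_ratings, ignore_index=True) \
        .to_csv(design_dir / "ratings.tsv", sep="\t", index=False)
    pd.concat(all_baseline, ignore_index=True) \
        .to_csv(design_dir / "baseline_ratings.tsv", sep="\t", index=False)


def _load_run(config: PipelineConfig, out: Path, s: int, r: int):
    events = read_events(out / "design" / f"{_sub(s)}_run-{r}_events.tsv")
    motion = pd.read_csv(out / "design" / f"{_sub(s)}_run-{r}_motion.tsv",
                         sep="\t").to_numpy()
    vol = read_volume(out / "bold" / f"{_sub(s)}_run-{r}_bold.nii")
    return events, motion, vol


def stage_glm(config: PipelineConfig, out: Path) -> None:
    """Per-subject first-level fits for all three design variants."""
    glm_dir = out / "glm"
    glm_dir.mkdir(parents=True, exist_ok=True)
    mask = synth.brain_mask(config.grid_shape)
    for s in range(config.n_subjects):
        effects = {name: [] for name in CONTRASTS}
        trial_maps, trial_conds = [], []
        for r in range(1, config.n_runs + 1):
            events, motion, vol = _load_run(config, out, s, r)
            for mode in ("univariate", "mvpa", "beta_series"):
                design = glm.build_design_matrix(
                    events, mode, motion, config.tr_s, config.n_volumes,
                    config.glm.highpass_hz, config.glm.rating_duration_s,
                    config.glm.hrf_dt)
                fit = glm.fit_glm(vol, design, mask)
                if mode == "univariate":
                    design.matrix.to_csv(
                        glm_dir / f"{_sub(s)}_run-{r}_design.tsv", sep="\t",
                        index=False)
                    for name, weights in CONTRASTS.items():
                        cmap = glm.compute_contrast(fit, weights)
                        effects[name].append(cmap.effect)
                elif mode == "mvpa":
                    for col in design.condition_columns:
                        write_map(fit.beta_map(col), config.voxel_size_mm,
                                  glm_dir / f"{_sub(s)}_run-{r}_beta-{col}.nii")
                else:
                    for col in design.condition_columns:
                        trial_maps.append(fit.beta_map(col))
                        trial_conds.append(design.trial_conditions[col])
        for name, maps in effects.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # out-of-mask NaNs
                avg = np.nanmean(maps, axis=0)
            write_map(avg, config.voxel_size_mm,
                      glm_dir / f"{_sub(s)}_contrast-{name}.nii")
        stack = np.stack([np.nan_to_num(m, nan=0.0) for m in trial_maps], axis=-1)
        from .io import Volume4D
        write_volume(Volume4D(stack, config.voxel_size_mm, config.tr_s),
                     glm_dir / f"{_sub(s)}_trial-betas.nii")
        pd.DataFrame({"trial": np.arange(1, len(trial_conds) + 1),
                      "condition": trial_conds}) \
            .to_csv(glm_dir / f"{_sub(s)}_trial-conditions.tsv", sep="\t",
                    index=False)
        log.info("glm: %s done (rho last fit n/a)", _sub(s))


def stage_mvpa(config: PipelineConfig, out: Path) -> None:
    """Searchlight cross-classification plus permutation chance maps."""
    mvpa_dir = out / "mvpa"
    mvpa_dir.mkdir(parents=True, exist_ok=True)
    mask = synth.brain_mask(config.grid_shape)
    spec = searchlight.SearchlightSpec(mask=mask,
                                       radius_voxels=config.mvpa.radius_voxels,
                                       min_voxels=config.mvpa.min_sphere_voxels,
                                       svc_c=config.mvpa.svc_c)
    rng = _rng_for(config, "mvpa")
    log.info("mvpa: n_perm_chance=%d seed=%d", config.mvpa.n_perm_chance,
             config.seed)
    for s in range(config.n_subjects):
        pats = np.empty((config.n_runs, 2, 2, int(mask.sum())))
        for r in range(1, config.n_runs + 1):
            for i, strat in enumerate(searchlight.STRATEGIES):
                for j, cue in enumerate(searchlight.CUES):
                    data, _ = read_map(
                        out / "glm" / f"{_sub(s)}_run-{r}_beta-{strat}_cue{cue}.nii")
                    pats[r - 1, i, j] = data[mask]
        pset = searchlight.PatternSet(patterns=pats, mask=mask)
        amap = searchlight.cross_classify_searchlight(pset, spec)
        chance = searchlight.permutation_chance_map(pset, spec,
                                                    config.mvpa.n_perm_chance, rng)
        write_map(amap.accuracy, config.voxel_size_mm,
                  mvpa_dir / f"{_sub(s)}_accuracy.nii")
        write_map(chance, config.voxel_size_mm, mvpa_dir / f"{_sub(s)}_chance.nii")
        skipped = np.argwhere(amap.skipped)
        pd.DataFrame(skipped, columns=["i", "j", "k"]) \
            .to_csv(mvpa_dir / f"{_sub(s)}_skipped.tsv", sep="\t", index=False)


def _covariate(out: Path) -> np.ndarray:
    ratings = pd.read_csv(out / "design" / "ratings.tsv", sep="\t")
    summary = behavior_mod.summarize_ratings(ratings)
    return (summary["positive"] - summary["negative"]).to_numpy()


def stage_group(config: PipelineConfig, out: Path) -> None:
    """Second-level permutation FWE inference and Table-style peak reports."""
    if config.n_subjects < 3:
        raise ValueError("insufficient subjects for group inference (need >= 3)")
    group_dir = out / "group"
    group_dir.mkdir(parents=True, exist_ok=True)
    mask = synth.brain_mask(config.grid_shape)
    atlas, _ = read_label_volume(out / "design" / "atlas.nii")
    names = pd.read_csv(out / "design" / "atlas_labels.tsv", sep="\t")["name"].tolist()
    affine = default_affine(config.voxel_size_mm, config.grid_shape)
    covariate = _covariate(out)
    rng = _rng_for(config, "group")
    log.info("group: n_perm=%d alpha=%.3f seed=%d", config.group.n_perm,
             config.group.alpha, config.seed)

    def run_family(maps: list[np.ndarray], null_value: float, tag: str) -> None:
        sm = [glm.smooth_volume(m, config.glm.smooth_fwhm_mm, config.voxel_size_mm)
              for m in maps]
        res = group.fwe_peak_correct(sm, mask, config.group.alpha,
                                     config.group.n_perm, rng,
                                     null_value=null_value, covariate=covariate)
        table = group.report_clusters(np.where(mask, res.t_map, np.nan),
                                      res.threshold, atlas, names, affine)
        table["p_fwe"] = [res.corrected_p(t) for t in table["t"]]
        table.to_csv(group_dir / f"{tag}_peaks.tsv", sep="\t", index=False)
        write_map(np.where(mask, res.t_map, np.nan), config.voxel_size_mm,
                  group_dir / f"{tag}_tmap.nii")

    for name in CONTRASTS:
        maps = [read_map(out / "glm" / f"{_sub(s)}_contrast-{name}.nii")[0]
                for s in range(config.n_subjects)]
        run_family(maps, 0.0, f"univariate_{name}")

    acc = [read_map(out / "mvpa" / f"{_sub(s)}_accuracy.nii")[0]
           for s in range(config.n_subjects)]
    run_family(acc, 0.5, "mvpa_vs-theoretical-chance")
    chance = [read_map(out / "mvpa" / f"{_sub(s)}_chance.nii")[0]
              for s in range(config.n_subjects)]
    diff = [a - c for a, c in zip(acc, chance)]
    run_family(diff, 0.0, "mvpa_vs-empirical-chance")


def stage_connectivity(config: PipelineConfig, out: Path) -> None:
    """Beta-series connectivity matrices, NBS and link-FDR reports."""
    conn_dir = out / "connectivity"
    conn_dir.mkdir(parents=True, exist_ok=True)
    atlas, _ = read_label_volume(out / "design" / "atlas.nii")
    names = pd.read_csv(out / "design" / "atlas_labels.tsv", sep="\t")["name"].tolist()
    mats = {"positive": [], "negative": []}
    for s in range(config.n_subjects):
        vol = read_volume(out / "glm" / f"{_sub(s)}_trial-betas.nii")
        conds = pd.read_csv(out / "glm" / f"{_sub(s)}_trial-conditions.tsv",
                            sep="\t")["condition"].tolist()
        trial_betas = np.moveaxis(vol.data, -1, 0)
        series = network.extract_beta_series(trial_betas, conds, atlas)
        for cond in ("positive", "negative"):
            corr = network.connectivity_matrix(series[cond])
            network.matrices_to_frame(corr, names).to_csv(
                conn_dir / f"{_sub(s)}_cond-{cond}_matrix.tsv", sep="\t")
            mats[cond].append(corr)
    rng = _rng_for(config, "nbs")
    log.info("connectivity: n_perm=%d link_alpha=%g seed=%d", config.nbs.n_perm,
             config.nbs.link_alpha, config.seed)
    res = network.nbs(mats["positive"], mats["negative"],
                      link_alpha=config.nbs.link_alpha, n_perm=config.nbs.n_perm,
                      alpha=config.nbs.alpha, seed=rng)
    rows = [{"component": k + 1, "n_edges": c.n_edges, "p_fwe": c.p,
             "nodes": ";".join(names[v - 1] for v in c.nodes),
             "edges": ";".join(f"{names[i - 1]}-{names[j - 1]}"
                               for i, j in c.edges)}
            for k, c in enumerate(res.all_components)]
    pd.DataFrame(rows, columns=["component", "n_edges", "p_fwe", "nodes", "edges"]) \
        .to_csv(conn_dir / "nbs_components.tsv", sep="\t", index=False)
    pd.DataFrame({"max_component_size": res.null_max_size}) \
        .to_csv(conn_dir / "nbs_null.tsv", sep="\t", index=False)
    fdr = network.link_fdr(mats["positive"], mats["negative"], q=config.nbs.fdr_q,
                           n_perm=config.nbs.n_perm, seed=rng)
    pd.DataFrame([{"edge": f"{names[i - 1]}-{names[j - 1]}"} for i, j in fdr.edges]) \
        .to_csv(conn_dir / "fdr_edges.tsv", sep="\t", index=False)


def stage_behavior(config: PipelineConfig, out: Path) -> None:
    """RM-ANOVA on condition means, Bonferroni post hocs, baseline check."""
    behav_dir = out / "behavior"
    behav_dir.mkdir(parents=True, exist_ok=True)
    ratings = pd.read_csv(out / "design" / "ratings.tsv", sep="\t")
    summary = behavior_mod.summarize_ratings(ratings)
    summary.to_csv(behav_dir / "condition_means.tsv", sep="\t")
    res = behavior_mod.rm_anova(summary, config.behavior.mauchly_alpha)
    pd.DataFrame([{"effect": "condition", "F": res.f, "df1": res.df1,
                   "df2": res.df2, "p": res.p, "epsilon_hf": res.epsilon_hf,
                   "mauchly_w": res.mauchly_w, "mauchly_p": res.mauchly_p,
                   "hf_corrected": res.corrected}]) \
        .to_csv(behav_dir / "rm_anova.tsv", sep="\t", index=False)
    posthocs = behavior_mod.paired_posthocs(
        summary, [("positive", "now"), ("negative", "now"),
                  ("positive", "negative")], config.behavior.family_alpha)
    posthocs.to_csv(behav_dir / "posthocs.tsv", sep="\t", index=False)
    base = pd.read_csv(out / "design" / "baseline_ratings.tsv", sep="\t")
    bres = behavior_mod.baseline_check(base)
    pd.DataFrame([{"effect": "assigned strategy", "F": bres.f, "df1": bres.df1,
                   "df2": bres.df2, "p": bres.p}]) \
        .to_csv(behav_dir / "baseline_anova.tsv", sep="\t", index=False)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "glm": stage_glm,
    "mvpa": stage_mvpa,
    "group": stage_group,
    "connectivity": stage_connectivity,
    "behavior": stage_behavior,
}


def run_stage(name: str, config: PipelineConfig, out: str | Path) -> None:
    out = Path(out)
    _setup_logging(out)
    try:
        _STAGE_FUNCS[name](config, out)
    except Exception as exc:                       # noqa: BLE001 - re-tagged
        log.error("stage %s failed: %s", name, exc)
        raise StageError(name, exc) from exc


def run_pipeline(config: PipelineConfig, out: str | Path) -> Path:
    """Run all stages end to end; returns the report directory."""
    out = Path(out)
    _setup_logging(out)
    config.to_yaml(out / "config.yaml")
    log.info("pipeline start: seed=%d", config.seed)
    for name in STAGES:
        run_stage(name, config, out)
    log.info("pipeline done")
    return out
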