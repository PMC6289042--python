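# cravemap

A simulation-backed fMRI analysis pipeline for a three-condition craving
regulation task (two regulation strategies + a "now" control, two visual cues
per strategy). Every analysis stage is exercised end to end on synthetic data
that emulates the study design — 31 subjects, 5 runs of 36 trials (12 per
condition), 2 s cue + 6 ± 1 s image epochs, 10 ± 4 s inter-trial intervals,
TR 2 s, 380 frames per run — so the full pipeline is testable without any
acquisition or download.

## What is implemented

| module | contents |
|---|---|
| `cravemap.synth` | experiment designs (balanced jitters, pseudorandomized orders, cue counterbalancing, stimulus-to-condition rotation), phantom parcellations, BOLD simulation (HRF-convolved epochs, cue-invariant strategy patterns, planted connectivity, AR(1) noise), rating generators, direct beta-series generator |
| `cravemap.glm` | canonical double-gamma HRF, discrete-cosine high-pass basis (1/128 Hz), design matrices in three variants (univariate / strategy×cue MVPA / trial-wise beta series), AR(1)-prewhitened GLM with bias-corrected pooled ρ̂, contrasts, Gaussian smoothing |
| `cravemap.searchlight` | radius-3 sphere searchlight, linear SVC (C = 1), cross-cue cross-classification with leave-one-run-out folds, permutation-derived voxel-wise empirical chance maps |
| `cravemap.group` | one-sample t maps (optional covariate), sign-flip max-statistic peak-level FWE (whole mask or small volume), cluster/peak tables |
| `cravemap.network` | beta-series ROI connectivity (Pearson, 116×116 by default), network-based statistic with permutation max-component null, link-wise Benjamini–Hochberg FDR |
| `cravemap.behavior` | repeated-measures ANOVA with Mauchly's test and Huynh–Feldt correction, Bonferroni-corrected paired post hocs, baseline assignment check |
| `cravemap.pipeline` / `cravemap.cli` | configuration, NIfTI/TSV I/O, logging, stage orchestration |

## CLI

```sh
cravemap init-config --out config.yaml        # full default config
cravemap all --config config.yaml --out report/
cravemap simulate --out report/ --subjects 6 --seed 3   # single stage
cravemap behavior --out report/                          # rerun in isolation
```

Subcommands: `simulate`, `glm`, `mvpa`, `group`, `connectivity`, `behavior`,
`all`. Flags `--config`, `--seed`, `--subjects`, `--out`; CLI flags override
config keys. Stages consume only files written by earlier stages plus the
config, so they can be rerun independently. With a fixed seed the report is
bit-identical across runs. The default configuration is study-sized (31
subjects); pass a reduced config (fewer subjects, smaller grid, fewer
permutations) for desk-scale runs.

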