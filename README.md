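# mcmflow

Analysis pipeline for simultaneous PET/MR studies of learning-induced
coupling between glucose metabolism and functional connectivity — with
a synthetic-study generator carrying known ground truth, so every stage
can be validated end to end.

## Who this is for

Researchers analysing longitudinal task-learning studies acquired with
simultaneous [18F]FDG functional PET and MRI (BOLD, arterial spin
labeling), and methodologists who want a fully controllable testbed for
**metabolic connectivity mapping (MCM)** — a directional connectivity
measure that asks whether a source region's functional-connectivity
fingerprint in a target region matches the target's metabolic pattern.

## The models at the core

**CMRGlu (Patlak).** For an irreversibly trapped tracer, the points
(∫₀ᵗC_p dτ / C_p(t), C_t(t)/C_p(t)) become linear after equilibration;
the slope is the influx constant K_i, converted to the cerebral
metabolic rate of glucose by

    CMRGlu = K_i · Glu_plasma / LC · 100        [µmol/100g/min]

with lumped constant LC = 0.89. Baseline and task uptake are separated
by a GLM with a gray-matter baseline regressor and linear task ramps.

**CBF (ASL).** Control−label differences ΔM are quantified with the
single-compartment equation

    CBF = λ·ΔM·R₁ₐ / (2α·M₀·[e^(−ω·R₁ₐ) − e^(−(τ+ω)·R₁ₐ)])

(λ = 0.9 ml/g, R₁ₐ = 0.67 s⁻¹, α = 0.8, ω = 1800 ms at slice 1,
τ = 1508 ms), in ml/100g/min.

**MCM.** For each source voxel A_i: temporally correlate its cleaned
BOLD series with every voxel of a target region B, Fisher-z the
pattern, spatially correlate that pattern with B's CMRGlu pattern, and
Fisher-z again — the result is the directional connectivity of A_i
toward B. Group inference uses a repeated-measures ANOVA with factors
group × time × condition (time entering through scan-2 − scan-1
differences), Holm-corrected post-hocs, and permutation cluster
inference on difference maps. A voxel-removal simulation attributes
learning effects to CMRGlu or FC by deleting target voxels in 10%
steps, lowest value first, and recomputing the interaction F.

## Worked example

```python
from mcmflow.synthetic import SyntheticConfig, simulate_mcm_study
from mcmflow.stats import rm_anova_gtc, posthoc, holm

study = simulate_mcm_study(SyntheticConfig(seed=1))
res = rm_anova_gtc(study.mcm_values, study.groups)
r = res["group_x_time_x_condition"]
print(f"group x time x condition: F({r.df1},{r.df2}) = {r.F:.1f}, p = {r.p:.2g}")

raw = []
for i, cond in enumerate(("rest", "easy", "hard")):
    ph = posthoc(study.mcm_values, study.groups, i)
    raw.append(ph["interaction"].p)
    t_train = ph["within_group"]["training"]["t"]
    print(f"{cond:>4}: group x time F = {ph['interaction'].F:6.1f}, "
          f"training-group t = {t_train:+.1f}")
print("Holm-adjusted post-hoc p:", [f"{p:.2g}" for p in holm(raw)])
```

prints

```
group x time x condition: F(2,78) = 39.1, p = 1.7e-12
rest: group x time F =   34.2, training-group t = +7.8
easy: group x time F =    7.2, training-group t = -3.8
hard: group x time F =   33.0, training-group t = -9.0
Holm-adjusted post-hoc p: ['2.5e-06', '0.011', '2.5e-06']
```

The generated study of 21 training and 20 control subjects plants a
coupling increase at rest (ρ 0.5 → 0.8) and decreases during the task
(0.5 → 0.38/0.28) for the training group; the ANOVA recovers the
three-way interaction, and the post-hocs recover its signature —
MCM rises at rest (positive t) and falls during the task (negative t)
for the trained group only.

The same study object feeds the perturbation analysis:

```python
from mcmflow.perturb import perturbation_curve
pc = perturbation_curve(study, driver="cmrglu", condition="rest")
# pc.f_values[0] is the unperturbed F; by 50% CMRGlu-ordered removal it
# falls below pc.f_critical, while 90% random removal leaves it intact.
```

## Command line

`mcmflow` exposes the stages as subcommands — `simulate`,
`quantify-pet`, `quantify-asl`, `bold-clean`, `bold-glm`,
`conjunction`, `mcm`, `stats`, `perturb`, and `run-all` (the full
simulate → quantify → conjunction → MCM → statistics → perturbation
pipeline with a manifest of seeds and output hashes). For example:

```sh
mcmflow run-all --out results/demo --seed 3
mcmflow quantify-asl --rest asl_rest.nii.gz --easy asl_easy.nii.gz \
    --hard asl_hard.nii.gz --out-prefix cbf
```

## Layout

| module | contents |
| --- | --- |
| `mcmflow.synthetic` | study generator + ground truth |
| `mcmflow.pet` | input function, fPET GLM, Patlak, CMRGlu |
| `mcmflow.asl` | CBF quantification |
| `mcmflow.bold` | FD/scrubbing, nuisance + bandpass, block GLM |
| `mcmflow.conjunction` | threshold/binarize/intersect, Dice, cluster filter |
| `mcmflow.mcm` | FC patterns, MCM values and whole-brain maps |
| `mcmflow.stats` | mixed ANOVA, post-hocs, Holm, permutation clusters, behaviour |
| `mcmflow.perturb` | voxel-removal perturbation curves |
| `mcmflow.pipeline`, `mcmflow.cli`, `mcmflow.io` | driver, CLI, NIfTI/TSV I/O |

See `docs/methods.md` for the modelling assumptions, parameter
defaults, and what the synthetic validation does and does not
demonstrate.
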