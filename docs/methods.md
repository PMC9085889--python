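# Methods

`mcmflow` implements a multimodal PET/MR analysis of learning-induced
coupling between glucose metabolism and functional connectivity, plus a
synthetic-study generator with known ground truth on which every stage
can be validated end to end.

## Quantification models

**CMRGlu from functional PET.** Dynamic [18F]FDG data acquired with a
bolus+infusion protocol are modelled in 30-s frames. The arterial input
function is assembled from sparse manual samples (default draw times 3,
4, 5, 14, 25, 36, 47 min): whole-blood activity is linearly
interpolated to frame mid-times (held constant beyond the sampled
range) and scaled by the subject's mean plasma-to-whole-blood ratio,
computed over samples with positive whole-blood activity. A GLM on
low-pass-filtered time-activity curves separates baseline from
task-specific uptake; the regressors are the mean gray-matter TAC
(excluding task-activated voxels), one linear ramp per task condition
(slope 1 kBq per frame inside task blocks, held between blocks because
trapped FDG persists), and the first principal component of the six
realignment parameters. The low-pass filter is a moving average of
width equal to the 3-min cutoff (6 frames at 30 s) — zero-phase and
parameter-free; it is applied to data *and* regressors so that a TAC
proportional to a regressor is recovered exactly. Baseline kinetics
enter a Patlak fit: the least-squares line through
(∫₀ᵗC_p dτ / C_p(t), C_t(t)/C_p(t)) for t ≥ t\* gives the influx
constant K_i (slope) and effective distribution volume V₀ (intercept).
t\* defaults to 10 min, the conventional FDG equilibration point within
a 52-min scan; it is configurable because the linear-phase onset
depends on tracer kinetics. CMRGlu = K_i·Glu_plasma/LC·100 with
LC = 0.89, giving µmol/100g/min for K_i in 1/min and glucose in mmol/l.
Condition-specific K_i adds the ramp rate converted to an influx
constant, beta/(mean C_p over the task window × frame length).

**CBF from pseudo-continuous ASL.** Voxels below 0.8× the global mean
are zeroed, M₀ is the mean of non-labeled frames, and each
control−label pair is converted by the single-compartment equation
CBF = λ·ΔM·R₁ₐ / (2α·M₀·[exp(−ω·R₁ₐ) − exp(−(τ+ω)·R₁ₐ)]) with
λ = 0.9 ml/g, R₁ₐ = 0.67 s⁻¹, α = 0.8, ω = 1800 ms at slice 1 and
τ = 1508 ms. All times are converted to seconds internally and the
result rescaled to ml/100g/min (×6000), avoiding the ms/s ambiguity of
the printed constants. The per-slice ω increment of the 2D readout is
not a published constant and is exposed as configuration (default 0).
ΔM is control − label; pairs are frames (2k, 2k+1) with configurable
parity. Task maps contain rest + task signal, so task-specific CBF is
the task map minus the rest map.

**BOLD preprocessing and activation.** Framewise displacement uses
backward differences with L1 summation, rotations expressed as arc
length on a 50-mm sphere; frames with FD > 0.5 mm are censored together
with one frame back and two forward. Nuisance regression (motion, white
matter, CSF means and an intercept) and a 4th-order zero-phase
Butterworth bandpass (0.01–0.15 Hz) are applied to the retained,
re-indexed frames — censoring before filtering is a documented choice,
not an inference about any particular published pipeline; gap-aware
filtering would be the alternative. Activation maps come from an
ordinary block GLM with a canonical double-gamma HRF (peak 6 s,
undershoot 16 s, ratio 1/6).

**Conjunction target definition.** Each modality's group activation map
is thresholded, binarized and intersected; 26-connected components
below a volume cut (default 1 cm³, configurable — the published
exclusions were qualitative) are discarded, with an optional flag that
merges components mapping onto each other under reflection across the
grid midplane before the cut. Overlap is summarised by Dice
coefficients. When ASL is unavailable the conjunction runs on CMRGlu
and BOLD only.

**Metabolic connectivity mapping.** For a source voxel A_i, its BOLD
series is correlated with every target-region voxel and Fisher
z-transformed (|r| clipped at 1−10⁻⁷ so perfect correlations stay
finite); the spatial Pearson correlation of this FC pattern with the
target's condition-matched CMRGlu pattern, Fisher z-transformed again,
is the MCM value of A_i. Zero-variance target voxels contribute z = 0
(with a warning) so pattern length stays fixed across subjects; a
zero-variance source series is an error. Target voxels are excluded
from the source set by default because self-correlation inflates the
spatial match. Whether the spatial correlation should use ranks instead
of Pearson on z-values is genuinely open; Pearson is implemented.

## Group statistics

Scan-2 − scan-1 differences are computed per subject and condition,
then analysed with a two-way mixed ANOVA (group between, condition
within). On differences, the group main effect is the group×time
interaction and the group×condition effect is the group×time×condition
interaction — the same difference-map device the two-factor limitation
of standard neuroimaging ANOVA tools forces. The sums of squares are
computed explicitly (classic weighted-means decomposition, exact for
the unbalanced 21/20 groups); `pingouin.mixed_anova` serves as an
independent cross-check in the tests. The planned second contrast is
rest − (easy+hard)/2 (the equal-weight mean of the task conditions; the
sum-weighting alternative differs only by a factor and leaves F
unchanged). Post-hoc, the group×time interaction per condition is the
squared two-sample t on the differences, followed by paired t-tests
within groups; multiplicity is handled by Bonferroni–Holm
(statsmodels). Sphericity corrections are omitted: the 3-level within
factor enters only through differences, a documented limitation.
Map-level inference is a cluster-extent permutation test (group-label
exchanges, max-extent null, default 2000 permutations, cluster-forming
p = 0.001 two-sided, 95th-percentile extent threshold) — a
permutation replacement for parametric FWE cluster inference, which is
out of scope.

Behaviour: Tetris score per line is k·(n+1) with k = 40/100/300/1200
for 1–4 simultaneous lines at speed level n; performance is score per
minute. Fold changes are reported both as ratios of group means and as
means of subject ratios (the published convention is unstated). The
learning-curve AUC is the trapezoid over training days divided by the
span of days — i.e. the mean daily score; plain division by the day
*count* would not return the level of a flat curve. The rest/task
divergence is (MCM_rest − MCM_hard)/mean(·,·), scale-free by
construction; behaviour associations use Spearman's rho (average
ranks) to resist outliers.

## Voxel-removal perturbation

Target voxels are removed in 10% steps up to 90%, lowest value first,
ordered by (a) the across-subject mean CMRGlu pattern, (b) the
across-subject mean FC (Fisher z toward the cluster) at the first scan,
or (c) at random, and the group×time interaction F for the condition of
interest is recomputed each step. The ordering map is computed once at
fraction 0 and reused, keeping removal sets nested (re-ranking per
fraction would break nesting). Ties break by ascending linear voxel
index. The random arm averages the MCM z-scores over 500 seeded random
selections before the F computation (averaging F-values instead would
conflate selection noise with effect size). The group-mean ordering
(not subject-level) is a design choice; subject-level ordering would
make the removal sets subject-specific and the F-values incomparable
across subjects. The F reported per fraction is the condition-specific
group×time model, not a refit of the full three-factor model.

## The synthetic study

The generator emulates the statistical structure the analysis assumes —
not anatomy or scanner physics. Defaults mirror the study shape: 21
training / 20 control subjects, two scans four weeks apart, three
conditions (rest, easy, hard), 30-s PET frames over 52 min, arterial
samples at the seven draw times, behavioural fold changes 2.7 (easy)
and 3.1 (hard). The grid is a 24×24×12 desk-scale volume with an
axis-aligned cuboid target (the task-activation analogue, 192 voxels)
and a disjoint cuboid seed cluster (64 voxels); masks are unambiguous
by construction where the real study used anatomy.

**Coupling model.** Target voxel v receives
s_v(t) = a_v·seed(t) + √(1−a_v²)·ε_v(t) with a shared latent seed
series and unit Gaussian noise, so a_v is exactly the voxel's
correlation with the seed at infinite scan length. At the first scan
a_v = ρ·w_v, where the weights w_v are a noisy affine image of the
CMRGlu pattern (mismatch parameter κ, default 1.5, giving
corr(w, CMRGlu) ≈ 0.55; κ = 0 makes them identical, which is the
noise-free limit in which the planted spatial correlation approaches
1). MCM therefore rises monotonically with ρ. Learning is a change in
coupling *structure* confined to a carrier set — the lowest-CMRGlu 40%
of target voxels at rest, the lowest-FC 40% during task:
a_v = ρ_M1·w_v + (ρ−ρ_M1)·(ĉ_v−w_v) there, where ĉ_v is the aligned
profile. A positive change corrects the FC–CMRGlu misalignment and
raises the spatial correlation; a negative change tilts the pattern
against metabolism and lowers it. The carrier deliberately stops short
of the median value: removing the lowest-valued *half* then deletes
every carrier voxel even when measured-value ordering swaps a few
voxels near the boundary. This localisation is what makes the
value-ordered removal informative — without it, value-ordered removal
only shrinks the pattern variance and the group effect survives, so the
perturbation analysis could not dissociate the two parameters.
Default coupling: 0.5 in every cell, rising to 0.8 at rest and falling
to 0.38/0.28 (easy/hard) for the training group after training; the
control group is static. A latent per-subject ability (N(0,1)) scales
the coupling increment (sd 0.25) and, through behaviour-side noise
(sd 0.5), the behavioural learning gain — planting rank correlations of
roughly 0.4–0.6 between the rest/task divergence and the behavioural
outcomes, the magnitude regime of interest.

**Other modalities.** fPET tissue curves follow the Patlak relation
C_t = K_i·∫C_p + V₀·C_p for a gamma-variate bolus riding on a rising
infusion plateau, plus task ramps scaled by local K_i and doubled in
the target region (task-specific uptake). ASL frames alternate
control/label with ΔM obtained by inverting the quantification equation
at the configured CBF — rest CBF everywhere, task CBF inside the target
— so noise-free round trips are exact. Motion traces are low-amplitude
random walks with sustained translation jumps that exceed the scrubbing
threshold at known frames. Behavioural learning curves saturate
exponentially (time constant 6 days over 21 training days); the
functional form is a modelling choice, the published curve being shown
but not parameterised. All randomness derives from one root seed
through named substreams, so a fixed seed gives bit-identical studies.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: anatomy and registration error,
physiological (non-Gaussian, autocorrelated) BOLD noise, partial-volume
effects, attenuation/scatter, arterial dispersion and delay, and any
hemodynamic-metabolic decoupling. Recovery results certify the
*estimators and inference machinery*, not robustness to these real-data
effects.

## Problem sizes and numerical choices

The in-memory study (`simulate_mcm_study`) generates only the voxels
MCM consumes (target + seed cluster) and runs the genuine MCM estimator
on them; one default study takes well under a second, so
planted-effect recovery and type-I calibration are assessed over 100
independent seeds. The file-based pipeline (`run_pipeline`) writes and
re-reads full NIfTI studies and is exercised at a miniature scale
(12×12×6 grid, 6+6 subjects) where the mechanics — quantification,
conjunction recovery of the planted target, map generation, manifest
determinism — are checked but the learning effect itself is
underpowered; power claims rest on the full-scale in-memory study.
Correlations are clipped at |r| = 1−10⁻⁷ before atanh. Voxels with
zero variance yield r = 0 rather than NaN wherever a fixed-length
pattern is required. Degenerate inputs (empty masks, constant CMRGlu
patterns, <4 target voxels, <2 blood samples, rank-deficient designs)
raise errors rather than propagate NaNs. Permutation and random-removal
counts are seeded; the bandpass uses `sosfiltfilt` for numerical
stability.

## Known limitations

- No spatial registration or smoothing: all images must share one grid.
- The fPET baseline/task separation assumes the provided activation
  mask; parametric FWE thresholds for that mask are out of scope.
- The two reported fold-change conventions coincide only asymptotically.
- The condition-specific perturbation F uses the post-hoc model; the
  full three-factor refit is a flagged alternative.
- Behavioural and imaging noise are Gaussian and independent across
  frames/voxels, which understates real-data variance clustering.
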