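"""Synthetic PET/MR learning study with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* fPET time-activity curves obeying the Patlak relation for a
  bolus+infusion input function sampled in 30-s frames, with ramp-shaped
  task uptake and arterial samples at the study's blood-draw times;
* ASL control/label series whose pairwise difference encodes a known CBF
  through the single-compartment quantification equation;
* BOLD series in which target-region voxels carry a seed-driven
  connectivity pattern whose spatial profile matches the CMRGlu pattern
  with a controllable coupling strength ρ per (group, time, condition)
  cell — the quantity metabolic connectivity mapping estimates;
* motion traces with injected spikes, and Tetris-style learning curves
  with configurable fold changes.

Coupling construction.  Each target voxel v gets a seed-influence weight
w_v; its BOLD series is s_v(t) = a_v·seed(t) + √(1−a_v²)·ε_v(t) with
a_v = ρ·w_v at the first scan, so the FC pattern across target voxels is
proportional to w_v scaled by ρ.  The weights are a noisy affine image
of the CMRGlu pattern (w_v → ĉ_v exactly as the mismatch noise → 0), so
the planted MCM value rises monotonically with ρ.  Learning enters as a
change of the coupling *structure*, localised so that the value-ordered
voxel-removal simulation is informative:

* inside a condition-specific carrier set of target voxels (the
  lowest-CMRGlu ~40% at rest, the lowest-FC ~40% during task) the
  coupling moves toward or away from the aligned profile:
  a_v = ρ_M1·w_v + (ρ − ρ_M1)·(ĉ_v − w_v).  A positive change (rest
  after training) corrects the FC–CMRGlu misalignment there and raises
  the spatial correlation; a negative change (task after training)
  tilts it against the metabolic pattern and lowers it — monotonically
  in ρ either way.

Removing the low-valued half by the matching driver deletes every
carrier voxel, while random removal merely subsamples the pattern and
leaves the group effect intact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import mcm as mcm_mod
from . import pet as pet_mod
from .asl import AslConstants, deltam_from_cbf
from .io import Image4D, write_image, write_table
from .pet import cmrglu_from_ki, DEFAULT_LC

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "StudyMCM",
    "GROUPS",
    "TIMES",
    "CONDITIONS",
    "default_coupling",
    "default_masks",
    "plasma_curve",
    "generate_fpet_tacs",
    "generate_asl_series",
    "generate_motion",
    "generate_behavior",
    "make_ground_truth",
    "simulate_mcm_study",
    "generate_study",
]

GROUPS = ("training", "control")
TIMES = ("M1", "M2")
CONDITIONS = ("rest", "easy", "hard")

BLOOD_SAMPLE_TIMES_MIN = (3.0, 4.0, 5.0, 14.0, 25.0, 36.0, 47.0)


def default_coupling() -> dict[tuple[str, str, str], float]:
    """Coupling ρ per (group, time, condition).

    Baseline coupling 0.5 everywhere; after training the rest-state
    coupling rises to 0.8 while task coupling falls (hard more than
    easy), mirroring the direction of the reported learning effects.
    The control group is static.
    """
    rho = {(g, t, c): 0.5 for g in GROUPS for t in TIMES for c in CONDITIONS}
    rho[("training", "M2", "rest")] = 0.8
    rho[("training", "M2", "easy")] = 0.38
    rho[("training", "M2", "hard")] = 0.28
    return rho


@dataclass
class SyntheticConfig:
    """Study-shape constants and noise levels of the synthetic study."""

    grid_shape: tuple[int, int, int] = (24, 24, 12)
    n_frames_bold: int = 300
    tr_bold: float = 2.0                  # s
    n_frames_pet: int = 104               # 52 min of 30-s frames
    frame_len_pet: float = 30.0           # s
    n_asl_pairs: int = 20                 # control/label pairs per condition
    n_subjects_training: int = 21
    n_subjects_control: int = 20
    coupling: dict[tuple[str, str, str], float] = field(default_factory=default_coupling)
    coupling_subject_sd: float = 0.25     # between-subject sd of the increment multiplier
    pattern_mismatch: float = 1.5         # FC-weight vs CMRGlu-pattern mismatch (0 = aligned)
    ki_mean: float = 0.03                 # 1/min, gray matter influx constant
    ki_sd: float = 0.006
    glu_plasma: float = 5.45              # mmol/l
    lc: float = DEFAULT_LC
    cbf_rest: float = 50.0                # ml/100g/min
    cbf_task_easy: float = 58.0
    cbf_task_hard: float = 62.0
    fold_change_easy: float = 2.7
    fold_change_hard: float = 3.1
    plasma_wb_ratio: float = 1.0
    pet_noise_sd: float = 0.3             # kBq/ml, TAC noise
    asl_noise_sd: float = 2.0             # signal units
    cmrglu_noise_sd: float = 0.5          # µmol/100g/min, per-subject map noise
    behavior_noise_sd: float = 0.12       # relative score noise
    behavior_ability_gain: float = 0.35   # how strongly latent ability scales M2 scores
    behavior_ability_noise_sd: float = 0.5  # sd of the behaviour-side ability noise
    n_motion_spikes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            *self.grid_shape, self.n_frames_bold, self.n_frames_pet,
            self.n_asl_pairs, self.n_subjects_training, self.n_subjects_control,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        for key, rho in self.coupling.items():
            if not 0.0 <= rho <= 1.0:
                raise ValueError(f"coupling {key} = {rho} outside [0, 1]")
        if min(self.cbf_rest, self.cbf_task_easy, self.cbf_task_hard) < 0:
            raise ValueError("CBF must be >= 0")

    @property
    def n_subjects(self) -> int:
        return self.n_subjects_training + self.n_subjects_control

    def subject_groups(self) -> np.ndarray:
        return np.array(
            ["training"] * self.n_subjects_training + ["control"] * self.n_subjects_control
        )

    def pet_frame_times_min(self) -> np.ndarray:
        dt = self.frame_len_pet / 60.0
        return (np.arange(self.n_frames_pet) + 0.5) * dt

    def pet_task_blocks(self) -> dict[str, tuple[int, int]]:
        """Easy/hard task blocks (frame index ranges) within the fPET scan."""
        n = self.n_frames_pet
        return {"easy": (int(0.40 * n), int(0.55 * n)), "hard": (int(0.65 * n), int(0.85 * n))}


def default_masks(grid_shape: tuple[int, int, int]) -> dict[str, np.ndarray]:
    """Axis-aligned cuboid target ('Occ') and a disjoint seed ('SN').

    Desk-scale stand-ins for the anatomical regions; the brain mask is
    the full grid and gray matter a central slab.
    """
    nx, ny, nz = grid_shape
    target = np.zeros(grid_shape, dtype=bool)
    target[nx // 12: nx // 12 + max(nx // 3, 2),
           ny // 12: ny // 12 + max(ny // 3, 2),
           nz // 4: nz // 4 + max(nz // 4, 2)] = True
    source = np.zeros(grid_shape, dtype=bool)
    source[-max(nx // 6, 2) - 1: -1, -max(ny // 6, 2) - 1: -1,
           nz // 3: nz // 3 + max(nz // 3, 2)] = True
    if (target & source).any():
        raise ValueError("degenerate grid: target and seed overlap")
    if target.sum() < 2:
        raise ValueError("degenerate grid: < 2 target voxels")
    brain = np.ones(grid_shape, dtype=bool)
    gm = np.zeros(grid_shape, dtype=bool)
    gm[1:-1, 1:-1, 1:-1] = True
    return {"target": target, "source": source, "brain": brain, "gm": gm}


@dataclass
class GroundTruth:
    """Everything the recovery tests need to know about the study."""

    ki_true: np.ndarray                    # 3D, 1/min
    cmrglu_true: np.ndarray                # 3D, µmol/100g/min
    cbf_true: dict[str, float]             # per condition
    coupling_true: dict                    # (subject, time, condition) -> realized ρ
    weights_true: np.ndarray               # per-target-voxel seed-influence w_v
    aligned_profile: np.ndarray            # ĉ_v: the CMRGlu-aligned coupling profile
    low_cmrglu_half: np.ndarray            # bool per target voxel: low-CMRGlu carrier set
    low_fc_half: np.ndarray                # bool per target voxel: low-FC carrier set
    ability: np.ndarray                    # latent per-subject ability (drives behavior)
    scrub_frames_true: dict                # (subject, time, condition) -> spike frames
    behavior_true: dict                    # per-subject learning-curve parameters
    masks: dict[str, np.ndarray]


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Named substream: all randomness flows from one root seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _carrier_set(values: np.ndarray, fraction: float = 0.4) -> np.ndarray:
    """Boolean marker of the ⌊fraction·n⌋ lowest entries (stable ties).

    The carrier stops short of the median on purpose: removing the
    lowest half of the voxels then deletes every carrier even when the
    measured ordering swaps a few voxels near the boundary.
    """
    low = np.argsort(values, kind="stable")[: int(len(values) * fraction)]
    out = np.zeros(len(values), dtype=bool)
    out[low] = True
    return out


def make_ground_truth(config: SyntheticConfig) -> GroundTruth:
    """Draw the fixed (subject-independent) ground truth of one study."""
    masks = default_masks(config.grid_shape)
    target = masks["target"]
    n_t = int(target.sum())
    if n_t < 2:
        raise ValueError("degenerate grid: < 2 target voxels")

    rng = _rng(config.seed, 0)
    # CMRGlu pattern over the target; the seed-influence weights are a
    # noisy affine image of it (w → ĉ exactly as pattern_mismatch → 0).
    c_z = rng.standard_normal(n_t)
    c_z = (c_z - c_z.mean()) / c_z.std()
    kappa = config.pattern_mismatch
    mix = (c_z + kappa * rng.standard_normal(n_t)) / np.sqrt(1.0 + kappa**2)
    mix = (mix - mix.mean()) / mix.std()
    chat = np.clip(0.65 + 0.175 * c_z, 0.15, 1.0)          # aligned profile ĉ_v
    w = np.clip(0.65 + 0.175 * mix, 0.15, 1.0)             # seed-influence weights w_v

    ki = np.clip(config.ki_mean + config.ki_sd * rng.standard_normal(config.grid_shape), 1e-4, None)
    ki[target] = np.clip(config.ki_mean + config.ki_sd * c_z, 1e-4, None)
    cmrglu = cmrglu_from_ki(ki, config.glu_plasma, config.lc)

    low_c = _carrier_set(cmrglu[target])
    low_w = _carrier_set(w)

    rng_sub = _rng(config.seed, 1)
    ability = rng_sub.standard_normal(config.n_subjects)

    groups = config.subject_groups()
    coupling_true: dict = {}
    for i in range(config.n_subjects):
        mult = 1.0 + config.coupling_subject_sd * ability[i]
        for t in TIMES:
            for c in CONDITIONS:
                base = config.coupling[(groups[i], "M1", c)]
                rho = config.coupling[(groups[i], t, c)]
                inc = (rho - base) * max(mult, 0.0)
                coupling_true[(i, t, c)] = float(np.clip(base + inc, 0.0, 1.0))

    behavior_true = {
        "base_score_easy": 18.0,
        "base_score_hard": 8.0,
        "learning_tau_days": 6.0,
        "n_training_days": 21,
    }
    return GroundTruth(
        ki_true=ki,
        cmrglu_true=cmrglu,
        cbf_true={
            "rest": config.cbf_rest,
            "easy": config.cbf_task_easy,
            "hard": config.cbf_task_hard,
        },
        coupling_true=coupling_true,
        weights_true=w,
        aligned_profile=chat,
        low_cmrglu_half=low_c,
        low_fc_half=low_w,
        ability=ability,
        scrub_frames_true={},
        behavior_true=behavior_true,
        masks=masks,
    )


def coupling_profile(
    config: SyntheticConfig,
    gt: GroundTruth,
    subject: int,
    time: str,
    condition: str,
) -> np.ndarray:
    """Per-target-voxel coupling amplitude a_v for one study cell.

    At the first scan a_v = ρ·w_v.  A coupling change moves the carrier
    set (lowest-CMRGlu voxels at rest, lowest-FC voxels during task)
    toward (Δρ > 0) or away from (Δρ < 0) the aligned profile ĉ_v,
    leaving the remaining voxels untouched — so removing the lowest-
    valued half by the matching driver removes the learning signal.
    """
    group = config.subject_groups()[subject]
    base = config.coupling[(group, "M1", condition)]
    rho = gt.coupling_true[(subject, time, condition)]
    delta = rho - base
    carrier = gt.low_cmrglu_half if condition == "rest" else gt.low_fc_half
    a = base * gt.weights_true + delta * (gt.aligned_profile - gt.weights_true) * carrier
    return np.clip(a, -0.97, 0.97)


def generate_bold_cell(
    config: SyntheticConfig,
    gt: GroundTruth,
    subject: int,
    time: str,
    condition: str,
    source_noise: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Target and seed-region BOLD series for one subject/scan/condition.

    Returns (target_ts, source_ts) as frames×voxels matrices.  Target
    voxel v follows a_v·seed(t) + √(1−a_v²)·ε_v(t); seed-region voxels
    follow seed(t) + source_noise·ε(t).
    """
    a = coupling_profile(config, gt, subject, time, condition)
    t_idx = TIMES.index(time)
    c_idx = CONDITIONS.index(condition)
    rng = _rng(config.seed, 2, subject, t_idx, c_idx)
    T = config.n_frames_bold
    seed_ts = rng.standard_normal(T)
    tgt = a[None, :] * seed_ts[:, None] + np.sqrt(1.0 - a**2)[None, :] * rng.standard_normal(
        (T, len(a))
    )
    n_src = int(gt.masks["source"].sum())
    src = seed_ts[:, None] + source_noise * rng.standard_normal((T, n_src))
    return tgt, src


def subject_cmrglu_pattern(
    config: SyntheticConfig, gt: GroundTruth, subject: int, condition: str
) -> np.ndarray:
    """Condition-matched CMRGlu pattern over the target for one subject:
    the shared ground-truth pattern (scaled up during task) plus
    subject-level measurement noise."""
    task_gain = {"rest": 1.0, "easy": 1.05, "hard": 1.08}[condition]
    rng = _rng(config.seed, 3, subject, CONDITIONS.index(condition))
    c = gt.cmrglu_true[gt.masks["target"]] * task_gain
    return c + config.cmrglu_noise_sd * rng.standard_normal(len(c))


# ---------------------------------------------------------------------------
# fPET
# ---------------------------------------------------------------------------

def plasma_curve(
    t_min: np.ndarray,
    bolus_peak: float = 40.0,
    bolus_tp_min: float = 0.75,
    washout_min: float = 2.0,
    plateau: float = 15.0,
    plateau_rise_min: float = 3.0,
) -> np.ndarray:
    """Bolus+infusion plasma activity (kBq/ml): a gamma-variate bolus
    with exponential washout riding on a rising infusion plateau."""
    t = np.asarray(t_min, dtype=float)
    bolus = bolus_peak * (t / bolus_tp_min) * np.exp(1.0 - t / bolus_tp_min)
    infusion = plateau * (1.0 - np.exp(-t / plateau_rise_min))
    return bolus + infusion


def generate_fpet_tacs(
    config: SyntheticConfig,
    gt: GroundTruth,
    subject: int = 0,
    time: str = "M1",
    v0: float = 0.3,
    task_amp_easy: float = 0.10,
    task_amp_hard: float = 0.15,
) -> tuple[Image4D, pd.DataFrame]:
    """fPET frame series and the matching arterial blood sample table.

    Tissue follows the Patlak relation C_t = Ki·∫Cp + V0·Cp plus linear
    ramps during the task blocks (amplitude in kBq/ml per frame, scaled
    by the local Ki relative to its mean) and optional Gaussian noise.
    """
    from scipy.integrate import cumulative_trapezoid

    t_mid = config.pet_frame_times_min()
    cp = plasma_curve(t_mid)
    cum = cumulative_trapezoid(cp, t_mid, initial=0.0)

    ki_flat = gt.ki_true.reshape(-1)
    tac = ki_flat[:, None] * cum[None, :] + v0 * cp[None, :]

    blocks = config.pet_task_blocks()
    # task uptake scales with local Ki and is boosted in the task-active target
    ki_mean = ki_flat.mean()
    rel = (ki_flat / ki_mean if ki_mean > 0 else np.zeros_like(ki_flat)) * (
        1.0 + gt.masks["target"].reshape(-1)
    )
    for cond, amp in (("easy", task_amp_easy), ("hard", task_amp_hard)):
        ramp = pet_mod.make_ramp_regressor(config.n_frames_pet, [blocks[cond]])
        tac += (amp * rel)[:, None] * ramp[None, :]

    if config.pet_noise_sd > 0:
        rng = _rng(config.seed, 4, subject, TIMES.index(time))
        tac = tac + config.pet_noise_sd * rng.standard_normal(tac.shape)

    img = Image4D(
        data=tac.reshape(*config.grid_shape, config.n_frames_pet),
        frame_times=t_mid * 60.0,
        units="kBq/ml",
    )
    wb = np.interp(BLOOD_SAMPLE_TIMES_MIN, t_mid, cp) / config.plasma_wb_ratio
    blood = pd.DataFrame(
        {
            "time_min": BLOOD_SAMPLE_TIMES_MIN,
            "wholeblood_kBq_ml": wb,
            "plasma_kBq_ml": wb * config.plasma_wb_ratio,
        }
    )
    return img, blood


# ---------------------------------------------------------------------------
# ASL
# ---------------------------------------------------------------------------

def generate_asl_series(
    config: SyntheticConfig,
    gt: GroundTruth,
    condition: str,
    subject: int = 0,
    time: str = "M1",
    m0_value: float = 1000.0,
    constants: AslConstants = AslConstants(),
    label_parity: str = "control-first",
) -> Image4D:
    """Alternating control/label series encoding the condition's CBF.

    ΔM is obtained by inverting the quantification equation at the
    ground-truth CBF (slice-dependent post-labeling delay), so a
    noise-free round trip through the quantifier is exact.
    """
    if gt.cbf_true[condition] < 0:
        raise ValueError("CBF must be >= 0")
    shape = config.grid_shape
    slices = np.arange(1, shape[2] + 1)[None, None, :]
    m0 = np.full(shape, m0_value)
    # task hyperemia is confined to the task-active (target) region
    cbf = np.full(shape, gt.cbf_true["rest"])
    cbf[gt.masks["target"]] = gt.cbf_true[condition]
    dm = deltam_from_cbf(cbf, m0, constants, slices)
    n_frames = 2 * config.n_asl_pairs
    series = np.empty((*shape, n_frames))
    ctrl_first = label_parity == "control-first"
    for k in range(n_frames):
        is_control = (k % 2 == 0) == ctrl_first
        series[..., k] = m0 if is_control else m0 - dm
    if config.asl_noise_sd > 0:
        rng = _rng(config.seed, 5, subject, TIMES.index(time), CONDITIONS.index(condition))
        series = series + config.asl_noise_sd * rng.standard_normal(series.shape)
    return Image4D(data=series, units="a.u.")


# ---------------------------------------------------------------------------
# Motion and behavior
# ---------------------------------------------------------------------------

def generate_motion(
    config: SyntheticConfig,
    subject: int = 0,
    time: str = "M1",
    condition: str = "rest",
    spike_mm: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Six-column motion trace (mm, rad) with injected FD spikes.

    The baseline is a smooth low-amplitude random walk (FD well below
    the 0.5 mm scrubbing threshold); ``n_motion_spikes`` frames get a
    translation jump of ``spike_mm``.
    """
    rng = _rng(config.seed, 6, subject, TIMES.index(time), CONDITIONS.index(condition))
    n = config.n_frames_bold
    steps = rng.normal(0.0, 0.01, size=(n, 6))
    steps[:, 3:] *= 1e-3 / 0.01  # rotations in rad, tiny
    trace = np.cumsum(steps, axis=0)
    n_spikes = min(config.n_motion_spikes, max(n // 10, 0))
    spikes = np.sort(rng.choice(np.arange(5, n - 5), size=n_spikes, replace=False))
    for s in spikes:
        trace[s:, 0] += spike_mm  # sustained jump: one FD excursion at s
    return trace, spikes


def _learning_curve(days: np.ndarray, fold: float, tau: float, horizon: float) -> np.ndarray:
    """Saturating relative performance, 1 at day 0 → fold at the horizon."""
    sat = (1.0 - np.exp(-days / tau)) / (1.0 - np.exp(-horizon / tau))
    return 1.0 + (fold - 1.0) * sat


def generate_behavior(config: SyntheticConfig, gt: GroundTruth) -> pd.DataFrame:
    """Scan scores (score/min at M1, M2 per condition) and daily training
    scores following a saturating learning curve.

    Training-group M2/M1 group-mean ratios equal the configured fold
    changes in expectation; the control group is flat.  A subject's
    latent ability (observed through behaviour-side noise) scales the
    learning gain, tying behaviour to the planted coupling increments.
    A mental-rotation summary (duration per correct answer, low = good)
    is emitted per subject at the second scan with the opposite sign.
    """
    rng = _rng(config.seed, 7)
    groups = config.subject_groups()
    bt = gt.behavior_true
    folds = {"easy": config.fold_change_easy, "hard": config.fold_change_hard}
    base = {"easy": bt["base_score_easy"], "hard": bt["base_score_hard"]}
    tau, n_days = bt["learning_tau_days"], int(bt["n_training_days"])
    rows = []
    for i in range(config.n_subjects):
        trains = groups[i] == "training"
        # behaviour observes the latent ability through its own noise
        expressed = (
            gt.ability[i] + config.behavior_ability_noise_sd * rng.standard_normal()
        ) / np.sqrt(1.0 + config.behavior_ability_noise_sd**2)
        gain = max(1.0 + config.behavior_ability_gain * expressed, 0.1)
        for cond in ("easy", "hard"):
            fold = folds[cond] if trains else 1.0
            m1 = base[cond] * (1.0 + config.behavior_noise_sd * rng.standard_normal())
            # E[M2]/E[M1] = fold: the ability gain has mean 1 across subjects
            m2_mean = base[cond] * (1.0 + (fold - 1.0) * gain) if trains else base[cond]
            m2 = m2_mean * (1.0 + config.behavior_noise_sd * rng.standard_normal())
            rows.append((i, groups[i], "scan", "M1", cond, max(m1, 0.1)))
            rows.append((i, groups[i], "scan", "M2", cond, max(m2, 0.1)))
        rot = 20.0 * (1.0 - 0.25 * expressed) * (
            1.0 + config.behavior_noise_sd * rng.standard_normal()
        )
        rows.append((i, groups[i], "cognitive", "M2", "rotation", max(rot, 0.1)))
        if trains:
            days = np.arange(1, n_days + 1, dtype=float)
            curve = base["hard"] * _learning_curve(days * gain, folds["hard"], tau, n_days)
            noise = 1.0 + config.behavior_noise_sd * rng.standard_normal(n_days)
            for d, s in zip(days, np.clip(curve * noise, 0.1, None)):
                rows.append((i, groups[i], "training", d, "hard", s))
    return pd.DataFrame(
        rows, columns=["subject", "group", "kind", "time", "condition", "score_per_min"]
    )


# ---------------------------------------------------------------------------
# In-memory MCM study and the full on-disk study
# ---------------------------------------------------------------------------

@dataclass
class StudyMCM:
    """MCM-ready in-memory study: per-cell FC z-patterns over the target,
    CMRGlu patterns, cluster-mean MCM values, behaviour and ground truth."""

    config: SyntheticConfig
    ground_truth: GroundTruth
    groups: np.ndarray
    z_patterns: dict          # (subject, time, condition) -> (n_source, n_target) Fisher z
    cmrglu_patterns: dict     # (subject, condition) -> (n_target,)
    mcm_values: np.ndarray    # (n_subjects, 2 times, 3 conditions) cluster-mean MCM z
    behavior: pd.DataFrame


def simulate_mcm_study(config: SyntheticConfig) -> StudyMCM:
    """Generate the study restricted to the voxels MCM needs (target +
    seed cluster) and run the MCM computation for every cell.

    This is the full generative model and the genuine MCM estimator —
    only the source set is the seed cluster instead of the whole brain,
    which is what the group statistics and the perturbation analysis
    consume.
    """
    gt = make_ground_truth(config)
    groups = config.subject_groups()
    z_patterns: dict = {}
    cmrglu_patterns: dict = {}
    values = np.empty((config.n_subjects, len(TIMES), len(CONDITIONS)))
    for i in range(config.n_subjects):
        for c_idx, cond in enumerate(CONDITIONS):
            cmrglu_patterns[(i, cond)] = subject_cmrglu_pattern(config, gt, i, cond)
        for t_idx, time in enumerate(TIMES):
            for c_idx, cond in enumerate(CONDITIONS):
                tgt, src = generate_bold_cell(config, gt, i, time, cond)
                z = mcm_mod.fisher_z(mcm_mod.temporal_corr(src, tgt))
                z_patterns[(i, time, cond)] = z
                c = cmrglu_patterns[(i, cond)]
                r = mcm_mod.spatial_corr_masked(z, c, np.ones((1, len(c)), dtype=bool))[0]
                values[i, t_idx, c_idx] = mcm_mod.fisher_z(r).mean()
    return StudyMCM(
        config=config,
        ground_truth=gt,
        groups=groups,
        z_patterns=z_patterns,
        cmrglu_patterns=cmrglu_patterns,
        mcm_values=values,
        behavior=generate_behavior(config, gt),
    )


def _fill_brain_bold(
    config: SyntheticConfig, gt: GroundTruth, subject: int, time: str, condition: str
) -> np.ndarray:
    """Full-grid BOLD volume: target and seed voxels from the coupling
    model, everything else unit Gaussian noise.  Task runs additionally
    carry a block-design activation in the target region so that the
    BOLD leg of the multimodal conjunction can recover it."""
    from .bold import block_regressor

    tgt, src = generate_bold_cell(config, gt, subject, time, condition)
    rng = _rng(config.seed, 8, subject, TIMES.index(time), CONDITIONS.index(condition))
    T = config.n_frames_bold
    data = rng.standard_normal((*config.grid_shape, T))
    data[gt.masks["target"]] = tgt.T
    data[gt.masks["source"]] = src.T
    if condition != "rest":
        act = block_regressor(T, bold_task_blocks(T), config.tr_bold)
        data[gt.masks["target"]] += 0.6 * act
    return data


def bold_task_blocks(n_frames: int) -> list[tuple[int, int]]:
    """Four equally spaced task blocks covering ~40% of the run."""
    block = max(n_frames // 10, 2)
    starts = [int(f * n_frames) for f in (0.1, 0.35, 0.6, 0.85)]
    return [(s, min(s + block, n_frames)) for s in starts]


def generate_study(config: SyntheticConfig, out_dir) -> tuple[pd.DataFrame, GroundTruth]:
    """Write a complete synthetic study to disk and return its design.

    Layout: one directory per subject/time with BOLD, fPET, ASL NIfTI
    series and motion/blood TSVs, plus study-level masks, behaviour
    table, design table and a JSON ground-truth sidecar.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gt = make_ground_truth(config)
    groups = config.subject_groups()

    for name in ("target", "source", "brain", "gm"):
        write_image(gt.masks[name].astype(float), out / f"mask_{name}.nii.gz")
    write_image(gt.ki_true, out / "ki_true.nii.gz")
    write_image(gt.cmrglu_true, out / "cmrglu_true.nii.gz")

    rows = []
    for i in range(config.n_subjects):
        for time in TIMES:
            sdir = out / f"sub-{i:02d}" / time
            sdir.mkdir(parents=True, exist_ok=True)
            pet_img, blood = generate_fpet_tacs(config, gt, i, time)
            write_image(pet_img, sdir / "fpet.nii.gz")
            write_table(blood, sdir / "blood.tsv")
            for cond in CONDITIONS:
                bold = _fill_brain_bold(config, gt, i, time, cond)
                write_image(bold, sdir / f"bold_{cond}.nii.gz")
                asl_img = generate_asl_series(config, gt, cond, i, time)
                write_image(asl_img, sdir / f"asl_{cond}.nii.gz")
                trace, spikes = generate_motion(config, i, time, cond)
                write_table(
                    pd.DataFrame(
                        trace,
                        columns=["tx_mm", "ty_mm", "tz_mm", "rx_rad", "ry_rad", "rz_rad"],
                    ),
                    sdir / f"motion_{cond}.tsv",
                )
                gt.scrub_frames_true[(i, time, cond)] = spikes
                rows.append(
                    {
                        "subject_id": i,
                        "group": groups[i],
                        "time": time,
                        "condition": cond,
                        "bold": str((sdir / f"bold_{cond}.nii.gz").relative_to(out)),
                        "fpet": str((sdir / "fpet.nii.gz").relative_to(out)),
                        "asl": str((sdir / f"asl_{cond}.nii.gz").relative_to(out)),
                        "blood": str((sdir / "blood.tsv").relative_to(out)),
                        "motion": str((sdir / f"motion_{cond}.tsv").relative_to(out)),
                    }
                )
    design = pd.DataFrame(rows)
    write_table(design, out / "design.tsv")
    write_table(generate_behavior(config, gt), out / "behavior.tsv")

    sidecar = {
        "seed": config.seed,
        "coupling_true": {f"{k[0]}|{k[1]}|{k[2]}": v for k, v in gt.coupling_true.items()},
        "cbf_true": gt.cbf_true,
        "behavior_true": gt.behavior_true,
        "scrub_frames_true": {
            f"{k[0]}|{k[1]}|{k[2]}": [int(s) for s in v]
            for k, v in gt.scrub_frames_true.items()
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=2))
    return design, gt
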