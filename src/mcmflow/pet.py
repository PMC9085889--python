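"""CMRGlu quantification from functional PET (bolus+infusion [18F]FDG).

The pipeline is: assemble the arterial input function from sparse blood
samples; separate baseline from task-specific uptake with a GLM on
low-pass-filtered time-activity curves (baseline = mean gray-matter TAC
excluding task-activated voxels, task regressors = linear ramps over the
task blocks, motion = first principal component of the six realignment
parameters); fit the Patlak plot to the baseline kinetics for the influx
constant Ki; and convert to the cerebral metabolic rate of glucose,

    CMRGlu = Ki · Glu_plasma / LC · 100     [µmol/100g/min]

with the lumped constant LC = 0.89 and plasma glucose in mmol/l.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import uniform_filter1d

__all__ = [
    "InputFunction",
    "FpetDesign",
    "KineticResult",
    "assemble_input_function",
    "build_baseline_regressor",
    "make_ramp_regressor",
    "motion_pc1",
    "lowpass_tacs",
    "fit_fpet_glm",
    "patlak_ki",
    "cmrglu_from_ki",
    "condition_ki",
]

DEFAULT_LC = 0.89


@dataclass
class InputFunction:
    """Arterial plasma activity resampled to the PET frame grid."""

    frame_times: np.ndarray        # min, frame mid-times
    cp: np.ndarray                 # kBq/ml
    cumulative_integral: np.ndarray = field(init=False)  # kBq·min/ml

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.frame_times.shape != self.cp.shape:
            raise ValueError("frame_times and cp must have equal length")
        self.cumulative_integral = cumulative_trapezoid(
            self.cp, self.frame_times, initial=0.0
        )


def assemble_input_function(samples: pd.DataFrame, frame_times_min) -> InputFunction:
    """Build the input function from manual arterial samples.

    ``samples`` needs columns ``time_min`` (or ``time_s``),
    ``wholeblood_kBq_ml`` and ``plasma_kBq_ml``.  Whole-blood activity is
    linearly interpolated to the frame mid-times (held constant beyond
    the sampled range) and scaled by the average per-sample
    plasma-to-whole-blood ratio.
    """
    if "time_min" in samples.columns:
        t = samples["time_min"].to_numpy(dtype=float)
    elif "time_s" in samples.columns:
        t = samples["time_s"].to_numpy(dtype=float) / 60.0
    else:
        raise ValueError("samples need a time_min or time_s column")
    wb = samples["wholeblood_kBq_ml"].to_numpy(dtype=float)
    pl = samples["plasma_kBq_ml"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("need >= 2 blood samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("sample times must be strictly increasing")
    ok = wb > 0  # the ratio is undefined on zero-activity samples
    if not ok.any():
        raise ValueError("no positive whole-blood samples for the plasma ratio")
    ratio = float(np.mean(pl[ok] / wb[ok]))
    frame_times = np.asarray(frame_times_min, dtype=float)
    cp = np.interp(frame_times, t, wb) * ratio
    return InputFunction(frame_times=frame_times, cp=cp)


def build_baseline_regressor(
    pet4d: np.ndarray,
    gm_mask: np.ndarray,
    exclusion_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Baseline regressor: frame-wise mean TAC over gray matter voxels,
    excluding those activated during the hard task."""
    pet4d = np.asarray(pet4d, dtype=float)
    include = np.asarray(gm_mask, dtype=bool)
    if exclusion_mask is not None:
        include = include & ~np.asarray(exclusion_mask, dtype=bool)
    if not include.any():
        raise ValueError("empty inclusion set (gray matter minus exclusion)")
    return pet4d[include].mean(axis=0)


def make_ramp_regressor(n_frames: int, blocks: list[tuple[int, int]]) -> np.ndarray:
    """Linear ramp with slope 1 kBq per frame over each task block.

    Zero before the first block; rises by one unit per frame inside each
    ``[start, stop)`` block and holds its value in between and after
    (FDG uptake accumulated during a task persists).
    """
    ramp = np.zeros(n_frames)
    for start, stop in blocks:
        if not (0 <= start < stop <= n_frames):
            raise ValueError(f"block [{start}, {stop}) outside 0..{n_frames}")
        ramp[start:stop] += np.arange(1, stop - start + 1)
        ramp[stop:] += stop - start
    return ramp


def motion_pc1(motion: np.ndarray) -> np.ndarray:
    """First principal component of the six motion parameters (per frame)."""
    m = np.asarray(motion, dtype=float)
    m = m - m.mean(axis=0)
    u, s, _ = np.linalg.svd(m, full_matrices=False)
    return u[:, 0] * s[0]


@dataclass
class FpetDesign:
    """GLM design: baseline + one ramp per task condition + motion PC."""

    baseline: np.ndarray
    ramps: dict[str, np.ndarray]
    motion: np.ndarray | None = None

    def matrix(self) -> tuple[np.ndarray, list[str]]:
        cols = [np.asarray(self.baseline, dtype=float)]
        names = ["baseline"]
        for name, r in self.ramps.items():
            cols.append(np.asarray(r, dtype=float))
            names.append(name)
        if self.motion is not None:
            cols.append(np.asarray(self.motion, dtype=float))
            names.append("motion")
        X = np.column_stack(cols)
        for j, name in enumerate(names):
            if np.ptp(X[:, j]) == 0:
                raise ValueError(f"design column '{name}' is constant")
        return X, names


def lowpass_tacs(tacs: np.ndarray, frame_len_min: float, cutoff_min: float = 3.0) -> np.ndarray:
    """Low-pass filter TACs with a moving average of width = cutoff.

    Zero-phase and parameter-free; a constant TAC passes unchanged.
    ``tacs`` has frames on the last axis.
    """
    width = max(int(round(cutoff_min / frame_len_min)), 1)
    return uniform_filter1d(np.asarray(tacs, dtype=float), size=width, axis=-1, mode="nearest")


def fit_fpet_glm(
    tacs: np.ndarray,
    design: FpetDesign,
    frame_len_min: float = 0.5,
    lowpass_cutoff_min: float = 3.0,
) -> dict:
    """Per-voxel OLS of low-pass-filtered TACs on the fPET design.

    Returns the beta maps per column, the baseline-only reconstructed
    TACs (input to the Patlak fit) and the residuals.  ``tacs`` may be
    1D (one voxel) or (..., n_frames).
    """
    X, names = design.matrix()
    # data and regressors pass through the same low-pass filter, so a TAC
    # proportional to a regressor is recovered exactly
    X = lowpass_tacs(X.T, frame_len_min, lowpass_cutoff_min).T
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient fPET design")
    tacs = np.asarray(tacs, dtype=float)
    y = lowpass_tacs(tacs, frame_len_min, lowpass_cutoff_min)
    flat = y.reshape(-1, y.shape[-1]).T                      # frames × voxels
    beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
    fitted = X @ beta
    betas = {name: beta[j].reshape(tacs.shape[:-1]) for j, name in enumerate(names)}
    baseline_fit = np.moveaxis(
        np.outer(X[:, 0], beta[0]).reshape(X.shape[0], *tacs.shape[:-1]), 0, -1
    )
    resid = (flat - fitted).T.reshape(tacs.shape)
    return {"betas": betas, "baseline_fit": baseline_fit, "residuals": resid}


def patlak_ki(
    tac: np.ndarray,
    input_function: InputFunction,
    t_star_min: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Patlak graphical analysis of an irreversibly trapped tracer.

    The points (∫0..t Cp dτ / Cp(t), Ct(t)/Cp(t)) become linear once the
    reversible compartments equilibrate (t >= t*); the least-squares
    slope over that window is the influx constant Ki (1/min) and the
    intercept the effective distribution volume V0.  ``tac`` may be 1D
    or (..., n_frames); Ki/V0 then keep the leading shape.
    """
    t = input_function.frame_times
    window = t >= t_star_min
    if window.sum() < 3:
        raise ValueError("need >= 3 frames at or after t_star")
    cp = input_function.cp[window]
    if np.any(cp <= 0):
        raise ValueError("Cp must be positive in the Patlak window")
    x = input_function.cumulative_integral[window] / cp
    tac = np.asarray(tac, dtype=float)
    y = tac[..., window] / cp
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y.reshape(-1, window.sum()).T, rcond=None)
    ki = coef[0].reshape(tac.shape[:-1])
    v0 = coef[1].reshape(tac.shape[:-1])
    if tac.ndim == 1:
        return float(ki), float(v0)
    return ki, v0


def cmrglu_from_ki(ki, glu_plasma_mmol_l: float, lc: float = DEFAULT_LC):
    """Convert an influx-constant map (1/min) to CMRGlu (µmol/100g/min)."""
    if lc <= 0:
        raise ValueError("lumped constant must be > 0")
    return np.asarray(ki, dtype=float) * glu_plasma_mmol_l / lc * 100.0


def condition_ki(
    ki_base,
    task_beta,
    input_function: InputFunction,
    task_window: np.ndarray,
) -> np.ndarray:
    """Condition-specific Ki: baseline slope plus the task ramp's
    contribution, beta (kBq/ml per ramp unit) divided by the mean plasma
    activity over the task window (converting the per-frame uptake rate
    into an influx constant)."""
    cp_task = float(input_function.cp[np.asarray(task_window, dtype=bool)].mean())
    if cp_task <= 0:
        raise ValueError("mean Cp over the task window must be positive")
    frame_len = float(np.median(np.diff(input_function.frame_times)))
    return np.asarray(ki_base, dtype=float) + np.asarray(task_beta, dtype=float) / (
        cp_task * frame_len
    )


@dataclass
class KineticResult:
    """Bundle of Patlak outputs and the CMRGlu conversion."""

    ki: np.ndarray                 # 1/min
    v0: np.ndarray
    glu_plasma: float              # mmol/l
    lc: float = DEFAULT_LC
    cmrglu: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.lc <= 0:
            raise ValueError("lumped constant must be > 0")
        self.cmrglu = cmrglu_from_ki(self.ki, self.glu_plasma, self.lc)
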