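"""Cerebral blood flow quantification from pseudo-continuous ASL.

CBF in ml/100g/min is obtained from the control−label difference signal
with the single-compartment model

    CBF = λ·ΔM·R1a / (2α·M0·[exp(−ω·R1a) − exp(−(τ+ω)·R1a)])

where λ is the blood–tissue water partition coefficient, R1a the
longitudinal relaxation rate of arterial blood, α the labeling
efficiency, ω the post-labeling delay (growing with slice index in a 2D
readout) and τ the label duration.  All times are converted to seconds
internally; the result is rescaled from ml/g/s to ml/100g/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Image4D

__all__ = [
    "AslConstants",
    "CbfMaps",
    "mask_low_intensity",
    "compute_m0",
    "cbf_from_deltam",
    "deltam_from_cbf",
    "condition_cbf",
]

_ML_G_S_TO_ML_100G_MIN = 100.0 * 60.0


@dataclass(frozen=True)
class AslConstants:
    """Quantification constants (stored in conventional units)."""

    lambda_bt: float = 0.9       # blood-tissue partition coefficient, ml/g
    r1a: float = 0.67            # 1/s, longitudinal relaxation rate of blood
    alpha: float = 0.8           # labeling efficiency
    omega_base_ms: float = 1800  # post-labeling delay at slice 1, ms
    tau_ms: float = 1508         # label duration, ms
    slice_time_ms: float = 0.0   # per-slice delay increment of a 2D readout

    def __post_init__(self) -> None:
        if min(self.lambda_bt, self.r1a, self.alpha, self.omega_base_ms, self.tau_ms) <= 0:
            raise ValueError("ASL constants must be positive")
        if self.alpha > 1:
            raise ValueError("labeling efficiency alpha must be <= 1")
        if self.slice_time_ms < 0:
            raise ValueError("slice_time_ms must be >= 0")

    def omega_s(self, slice_index: int | np.ndarray) -> np.ndarray:
        """Post-labeling delay in seconds for a 1-based slice index."""
        return (self.omega_base_ms + (np.asarray(slice_index) - 1) * self.slice_time_ms) / 1000.0

    def denominator(self, slice_index: int | np.ndarray) -> np.ndarray:
        """exp(−ω·R1a) − exp(−(τ+ω)·R1a) at the slice's delay."""
        omega = self.omega_s(slice_index)
        tau = self.tau_ms / 1000.0
        return np.exp(-omega * self.r1a) - np.exp(-(tau + omega) * self.r1a)


@dataclass
class CbfMaps:
    rest: np.ndarray
    easy: np.ndarray
    hard: np.ndarray

    @property
    def task_delta_easy(self) -> np.ndarray:
        return self.easy - self.rest

    @property
    def task_delta_hard(self) -> np.ndarray:
        return self.hard - self.rest


def mask_low_intensity(series: np.ndarray, factor: float = 0.8) -> np.ndarray:
    """Zero voxels whose mean intensity is below ``factor`` times the
    global mean (spurious-signal suppression before quantification)."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    vox_mean = series.mean(axis=-1) if series.ndim == 4 else series
    cut = factor * series.mean()
    out = series.copy()
    out[vox_mean < cut] = 0.0
    return out


def _control_frames(n_frames: int, label_parity: str) -> np.ndarray:
    if label_parity not in ("control-first", "label-first"):
        raise ValueError("label_parity must be 'control-first' or 'label-first'")
    idx = np.arange(n_frames)
    return idx % 2 == (0 if label_parity == "control-first" else 1)


def compute_m0(series: np.ndarray, label_parity: str = "control-first") -> np.ndarray:
    """Equilibrium magnetization: voxelwise mean of the non-labeled frames."""
    series = np.asarray(series, dtype=float)
    ctrl = _control_frames(series.shape[-1], label_parity)
    if not ctrl.any():
        raise ValueError("no control frames")
    return series[..., ctrl].mean(axis=-1)


def cbf_from_deltam(
    dm: np.ndarray,
    m0: np.ndarray,
    constants: AslConstants = AslConstants(),
    slice_index: int | np.ndarray = 1,
) -> np.ndarray:
    """Convert a ΔM (control − label) map to CBF in ml/100g/min.

    ``slice_index`` is 1-based and may be an array broadcastable against
    the map (per-slice post-labeling delays).  Voxels with M0 <= 0 are
    masked to 0.
    """
    dm = np.asarray(dm, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    denom = 2.0 * constants.alpha * m0 * constants.denominator(slice_index)
    with np.errstate(divide="ignore", invalid="ignore"):
        cbf = constants.lambda_bt * dm * constants.r1a / denom
    cbf = np.where(m0 > 0, cbf, 0.0)
    return cbf * _ML_G_S_TO_ML_100G_MIN


def deltam_from_cbf(
    cbf: np.ndarray,
    m0: np.ndarray,
    constants: AslConstants = AslConstants(),
    slice_index: int | np.ndarray = 1,
) -> np.ndarray:
    """Inverse of :func:`cbf_from_deltam`: ΔM producing a given CBF."""
    cbf = np.asarray(cbf, dtype=float) / _ML_G_S_TO_ML_100G_MIN
    m0 = np.asarray(m0, dtype=float)
    denom = 2.0 * constants.alpha * m0 * constants.denominator(slice_index)
    return cbf * denom / (constants.lambda_bt * constants.r1a)


def _slice_index_grid(shape: tuple[int, ...]) -> np.ndarray:
    """1-based slice index along z, broadcastable to a 3D map."""
    return np.arange(1, shape[2] + 1)[None, None, :]


def _condition_mean_cbf(
    series: np.ndarray,
    constants: AslConstants,
    label_parity: str,
) -> np.ndarray:
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    if n % 2:
        raise ValueError("odd frame count: control/label frames must pair up")
    ctrl = _control_frames(n, label_parity)
    pairs_ctrl = series[..., ctrl]
    pairs_label = series[..., ~ctrl]
    dm = pairs_ctrl - pairs_label          # pairwise control − label
    m0 = compute_m0(series, label_parity)
    sl = _slice_index_grid(series.shape[:3])
    cbf_pairs = cbf_from_deltam(dm, m0[..., None], constants, sl[..., None])
    return cbf_pairs.mean(axis=-1)


def condition_cbf(
    rest: Image4D | np.ndarray,
    easy: Image4D | np.ndarray,
    hard: Image4D | np.ndarray,
    constants: AslConstants = AslConstants(),
    label_parity: str = "control-first",
    intensity_factor: float | None = 0.8,
) -> CbfMaps:
    """Quantify per-condition CBF maps; task maps carry rest+task signal,
    so the task-specific change is read from ``task_delta_*``."""
    maps = []
    for s in (rest, easy, hard):
        arr = s.data if isinstance(s, Image4D) else np.asarray(s, dtype=float)
        if intensity_factor is not None:
            arr = mask_low_intensity(arr, intensity_factor)
        maps.append(_condition_mean_cbf(arr, constants, label_parity))
    return CbfMaps(rest=maps[0], easy=maps[1], hard=maps[2])
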