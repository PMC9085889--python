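"""BOLD preprocessing for functional connectivity and a block-design GLM.

Connectivity preprocessing follows the scrubbing approach: framewise
displacement from the six realignment parameters (rotations expressed as
arc length on a 50 mm sphere), censoring of frames with FD > 0.5 mm plus
one frame back and two forward, nuisance regression (motion, white
matter, CSF) and a 0.01–0.15 Hz bandpass, applied to the retained
frames.  Activation maps come from an ordinary block GLM with a
canonical double-gamma hemodynamic response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy import stats as sps

__all__ = [
    "ScrubResult",
    "framewise_displacement",
    "scrub",
    "clean_timeseries",
    "double_gamma_hrf",
    "block_regressor",
    "block_glm",
]


def framewise_displacement(motion: np.ndarray, radius_mm: float = 50.0) -> np.ndarray:
    """Framewise displacement from a (n_frames, 6) motion trace.

    Backward differences of the three translations (mm) and the three
    rotations (rad, converted to displacement on a ``radius_mm`` sphere),
    summed as absolute values; the first frame gets FD = 0.
    """
    m = np.asarray(motion, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError("motion must be (n_frames, 6): 3 translations + 3 rotations")
    if m.shape[0] < 2:
        raise ValueError("need >= 2 frames")
    if not np.all(np.isfinite(m)):
        raise ValueError("motion trace contains non-finite values")
    d = np.abs(np.diff(m, axis=0))
    fd = d[:, :3].sum(axis=1) + radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def scrub(fd: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Censoring mask: frames with FD > threshold are removed together
    with one frame back and two forward; returns the kept-frame mask."""
    fd = np.asarray(fd, dtype=float)
    n = len(fd)
    kept = np.ones(n, dtype=bool)
    for t in np.flatnonzero(fd > threshold):
        kept[max(t - 1, 0): min(t + 3, n)] = False
    return kept


@dataclass
class ScrubResult:
    fd: np.ndarray
    kept: np.ndarray

    @property
    def pct_removed(self) -> float:
        return 100.0 * (1.0 - self.kept.mean())


def scrub_motion(motion: np.ndarray, threshold: float = 0.5, radius_mm: float = 50.0) -> ScrubResult:
    fd = framewise_displacement(motion, radius_mm)
    return ScrubResult(fd=fd, kept=scrub(fd, threshold))


def _bandpass_sos(band: tuple[float, float], tr: float):
    nyq = 0.5 / tr
    low, high = band
    if not 0 < low < high:
        raise ValueError("band must satisfy 0 < low < high")
    if high >= nyq:
        return signal.butter(4, low / nyq, btype="highpass", output="sos")
    return signal.butter(4, [low / nyq, high / nyq], btype="bandpass", output="sos")


def clean_timeseries(
    series: np.ndarray,
    kept: np.ndarray | None,
    nuisance: np.ndarray | None,
    tr: float,
    band: tuple[float, float] = (0.01, 0.15),
) -> np.ndarray:
    """Censor, regress nuisance signals and bandpass a voxel×time matrix.

    ``series`` is (n_voxels, n_frames) (a single 1D series also works);
    censored frames are dropped first, the nuisance columns (plus an
    intercept) are regressed out by least squares, and a 4th-order
    zero-phase Butterworth bandpass is applied to the retained,
    re-indexed frames.  Returns the cleaned (n_voxels, n_kept) matrix.
    """
    y = np.atleast_2d(np.asarray(series, dtype=float))
    n = y.shape[1]
    if kept is not None:
        kept = np.asarray(kept, dtype=bool)
        if len(kept) != n:
            raise ValueError("kept mask length mismatch")
        y = y[:, kept]
    if y.shape[1] < 20:
        raise ValueError("too few retained frames (< 20)")
    cols = [np.ones(y.shape[1])]
    if nuisance is not None:
        nuis = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuis.shape[0] == n and kept is not None:
            nuis = nuis[kept]
        elif nuis.shape[0] != y.shape[1]:
            raise ValueError("nuisance rows must match frames (before or after censor)")
        cols.append(nuis)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    resid = y - (X @ beta).T
    sos = _bandpass_sos(band, tr)
    cleaned = signal.sosfiltfilt(sos, resid, axis=1)
    return cleaned if np.asarray(series).ndim > 1 else cleaned[0]


def double_gamma_hrf(tr: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at the repetition time
    (peak 6 s, undershoot 16 s, undershoot ratio 1/6), unit peak."""
    t = np.arange(0, duration_s, tr)
    peak = sps.gamma.pdf(t, 6)
    undershoot = sps.gamma.pdf(t, 16)
    h = peak - undershoot / 6.0
    return h / h.max()


def block_regressor(
    n_frames: int, blocks: list[tuple[int, int]], tr: float, hrf: np.ndarray | None = None
) -> np.ndarray:
    """Boxcar over ``[start, stop)`` frame blocks convolved with the HRF."""
    box = np.zeros(n_frames)
    for start, stop in blocks:
        if not (0 <= start < stop <= n_frames):
            raise ValueError(f"block [{start}, {stop}) outside 0..{n_frames}")
        box[start:stop] = 1.0
    h = double_gamma_hrf(tr) if hrf is None else np.asarray(hrf, dtype=float)
    return np.convolve(box, h)[:n_frames]


def block_glm(
    series: np.ndarray,
    design: np.ndarray,
    contrasts: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Per-voxel OLS t-statistics for each contrast.

    ``series`` is (n_voxels, n_frames) or 1D, ``design`` (n_frames, p)
    with HRF-convolved condition regressors (an intercept is appended),
    ``contrasts`` maps a name to a length-p weight vector.
    """
    y = np.atleast_2d(np.asarray(series, dtype=float))
    X = np.asarray(design, dtype=float)
    X = np.column_stack([X, np.ones(X.shape[0])])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient block design")
    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    resid = y.T - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    out = {}
    for name, c in contrasts.items():
        c = np.concatenate([np.asarray(c, dtype=float), [0.0]])  # intercept weight 0
        var = sigma2 * (c @ xtx_inv @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(var > 0, (c @ beta) / np.sqrt(var), 0.0)
        out[name] = t if np.asarray(series).ndim > 1 else float(t[0])
    out["dof"] = dof
    return out
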