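"""Metabolic connectivity mapping (MCM).

MCM assigns a directional connectivity value to every source voxel A_i:
the BOLD series of A_i is temporally correlated with every voxel of a
target region B (Fisher z), and that spatial FC pattern over B is then
spatially correlated with B's CMRGlu pattern; the Fisher z of this
spatial correlation is the MCM value of A_i.  Because energy demands
arise predominantly post-synaptically, a match between a source voxel's
FC pattern and the target's metabolic pattern is read as influence *from*
the source *onto* the target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import Image4D, check_same_grid

__all__ = [
    "R_CLIP",
    "fisher_z",
    "fc_pattern",
    "mcm_value",
    "mcm_map",
    "MCMMap",
    "temporal_corr",
    "spatial_corr_masked",
]

R_CLIP = 1.0 - 1e-7


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with |r| clipped at 1 − 1e−7 (finite z at perfect correlation)."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def _standardize(ts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize a frames×voxels matrix; flag zero-variance columns."""
    ts = np.asarray(ts, dtype=float)
    mean = ts.mean(axis=0)
    sd = ts.std(axis=0)
    ok = sd > 0
    z = np.zeros_like(ts)
    np.divide(ts - mean, sd, out=z, where=ok)
    return z, ok


def temporal_corr(source_ts: np.ndarray, target_ts: np.ndarray) -> np.ndarray:
    """Pearson correlation of each source column with each target column.

    ``source_ts`` (T, Ns) and ``target_ts`` (T, Nt) share the frame axis;
    returns (Ns, Nt).  Zero-variance columns yield r = 0.
    """
    src = np.atleast_2d(np.asarray(source_ts, dtype=float).T).T
    tgt = np.asarray(target_ts, dtype=float)
    if src.shape[0] != tgt.shape[0]:
        raise ValueError("source and target series must share frames")
    zs, _ = _standardize(src)
    zt, _ = _standardize(tgt)
    return zs.T @ zt / src.shape[0]


def fc_pattern(source_ts: np.ndarray, target_ts: np.ndarray) -> np.ndarray:
    """FC pattern of one source voxel over the target region.

    Pearson r of the source series with each target voxel's series,
    Fisher z-transformed.  A zero-variance source series is an error;
    zero-variance target voxels contribute z = 0 (with a warning) so the
    pattern length stays fixed across subjects.
    """
    src = np.asarray(source_ts, dtype=float)
    tgt = np.asarray(target_ts, dtype=float)
    if src.ndim != 1:
        raise ValueError("source_ts must be one voxel's series")
    if len(src) < 10:
        raise ValueError("need >= 10 retained frames")
    if src.std() == 0:
        raise ValueError("zero-variance source series")
    _, ok = _standardize(tgt)
    if not ok.all():
        warnings.warn("zero-variance target voxels set to z = 0", stacklevel=2)
    r = temporal_corr(src[:, None], tgt)[0]
    return fisher_z(r)


def mcm_value(fc: np.ndarray, cmrglu_pattern: np.ndarray) -> float:
    """MCM value: Fisher z of the spatial Pearson correlation between an
    FC pattern and the CMRGlu pattern across the target voxels."""
    fc = np.asarray(fc, dtype=float)
    c = np.asarray(cmrglu_pattern, dtype=float)
    if fc.shape != c.shape or fc.ndim != 1:
        raise ValueError("fc and cmrglu_pattern must be equal-length vectors")
    if len(fc) < 4:
        raise ValueError("need a target of >= 4 voxels")
    if c.std() == 0:
        raise ValueError("constant CMRGlu pattern: spatial correlation undefined")
    if fc.std() == 0:
        return 0.0
    r = float(np.corrcoef(fc, c)[0, 1])
    return float(fisher_z(r))


def spatial_corr_masked(
    z_patterns: np.ndarray, cmrglu_pattern: np.ndarray, masks: np.ndarray
) -> np.ndarray:
    """Spatial correlation of many FC patterns with the CMRGlu pattern
    under many target-voxel selections at once.

    ``z_patterns`` (Ns, Nt), ``cmrglu_pattern`` (Nt,), ``masks`` (M, Nt)
    boolean; returns r of shape (M, Ns).  Used by the voxel-removal
    perturbation, where the temporal correlations are fixed and only the
    retained target subset changes.
    """
    Z = np.asarray(z_patterns, dtype=float)
    c = np.asarray(cmrglu_pattern, dtype=float)
    M = np.asarray(masks, dtype=float)
    n = M.sum(axis=1, keepdims=True)                       # (M, 1)
    sz = M @ Z.T                                           # Σ z     (M, Ns)
    szz = M @ (Z**2).T                                     # Σ z²
    sc = M @ c                                             # Σ c     (M,)
    scc = M @ c**2
    szc = M @ (Z * c).T                                    # Σ z·c   (M, Ns)
    cov = szc - sz * (sc / n.ravel())[:, None]
    var_z = szz - sz**2 / n
    var_c = (scc - sc**2 / n.ravel())[:, None]
    denom = np.sqrt(np.clip(var_z * var_c, 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, cov / denom, 0.0)
    return r


@dataclass
class MCMMap:
    """Whole-brain map of directional connectivity toward one target."""

    values: np.ndarray             # 3D z map (0 outside source set)
    source_mask: np.ndarray
    target_mask: np.ndarray


def mcm_map(
    bold: Image4D | np.ndarray,
    target_mask: np.ndarray,
    cmrglu_map: np.ndarray,
    brain_mask: np.ndarray,
    exclude_target: bool = True,
) -> MCMMap:
    """Compute the MCM value for every source voxel in the brain mask.

    ``bold`` is the cleaned 4D series; the target's CMRGlu pattern comes
    from the condition-matched ``cmrglu_map``.  Target voxels are by
    default excluded from the source set (self-correlation inflates the
    spatial match).
    """
    data = bold.data if isinstance(bold, Image4D) else np.asarray(bold, dtype=float)
    target_mask = np.asarray(target_mask, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    check_same_grid(data, target_mask, np.asarray(cmrglu_map), brain_mask)
    if not target_mask.any() or not brain_mask.any():
        raise ValueError("empty target or brain mask")
    source_mask = brain_mask & ~target_mask if exclude_target else brain_mask

    tgt_ts = data[target_mask].T                       # T × Nt
    src_ts = data[source_mask].T                       # T × Ns
    c = np.asarray(cmrglu_map, dtype=float)[target_mask]
    if c.std() == 0:
        raise ValueError("constant CMRGlu pattern over the target")

    z_patterns = fisher_z(temporal_corr(src_ts, tgt_ts))           # Ns × Nt
    r = spatial_corr_masked(z_patterns, c, np.ones((1, len(c)), dtype=bool))[0]
    values = np.zeros(data.shape[:3])
    values[source_mask] = fisher_z(r)
    return MCMMap(values=values, source_mask=source_mask, target_mask=target_mask)
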