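"""Voxel-removal perturbation of the MCM learning effect.

To attribute a training effect to one of MCM's two ingredients, target
voxels are removed in 10% steps — ordered by their CMRGlu value, by
their FC value (lowest first), or at random — and the group×time
interaction F for the condition of interest is recomputed at every step.
If the effect is carried by the spatial structure of one parameter, the
value-ordered removal of that parameter destroys it while random
removal, which merely subsamples the pattern, does not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from . import mcm as mcm_mod
from .stats import posthoc_interaction_f
from .synthetic import CONDITIONS, TIMES

__all__ = ["PerturbationCurve", "reduce_target", "perturbation_curve", "driver_value_map"]

DRIVERS = ("cmrglu", "fc", "random")


def reduce_target(target, value_map, fraction: float, highest_first: bool = False):
    """Remove the ⌊fraction·n⌋ lowest-valued target voxels.

    Works on a 3D boolean mask with a 3D value map, or on 1D per-voxel
    arrays; ties are broken by ascending linear voxel index (stable
    sort), and ``highest_first`` flips the removal order (debug aid).
    Returns the reduced mask in the input's shape.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    target = np.asarray(target, dtype=bool)
    values = np.asarray(value_map, dtype=float)
    if target.ndim == 1:
        vals, keep = values, target.copy()
        idx_in_target = np.flatnonzero(target)
        vals = values[idx_in_target] if values.shape == target.shape else values
    else:
        if values.shape != target.shape:
            raise ValueError("value_map must match the target grid")
        idx_in_target = np.flatnonzero(target.ravel())
        vals = values.ravel()[idx_in_target]
        keep = target.copy()
    n = len(idx_in_target)
    n_remove = int(np.floor(fraction * n))
    if n - n_remove < 4:
        raise ValueError("reduction leaves fewer than 4 target voxels")
    order = np.argsort(-vals if highest_first else vals, kind="stable")
    removed = idx_in_target[order[:n_remove]]
    if target.ndim == 1:
        keep[removed] = False
    else:
        keep.ravel()[removed] = False
    return keep


@dataclass
class PerturbationCurve:
    fractions: np.ndarray
    f_values: np.ndarray
    p_values: np.ndarray
    driver: str
    condition: str
    n_random: int
    f_critical: float          # F at α = 0.05 for the group×time test

    def __post_init__(self) -> None:
        if np.any(np.diff(self.fractions) <= 0):
            raise ValueError("fractions must be strictly increasing")


def driver_value_map(study, driver: str, condition: str) -> np.ndarray:
    """Per-target-voxel ordering value, computed once at fraction 0.

    cmrglu: mean CMRGlu pattern across all subjects; fc: mean Fisher-z
    connectivity of each target voxel with the cluster voxels at the
    first scan.  Reusing the fraction-0 map keeps the removal nested.
    """
    n_sub = len(study.groups)
    if driver == "cmrglu":
        return np.mean([study.cmrglu_patterns[(i, condition)] for i in range(n_sub)], axis=0)
    if driver == "fc":
        return np.mean(
            [study.z_patterns[(i, "M1", condition)].mean(axis=0) for i in range(n_sub)], axis=0
        )
    raise ValueError(f"no value map for driver '{driver}'")


def _cell_values(study, condition: str, masks: np.ndarray) -> np.ndarray:
    """Cluster-mean MCM z per (subject, time) under each target-voxel
    selection, averaged over the selections: (n_subjects, 2)."""
    n_sub = len(study.groups)
    out = np.empty((n_sub, len(TIMES)))
    for i in range(n_sub):
        c = study.cmrglu_patterns[(i, condition)]
        for t_idx, time in enumerate(TIMES):
            z = study.z_patterns[(i, time, condition)]
            r = mcm_mod.spatial_corr_masked(z, c, masks)
            out[i, t_idx] = mcm_mod.fisher_z(r).mean()
    return out


def perturbation_curve(
    study,
    driver: str,
    condition: str = "rest",
    fractions=None,
    n_random: int = 500,
    seed: int = 0,
) -> PerturbationCurve:
    """Recompute the group×time interaction F while removing target voxels.

    ``study`` is any object exposing ``groups``, ``z_patterns`` keyed by
    (subject, time, condition) and ``cmrglu_patterns`` keyed by
    (subject, condition) — :class:`mcmflow.synthetic.StudyMCM` or the
    equivalent bundle assembled from a file-based analysis.

    For the value drivers the removal order comes from the fraction-0
    CMRGlu or FC map (lowest first, nested across fractions); for the
    random driver the MCM z-scores are averaged over ``n_random`` seeded
    random selections before the F computation.  The fraction-0 entry
    equals the unperturbed analysis exactly.
    """
    if driver not in DRIVERS:
        raise ValueError(f"driver must be one of {DRIVERS}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition '{condition}'")
    fractions = np.round(np.arange(0.0, 1.0, 0.1), 10) if fractions is None else np.asarray(fractions, dtype=float)
    n_t = len(next(iter(study.cmrglu_patterns.values())))
    rng = np.random.default_rng(seed)
    values = None if driver == "random" else driver_value_map(study, driver, condition)

    f_vals, p_vals = [], []
    for frac in fractions:
        n_remove = int(np.floor(frac * n_t))
        n_keep = n_t - n_remove
        if n_keep < 4:
            raise ValueError("reduction leaves fewer than 4 target voxels")
        if driver == "random":
            if frac == 0:
                masks = np.ones((1, n_t), dtype=bool)
            else:
                masks = np.zeros((n_random, n_t), dtype=bool)
                for m in masks:
                    m[rng.choice(n_t, size=n_keep, replace=False)] = True
        else:
            keep = reduce_target(np.ones(n_t, dtype=bool), values, float(frac))
            masks = keep[None, :]
        cell = _cell_values(study, condition, masks)
        res = posthoc_interaction_f(cell[:, 1] - cell[:, 0], study.groups)
        f_vals.append(res.F)
        p_vals.append(res.p)

    df2 = len(study.groups) - 2
    return PerturbationCurve(
        fractions=fractions,
        f_values=np.array(f_vals),
        p_values=np.array(p_vals),
        driver=driver,
        condition=condition,
        n_random=n_random if driver == "random" else 0,
        f_critical=float(sps.f.isf(0.05, 1, df2)),
    )
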