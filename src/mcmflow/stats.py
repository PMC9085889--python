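"""Group-level inference for the longitudinal PET/MR study.

The central model is a three-factor repeated-measures ANOVA with factors
group (training, control; between subjects), time (scan 1, scan 2) and
condition (rest, easy, hard).  Time is folded in by analysing per-subject
scan-2 minus scan-1 differences, so the group main effect on differences
is the group×time interaction and the group×condition effect on
differences is the group×time×condition interaction.  Post-hoc tests,
Bonferroni–Holm correction, permutation cluster inference on difference
maps, rank correlations with behaviour, and the behavioural summaries
(score per minute, fold changes, normalised learning-curve AUC, the
Tetris scoring rule) live here as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "rm_anova_gtc",
    "posthoc",
    "holm",
    "cluster_permutation",
    "PermutationClusters",
    "divergence",
    "spearman",
    "behavior_summary",
    "tetris_score",
]


@dataclass
class AnovaResult:
    effect: str
    F: float
    df1: int
    df2: int
    p: float

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("F must be >= 0")


def _check_gtc_input(values: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.ndim != 3 or values.shape[1] != 2:
        raise ValueError("values must be (n_subjects, 2 times, n_conditions)")
    if len(groups) != values.shape[0]:
        raise ValueError("groups length must match n_subjects")
    if not np.all(np.isfinite(values)):
        raise ValueError("missing cells: values contain non-finite entries")
    return values, groups


def rm_anova_gtc(values: np.ndarray, groups: np.ndarray) -> dict[str, AnovaResult]:
    """Three-factor group×time×condition repeated-measures ANOVA.

    Parameters
    ----------
    values :
        Array (n_subjects, 2, n_conditions): one scalar per subject, scan
        and condition (e.g. cluster-mean MCM z-scores).
    groups :
        Group label per subject (two levels).

    Returns
    -------
    dict
        Effects on the scan-2 − scan-1 differences: ``"group_x_time"``
        (group main effect on differences), ``"time_x_condition"``
        (condition main effect), ``"group_x_time_x_condition"`` (the
        training-effect interaction) and, with three conditions, the
        planned contrast ``"group_x_time_rest_vs_task"`` comparing rest
        against the mean of the task conditions.
    """
    values, groups = _check_gtc_input(values, groups)
    diffs = values[:, 1, :] - values[:, 0, :]  # (n_subjects, n_conditions)
    n_sub, n_cond = diffs.shape
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("exactly two groups required")

    grand = diffs.mean()
    subj_means = diffs.mean(axis=1)
    cond_means = diffs.mean(axis=0)
    group_sizes = np.array([(groups == g).sum() for g in levels])
    if group_sizes.min() < 2:
        raise ValueError("need >= 2 subjects per group")
    group_means = np.array([diffs[groups == g].mean() for g in levels])
    cell_means = np.array([diffs[groups == g].mean(axis=0) for g in levels])

    ss_total = ((diffs - grand) ** 2).sum()
    ss_between_subj = n_cond * ((subj_means - grand) ** 2).sum()
    ss_group = n_cond * (group_sizes * (group_means - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group
    ss_cond = n_sub * ((cond_means - grand) ** 2).sum()
    ss_cells = (group_sizes[:, None] * (cell_means - grand) ** 2).sum()
    ss_gxc = ss_cells - ss_group - ss_cond
    ss_err = ss_total - ss_between_subj - ss_cond - ss_gxc

    df_group, df_subj = 1, n_sub - 2
    df_cond = n_cond - 1
    df_gxc = df_group * df_cond
    df_err = df_subj * df_cond

    def _f(ss, df, ss_e, df_e, name):
        ms, ms_e = ss / df, ss_e / df_e
        if ms_e <= 0:
            f = 0.0 if ms <= 0 else np.inf
        else:
            f = max(ms / ms_e, 0.0)
        p = float(sps.f.sf(f, df, df_e)) if np.isfinite(f) else 0.0
        return AnovaResult(name, float(f), df, df_e, max(p, np.finfo(float).tiny))

    out = {
        "group_x_time": _f(ss_group, df_group, ss_subj_within, df_subj, "group_x_time"),
    }
    if n_cond > 1:
        out["time_x_condition"] = _f(ss_cond, df_cond, ss_err, df_err, "time_x_condition")
        out["group_x_time_x_condition"] = _f(
            ss_gxc, df_gxc, ss_err, df_err, "group_x_time_x_condition"
        )
    if n_cond == 3:
        # planned contrast on differences: rest vs mean(easy, hard)
        contrast = diffs[:, 0] - 0.5 * (diffs[:, 1] + diffs[:, 2])
        res = posthoc_interaction_f(contrast, groups)
        res.effect = "group_x_time_rest_vs_task"
        out["group_x_time_rest_vs_task"] = res
    return out


def posthoc_interaction_f(diffs: np.ndarray, groups: np.ndarray) -> AnovaResult:
    """Group×time interaction for one condition: two-sample comparison of
    the per-subject scan differences (F = t² of the independent t-test)."""
    diffs = np.asarray(diffs, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    a, b = diffs[groups == levels[0]], diffs[groups == levels[1]]
    if min(len(a), len(b)) < 2:
        raise ValueError("need >= 2 subjects per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return AnovaResult("group_x_time", 0.0, 1, len(a) + len(b) - 2, 1.0)
        return AnovaResult("group_x_time", np.inf, 1, len(a) + len(b) - 2, 0.0)
    t, p = sps.ttest_ind(a, b)
    return AnovaResult("group_x_time", float(t) ** 2, 1, len(a) + len(b) - 2, float(p))


def posthoc(values: np.ndarray, groups: np.ndarray, condition: int) -> dict:
    """Post-hoc tests for one condition.

    Returns the group×time interaction (on scan differences) and the
    paired t-test of the time effect within each group.
    """
    values, groups = _check_gtc_input(values, groups)
    diffs = values[:, 1, condition] - values[:, 0, condition]
    inter = posthoc_interaction_f(diffs, groups)
    within = {}
    for g in pd.unique(groups):
        d = diffs[groups == g]
        if d.std(ddof=1) == 0:
            t = 0.0 if d.mean() == 0 else np.sign(d.mean()) * np.inf
            p = 1.0 if d.mean() == 0 else 0.0
        else:
            t, p = sps.ttest_1samp(d, 0.0)
        within[g] = {"t": float(t), "p": float(p), "df": len(d) - 1, "mean_diff": float(d.mean())}
    return {"interaction": inter, "within_group": within}


def holm(p_values) -> np.ndarray:
    """Bonferroni–Holm step-down adjustment, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


@dataclass
class PermutationClusters:
    labels: np.ndarray            # cluster labels of significant clusters
    extents: np.ndarray           # voxel counts of significant clusters
    p_values: np.ndarray          # permutation p per significant cluster
    extent_threshold: float       # 95th percentile of the max-extent null
    t_map: np.ndarray
    t_threshold: float


def cluster_permutation(
    maps: np.ndarray,
    groups: np.ndarray,
    n_perm: int = 2000,
    cluster_forming_p: float = 0.001,
    seed: int | None = None,
) -> PermutationClusters:
    """Cluster-extent permutation test on subject-level difference maps.

    A two-sample t-map (training vs control differences) is thresholded
    at the two-sided cluster-forming level; the family-wise null is the
    maximum 26-connected cluster extent under random group-label
    exchanges, and clusters above its 95th percentile are reported.
    """
    maps = np.asarray(maps, dtype=float)
    groups = np.asarray(groups)
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n_sub = maps.shape[0]
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    ga = groups == levels[0]
    from math import comb

    if comb(n_sub, int(ga.sum())) < 100:
        raise ValueError("too few subjects for >= 100 unique permutations")

    df = n_sub - 2
    t_thr = sps.t.isf(cluster_forming_p / 2, df)
    struct = np.ones((3, 3, 3), dtype=bool)

    flat = maps.reshape(n_sub, -1)

    def _tmap(mask_a: np.ndarray) -> np.ndarray:
        a, b = flat[mask_a], flat[~mask_a]
        na, nb = len(a), len(b)
        ma, mb = a.mean(0), b.mean(0)
        va = a.var(0, ddof=1)
        vb = b.var(0, ddof=1)
        sp = ((na - 1) * va + (nb - 1) * vb) / df
        denom = np.sqrt(sp * (1 / na + 1 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(denom > 0, (ma - mb) / denom, 0.0)
        return t.reshape(maps.shape[1:])

    def _max_extent(t: np.ndarray) -> int:
        lab, n = ndimage.label(np.abs(t) > t_thr, structure=struct)
        if n == 0:
            return 0
        return int(np.bincount(lab.ravel())[1:].max())

    t_obs = _tmap(ga)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n_sub)
        null[i] = _max_extent(_tmap(ga[perm]))
    thr = float(np.quantile(null, 0.95))

    lab, n = ndimage.label(np.abs(t_obs) > t_thr, structure=struct)
    sizes = np.bincount(lab.ravel())[1:] if n else np.array([], dtype=int)
    keep = np.flatnonzero(sizes > thr) + 1
    out_lab = np.zeros_like(lab)
    extents, pvals = [], []
    for new, old in enumerate(keep, start=1):
        out_lab[lab == old] = new
        ext = int(sizes[old - 1])
        extents.append(ext)
        pvals.append(float((np.sum(null >= ext) + 1) / (n_perm + 1)))
    return PermutationClusters(
        labels=out_lab,
        extents=np.array(extents, dtype=int),
        p_values=np.array(pvals),
        extent_threshold=thr,
        t_map=t_obs,
        t_threshold=float(t_thr),
    )


def divergence(mcm_rest, mcm_hard):
    """Rest/task divergence score (rest − task) / mean(rest, task).

    Summarises the complementary learning effects — MCM increase at rest
    and decrease during the hard task — in one number per subject while
    normalising away the absolute MCM level.
    """
    rest = np.asarray(mcm_rest, dtype=float)
    hard = np.asarray(mcm_hard, dtype=float)
    mean = 0.5 * (rest + hard)
    if np.any(mean == 0):
        raise ValueError("divergence undefined where mean(rest, hard) = 0")
    return (rest - hard) / mean


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (rho, p); average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def tetris_score(lines_cleared: int, speed_level: int) -> int:
    """Score for clearing 1–4 lines simultaneously at speed level n.

    Standard Tetris rule k·(n+1) with k = 40, 100, 300, 1200 for one to
    four lines.
    """
    k = {1: 40, 2: 100, 3: 300, 4: 1200}
    if lines_cleared not in k:
        raise ValueError("lines_cleared must be in 1..4")
    if not (isinstance(speed_level, (int, np.integer)) and speed_level >= 0):
        raise ValueError("speed_level must be a non-negative integer")
    return k[lines_cleared] * (speed_level + 1)


def behavior_summary(table: pd.DataFrame) -> dict:
    """Summarise a behaviour table (scan scores + daily training scores).

    Expected columns: subject, group, kind ('scan'|'training'), time
    ('M1'/'M2' for scans, day number for training), condition, score_per_min.

    Returns per-condition fold changes for each group — both the ratio of
    group means (M2/M1) and the group mean of per-subject ratios — and the
    per-subject normalised learning-curve AUC (trapezoid over training
    days divided by the training-period length, i.e. the mean daily
    score).
    """
    scans = table[table["kind"] == "scan"]
    if scans.empty:
        raise ValueError("missing scan rows")
    folds: dict[str, dict[str, dict[str, float]]] = {}
    for group, gtab in scans.groupby("group"):
        folds[group] = {}
        for cond, ctab in gtab.groupby("condition"):
            piv = ctab.pivot_table(index="subject", columns="time", values="score_per_min")
            if not {"M1", "M2"}.issubset(piv.columns):
                raise ValueError("missing scans: need both M1 and M2 per condition")
            folds[group][cond] = {
                "ratio_of_means": float(piv["M2"].mean() / piv["M1"].mean()),
                "mean_of_ratios": float((piv["M2"] / piv["M1"]).mean()),
            }

    auc: dict = {}
    training = table[table["kind"] == "training"]
    for subj, stab in training.groupby("subject"):
        stab = stab.sort_values("time")
        days = stab["time"].to_numpy(dtype=float)
        score = stab["score_per_min"].to_numpy(dtype=float)
        if len(days) == 1 or days[-1] == days[0]:
            auc[subj] = float(score.mean())
        else:
            auc[subj] = float(np.trapezoid(score, days) / (days[-1] - days[0]))

    return {"fold_changes": folds, "auc_norm": auc}
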