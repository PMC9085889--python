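"""End-to-end pipeline driver: simulate → quantify → conjunction → MCM →
statistics → perturbation, with a manifest of seeds and output hashes.

Every stage is a pure function of (inputs, config, seed).  The driver
operates on the file layout written by
:func:`mcmflow.synthetic.generate_study` and writes NIfTI maps and TSV
tables beneath the configured output directory.  No spatial
registration is performed: all images must share one grid.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from scipy import stats as sps

from . import asl as asl_mod
from . import bold as bold_mod
from . import conjunction as conj_mod
from . import mcm as mcm_mod
from . import pet as pet_mod
from . import stats as stats_mod
from . import perturb as perturb_mod
from .io import read_image, read_table, write_image, write_table
from .synthetic import (
    CONDITIONS,
    TIMES,
    SyntheticConfig,
    bold_task_blocks,
    generate_study,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Schema-validated pipeline configuration (unknown keys rejected)."""

    out_dir: str = "mcmflow_out"
    seed: int = 0
    simulate: dict = field(default_factory=dict)   # SyntheticConfig overrides
    lc: float = 0.89
    t_star_min: float = 10.0
    fd_threshold_mm: float = 0.5
    band_hz: tuple[float, float] = (0.01, 0.15)
    activation_p: float = 0.001
    min_cluster_cm3: float = 1.0
    voxel_volume_cm3: float = 1.0
    n_perm: int = 500
    cluster_forming_p: float = 0.001
    n_random: int = 500
    require_asl: bool = True     # if False, conjunction uses CMRGlu+BOLD only

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "simulate" in raw:
            sim_known = {f.name for f in dataclasses.fields(SyntheticConfig)}
            bad = set(raw["simulate"]) - sim_known
            if bad:
                raise ValueError(f"unknown simulate keys: {sorted(bad)}")
        if "band_hz" in raw:
            raw["band_hz"] = tuple(raw["band_hz"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _one_sample_t(maps: np.ndarray) -> np.ndarray:
    """Voxelwise one-sample t across subjects (axis 0)."""
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a freshly simulated study; returns a result
    bundle with file paths, the fitted statistics and the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "notes": []}

    # ---- simulate -------------------------------------------------------
    sim_cfg = SyntheticConfig(**{**config.simulate, "seed": config.seed})
    study_dir = out / "study"
    design, gt = generate_study(sim_cfg, study_dir)
    manifest["stages"].append("simulate")
    groups_per_subject = (
        design[["subject_id", "group"]].drop_duplicates().set_index("subject_id")["group"]
    )
    subjects = list(groups_per_subject.index)
    groups = groups_per_subject.to_numpy()
    masks = {name: read_image(study_dir / f"mask_{name}.nii.gz").data > 0.5
             for name in ("target", "source", "brain", "gm")}

    frame_times_min = sim_cfg.pet_frame_times_min()
    pet_blocks = sim_cfg.pet_task_blocks()

    def cell_rows(subject, time):
        return design[(design.subject_id == subject) & (design.time == time)]

    # ---- PET quantification --------------------------------------------
    cmrglu_maps: dict = {}
    for subject in subjects:
        for time in TIMES:
            row = cell_rows(subject, time).iloc[0]
            tacs = read_image(study_dir / row["fpet"]).data
            blood = read_table(study_dir / row["blood"])
            inp = pet_mod.assemble_input_function(blood, frame_times_min)
            baseline = pet_mod.build_baseline_regressor(tacs, masks["gm"], masks["target"])
            motion = read_table(study_dir / row["motion"]).to_numpy()[: sim_cfg.n_frames_pet]
            ramps = {
                cond: pet_mod.make_ramp_regressor(sim_cfg.n_frames_pet, [pet_blocks[cond]])
                for cond in ("easy", "hard")
            }
            design_glm = pet_mod.FpetDesign(
                baseline=baseline, ramps=ramps, motion=pet_mod.motion_pc1(motion)
            )
            fit = pet_mod.fit_fpet_glm(
                tacs, design_glm, frame_len_min=sim_cfg.frame_len_pet / 60.0
            )
            ki_base, _ = pet_mod.patlak_ki(fit["baseline_fit"], inp, config.t_star_min)
            maps = {"rest": pet_mod.cmrglu_from_ki(ki_base, sim_cfg.glu_plasma, config.lc)}
            for cond in ("easy", "hard"):
                window = np.zeros(sim_cfg.n_frames_pet, dtype=bool)
                window[slice(*pet_blocks[cond])] = True
                ki_cond = pet_mod.condition_ki(ki_base, fit["betas"][cond], inp, window)
                maps[cond] = pet_mod.cmrglu_from_ki(ki_cond, sim_cfg.glu_plasma, config.lc)
            sdir = study_dir / f"sub-{subject:02d}" / time
            for cond, m in maps.items():
                write_image(m, sdir / f"cmrglu_{cond}.nii.gz")
                cmrglu_maps[(subject, time, cond)] = m
    manifest["stages"].append("quantify-pet")

    # ---- ASL quantification --------------------------------------------
    cbf_results: dict = {}
    have_asl = True
    for subject in subjects:
        for time in TIMES:
            sdir = study_dir / f"sub-{subject:02d}" / time
            paths = {c: sdir / f"asl_{c}.nii.gz" for c in CONDITIONS}
            if not all(p.exists() for p in paths.values()):
                have_asl = False
                break
            series = {c: read_image(paths[c]) for c in CONDITIONS}
            cbf = asl_mod.condition_cbf(series["rest"], series["easy"], series["hard"])
            write_image(cbf.rest, sdir / "cbf_rest.nii.gz")
            write_image(cbf.task_delta_easy, sdir / "cbf_delta_easy.nii.gz")
            write_image(cbf.task_delta_hard, sdir / "cbf_delta_hard.nii.gz")
            cbf_results[(subject, time)] = cbf
    if not have_asl and config.require_asl:
        raise FileNotFoundError("ASL inputs missing; set require_asl: false to proceed")
    manifest["stages"].append("quantify-asl" if have_asl else "quantify-asl (skipped)")

    # ---- BOLD cleaning and block GLM -----------------------------------
    cleaned: dict = {}
    bold_t_hard: dict = {}
    task_blocks = bold_task_blocks(sim_cfg.n_frames_bold)
    for subject in subjects:
        for time in TIMES:
            sdir = study_dir / f"sub-{subject:02d}" / time
            for cond in CONDITIONS:
                data = read_image(sdir / f"bold_{cond}.nii.gz").data
                motion = read_table(sdir / f"motion_{cond}.tsv").to_numpy()
                sr = bold_mod.scrub_motion(motion, config.fd_threshold_mm)
                flat = data.reshape(-1, data.shape[-1])
                nuis_pool = (masks["brain"] & ~masks["gm"]).reshape(-1)
                nuisance = np.column_stack(
                    [motion, flat[nuis_pool].mean(axis=0)[:, None]]
                )
                clean = bold_mod.clean_timeseries(
                    flat, sr.kept, nuisance, tr=sim_cfg.tr_bold, band=config.band_hz
                )
                cleaned[(subject, time, cond)] = clean.reshape(*data.shape[:3], -1)
                if cond == "hard" and time == "M1":
                    reg = bold_mod.block_regressor(
                        sim_cfg.n_frames_bold, task_blocks, sim_cfg.tr_bold
                    )
                    glm = bold_mod.block_glm(
                        flat, reg[:, None], {"task": np.array([1.0])}
                    )
                    bold_t_hard[subject] = glm["task"].reshape(data.shape[:3])
    manifest["stages"].append("bold-clean+glm")

    # ---- multimodal conjunction ----------------------------------------
    stat_maps = {
        "cmrglu": np.stack(
            [cmrglu_maps[(s, "M1", "hard")] - cmrglu_maps[(s, "M1", "rest")] for s in subjects]
        ),
        "bold": np.stack([bold_t_hard[s] for s in subjects]),
    }
    if have_asl:
        stat_maps["cbf"] = np.stack(
            [cbf_results[(s, "M1")].task_delta_hard for s in subjects]
        )
    else:
        manifest["notes"].append("conjunction from CMRGlu+BOLD only (no ASL)")
    t_crit = float(sps.t.isf(config.activation_p, len(subjects) - 1))
    modality_masks = {
        name: conj_mod.binarize(_one_sample_t(m), t_crit) for name, m in stat_maps.items()
    }
    inter = conj_mod.intersect(list(modality_masks.values()))
    _, target_region = conj_mod.cluster_filter(
        inter, config.min_cluster_cm3, config.voxel_volume_cm3
    )
    if not target_region.any():
        manifest["notes"].append("conjunction empty after cluster filter; using raw intersection")
        target_region = inter
    dices = {
        f"{a}_vs_{b}": conj_mod.dice(modality_masks[a], modality_masks[b])
        for a in modality_masks for b in modality_masks if a < b
    }
    write_image(target_region.astype(float), out / "target_region.nii.gz")
    manifest["stages"].append("conjunction")

    # ---- MCM maps -------------------------------------------------------
    mcm_maps: dict = {}
    for subject in subjects:
        for time in TIMES:
            for cond in CONDITIONS:
                m = mcm_mod.mcm_map(
                    cleaned[(subject, time, cond)],
                    target_region,
                    cmrglu_maps[(subject, time, cond)],
                    masks["brain"],
                )
                mcm_maps[(subject, time, cond)] = m.values
                sdir = study_dir / f"sub-{subject:02d}" / time
                write_image(m.values, sdir / f"mcm_{cond}.nii.gz")
    manifest["stages"].append("mcm")

    # ---- statistics -----------------------------------------------------
    diff_rest = np.stack(
        [mcm_maps[(s, "M2", "rest")] - mcm_maps[(s, "M1", "rest")] for s in subjects]
    )
    perm = stats_mod.cluster_permutation(
        diff_rest, groups, n_perm=config.n_perm,
        cluster_forming_p=config.cluster_forming_p, seed=config.seed,
    )
    if perm.labels.max() > 0:
        sizes = [(perm.labels == k).sum() for k in range(1, perm.labels.max() + 1)]
        cluster = perm.labels == (int(np.argmax(sizes)) + 1)
    else:
        manifest["notes"].append("no FWE-significant cluster; using largest suprathreshold")
        lab, n = ndimage.label(
            np.abs(perm.t_map) > perm.t_threshold, structure=np.ones((3, 3, 3), bool)
        )
        if n == 0:
            raise RuntimeError("stats stage: no suprathreshold voxels in the rest contrast")
        sizes = np.bincount(lab.ravel())[1:]
        cluster = lab == (int(np.argmax(sizes)) + 1)
    write_image(cluster.astype(float), out / "cluster.nii.gz")

    values = np.empty((len(subjects), len(TIMES), len(CONDITIONS)))
    for i, s in enumerate(subjects):
        for t_idx, time in enumerate(TIMES):
            for c_idx, cond in enumerate(CONDITIONS):
                values[i, t_idx, c_idx] = mcm_maps[(s, time, cond)][cluster].mean()
    anova = stats_mod.rm_anova_gtc(values, groups)
    posthocs = {c: stats_mod.posthoc(values, groups, i) for i, c in enumerate(CONDITIONS)}
    ph_p = stats_mod.holm([posthocs[c]["interaction"].p for c in CONDITIONS])
    stats_rows = [
        {"effect": r.effect, "F": r.F, "df1": r.df1, "df2": r.df2, "p": r.p}
        for r in anova.values()
    ]
    for (c, ph), p_adj in zip(posthocs.items(), ph_p):
        stats_rows.append(
            {
                "effect": f"group_x_time[{c}]",
                "F": ph["interaction"].F,
                "df1": ph["interaction"].df1,
                "df2": ph["interaction"].df2,
                "p": float(p_adj),
            }
        )
    write_table(pd.DataFrame(stats_rows), out / "stats.tsv")
    manifest["stages"].append("stats")

    # ---- perturbation ---------------------------------------------------
    n_tgt = int(target_region.sum())
    z_patterns = {}
    cmrglu_patterns = {}
    for i, s in enumerate(subjects):
        for cond in CONDITIONS:
            cmrglu_patterns[(i, cond)] = cmrglu_maps[(s, "M1", cond)][target_region]
        for time in TIMES:
            for cond in CONDITIONS:
                data = cleaned[(s, time, cond)]
                src_ts = data[cluster & ~target_region].T
                tgt_ts = data[target_region].T
                z_patterns[(i, time, cond)] = mcm_mod.fisher_z(
                    mcm_mod.temporal_corr(src_ts, tgt_ts)
                )
    bundle = type(
        "StudyBundle", (), {
            "groups": groups, "z_patterns": z_patterns, "cmrglu_patterns": cmrglu_patterns
        },
    )()
    curves = []
    max_frac = 1.0 - 4.0 / n_tgt
    fractions = np.round(np.arange(0.0, 1.0, 0.1), 10)
    fractions = fractions[fractions <= max_frac]
    for driver in perturb_mod.DRIVERS:
        for cond in ("rest", "hard"):
            pc = perturb_mod.perturbation_curve(
                bundle, driver, cond, fractions=fractions,
                n_random=config.n_random, seed=config.seed,
            )
            for frac, f, p in zip(pc.fractions, pc.f_values, pc.p_values):
                curves.append(
                    {"driver": driver, "condition": cond, "fraction": frac, "F": f, "p": p}
                )
    write_table(pd.DataFrame(curves), out / "perturbation.tsv")
    manifest["stages"].append("perturb")

    # ---- manifest -------------------------------------------------------
    outputs = sorted(
        str(p.relative_to(out)) for p in out.rglob("*")
        if p.is_file() and p.suffix in (".gz", ".tsv", ".json") and p.name != "manifest.json"
    )
    manifest["hashes"] = {name: _sha256(out / name) for name in outputs}
    import mcmflow

    manifest["version"] = mcmflow.__version__
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "manifest": manifest,
        "anova": anova,
        "posthoc": posthocs,
        "dice": dices,
        "cluster_voxels": int(cluster.sum()),
        "target_voxels": n_tgt,
        "values": values,
        "out_dir": str(out),
    }
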