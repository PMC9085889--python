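import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from mcmflow.asl import condition_cbf
from mcmflow.bold import scrub_motion
from mcmflow.pet import assemble_input_function, patlak_ki
from mcmflow.stats import behavior_summary, posthoc_interaction_f
from mcmflow.synthetic import (
    SyntheticConfig,
    coupling_profile,
    default_coupling,
    generate_asl_series,
    generate_behavior,
    generate_bold_cell,
    generate_fpet_tacs,
    generate_motion,
    generate_study,
    make_ground_truth,
    simulate_mcm_study,
)


def small(**kw):
    base = dict(
        grid_shape=(12, 12, 6),
        n_frames_bold=80,
        n_frames_pet=60,
        n_asl_pairs=6,
        n_subjects_training=3,
        n_subjects_control=3,
        seed=7,
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestConfig:
    def test_counts_validated(self):
        with pytest.raises(ValueError):
            small(n_frames_bold=0)

    def test_coupling_range_validated(self, null_coupling):
        null_coupling[("training", "M2", "rest")] = 1.2
        with pytest.raises(ValueError):
            small(coupling=null_coupling)

    def test_defaults_match_study_shape(self):
        cfg = SyntheticConfig()
        assert cfg.n_subjects_training == 21 and cfg.n_subjects_control == 20
        assert cfg.frame_len_pet == 30.0
        assert cfg.fold_change_easy == 2.7 and cfg.fold_change_hard == 3.1


class TestDeterminism:
    def test_in_memory_study_bit_identical(self):
        cfg = small()
        a = simulate_mcm_study(cfg)
        b = simulate_mcm_study(dataclasses.replace(cfg))
        np.testing.assert_array_equal(a.mcm_values, b.mcm_values)
        pd.testing.assert_frame_equal(a.behavior, b.behavior)

    def test_written_study_checksums_identical(self, tmp_path):
        cfg = small(
            grid_shape=(8, 8, 4), n_subjects_training=1, n_subjects_control=1,
            n_frames_bold=40, n_frames_pet=30, n_asl_pairs=3,
        )
        sums = []
        for sub in ("a", "b"):
            out = tmp_path / sub
            generate_study(cfg, out)
            digest = {}
            for p in sorted(out.rglob("*")):
                if p.is_file():
                    digest[str(p.relative_to(out))] = hashlib.sha256(
                        p.read_bytes()
                    ).hexdigest()
            sums.append(digest)
        assert sums[0] == sums[1]


class TestCouplingConstruction:
    def test_zero_coupling_gives_zero_mean_mcm(self, null_coupling):
        cfg = small(coupling={k: 0.0 for k in null_coupling}, seed=3)
        study = simulate_mcm_study(cfg)
        se = study.mcm_values.std() / np.sqrt(study.mcm_values.size)
        assert abs(study.mcm_values.mean()) < 3 * se + 1e-3

    def test_high_coupling_low_noise_correlation_near_one(self, null_coupling):
        # noise-free limit: aligned weights, no CMRGlu noise, long series
        cfg = small(
            coupling={k: 0.9 for k in null_coupling},
            pattern_mismatch=0.0,
            cmrglu_noise_sd=0.0,
            n_frames_bold=600,
            grid_shape=(16, 16, 8),
        )
        gt = make_ground_truth(cfg)
        tgt, src = generate_bold_cell(cfg, gt, 0, "M1", "rest", source_noise=0.05)
        from mcmflow.mcm import fisher_z, temporal_corr

        z = fisher_z(temporal_corr(src, tgt)).mean(axis=0)
        c = gt.cmrglu_true[gt.masks["target"]]
        assert np.corrcoef(z, c)[0, 1] > 0.95

    def test_mcm_rises_monotonically_with_coupling(self, null_coupling):
        means = []
        for rho in (0.2, 0.5, 0.8):
            coup = dict(null_coupling)
            coup[("training", "M2", "rest")] = rho
            cfg = small(coupling=coup, n_subjects_training=6, n_subjects_control=2,
                        n_frames_bold=200, grid_shape=(16, 16, 8), seed=5)
            st = simulate_mcm_study(cfg)
            means.append(st.mcm_values[st.groups == "training", 1, 0].mean())
        assert means[0] < means[1] < means[2]

    def test_scaling_coupling_difference_increases_rest_f(self, null_coupling):
        f_vals = []
        for rho in (0.5, 0.65, 0.8):
            coup = dict(null_coupling)
            coup[("training", "M2", "rest")] = rho
            cfg = small(coupling=coup, n_subjects_training=8, n_subjects_control=8,
                        n_frames_bold=200, grid_shape=(16, 16, 8), seed=11)
            st = simulate_mcm_study(cfg)
            d = st.mcm_values[:, 1, 0] - st.mcm_values[:, 0, 0]
            f_vals.append(posthoc_interaction_f(d, st.groups).F)
        assert f_vals[0] < f_vals[1] < f_vals[2]

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            make_ground_truth(small(grid_shape=(2, 2, 1)))


class TestFpet:
    def test_zero_kinetics_give_zero_tac(self):
        cfg = small(pet_noise_sd=0.0)
        gt = make_ground_truth(cfg)
        gt.ki_true[:] = 0.0
        img, _ = generate_fpet_tacs(cfg, gt, v0=0.0, task_amp_easy=0, task_amp_hard=0)
        np.testing.assert_allclose(img.data, 0.0, atol=1e-12)

    def test_noise_free_patlak_recovers_ki(self):
        cfg = small(pet_noise_sd=0.0)
        gt = make_ground_truth(cfg)
        gt.ki_true[:] = 0.02
        img, blood = generate_fpet_tacs(cfg, gt, v0=0.05, task_amp_easy=0, task_amp_hard=0)
        inp = assemble_input_function(blood, cfg.pet_frame_times_min())
        ki, _ = patlak_ki(img.data[0, 0, 0], inp, t_star_min=10)
        assert ki == pytest.approx(0.02, rel=0.01)

    def test_exactly_seven_arterial_samples(self):
        cfg = small()
        _, blood = generate_fpet_tacs(cfg, make_ground_truth(cfg))
        assert len(blood) == 7
        np.testing.assert_allclose(blood["time_min"], [3, 4, 5, 14, 25, 36, 47])


class TestAsl:
    def test_noise_free_round_trip_recovers_cbf(self):
        cfg = small(asl_noise_sd=0.0, cbf_rest=60.0)
        gt = make_ground_truth(cfg)
        img = generate_asl_series(cfg, gt, "rest")
        maps = condition_cbf(img, img, img, intensity_factor=None)
        np.testing.assert_allclose(maps.rest, 60.0, rtol=1e-10)

    def test_task_delta_recovered_in_target(self):
        cfg = small(asl_noise_sd=0.0)
        gt = make_ground_truth(cfg)
        maps = condition_cbf(
            generate_asl_series(cfg, gt, "rest"),
            generate_asl_series(cfg, gt, "easy"),
            generate_asl_series(cfg, gt, "hard"),
            intensity_factor=None,
        )
        tgt = gt.masks["target"]
        np.testing.assert_allclose(
            maps.task_delta_hard[tgt], cfg.cbf_task_hard - cfg.cbf_rest, rtol=1e-10
        )
        np.testing.assert_allclose(maps.task_delta_hard[~tgt], 0.0, atol=1e-8)

    def test_equal_label_control_counts(self):
        cfg = small()
        img = generate_asl_series(cfg, make_ground_truth(cfg), "rest")
        assert img.data.shape[-1] == 2 * cfg.n_asl_pairs

    def test_zero_cbf_label_equals_control(self):
        cfg = small(asl_noise_sd=0.0, cbf_rest=0.0)
        gt = make_ground_truth(cfg)
        gt.cbf_true["rest"] = 0.0
        img = generate_asl_series(cfg, gt, "rest")
        np.testing.assert_allclose(img.data[..., ::2], img.data[..., 1::2])

    def test_negative_cbf_rejected(self):
        cfg = small()
        gt = make_ground_truth(cfg)
        gt.cbf_true["rest"] = -1.0
        with pytest.raises(ValueError):
            generate_asl_series(cfg, gt, "rest")


class TestMotion:
    def test_spikes_exceed_scrub_threshold(self):
        cfg = small()
        trace, spikes = generate_motion(cfg)
        res = scrub_motion(trace)
        assert len(spikes) == cfg.n_motion_spikes
        for k in spikes:
            assert res.fd[k] > 0.5
            assert not res.kept[max(k - 1, 0): k + 3].any()

    def test_seed_fixed_reproducible(self):
        cfg = small()
        t1, s1 = generate_motion(cfg)
        t2, s2 = generate_motion(cfg)
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_array_equal(s1, s2)


class TestBehavior:
    def test_fold_changes_recovered_at_large_n(self):
        cfg = small(
            n_subjects_training=400, n_subjects_control=10,
            behavior_noise_sd=0.01, behavior_ability_noise_sd=0.01,
        )
        table = generate_behavior(cfg, make_ground_truth(cfg))
        folds = behavior_summary(table)["fold_changes"]["training"]
        assert folds["hard"]["ratio_of_means"] == pytest.approx(3.1, rel=0.05)
        assert folds["easy"]["ratio_of_means"] == pytest.approx(2.7, rel=0.05)

    def test_unit_fold_has_no_group_by_time_interaction_excess(self):
        rejections = 0
        n_runs = 40
        for seed in range(n_runs):
            cfg = small(fold_change_easy=1.0, fold_change_hard=1.0, seed=seed,
                        n_subjects_training=8, n_subjects_control=8)
            table = generate_behavior(cfg, make_ground_truth(cfg))
            scans = table[(table.kind == "scan") & (table.condition == "hard")]
            piv = scans.pivot_table(index=["subject", "group"], columns="time",
                                    values="score_per_min")
            d = (piv["M2"] - piv["M1"]).to_numpy()
            groups = piv.index.get_level_values("group").to_numpy()
            if posthoc_interaction_f(d, groups).p < 0.05:
                rejections += 1
        assert rejections <= 7  # ~binomial(40, 0.05) upper tail

    def test_control_group_flat_in_expectation(self):
        cfg = small(n_subjects_control=300, n_subjects_training=5,
                    behavior_ability_noise_sd=0.01)
        table = generate_behavior(cfg, make_ground_truth(cfg))
        folds = behavior_summary(table)["fold_changes"]["control"]
        assert folds["hard"]["ratio_of_means"] == pytest.approx(1.0, abs=0.05)


class TestStudyFiles:
    def test_generate_study_emits_all_declared_outputs(self, tmp_path):
        cfg = small(grid_shape=(8, 8, 4), n_subjects_training=1, n_subjects_control=1,
                    n_frames_bold=40, n_frames_pet=30, n_asl_pairs=3)
        design, gt = generate_study(cfg, tmp_path)
        assert (tmp_path / "design.tsv").exists()
        assert (tmp_path / "behavior.tsv").exists()
        assert (tmp_path / "ground_truth.json").exists()
        for _, row in design.iterrows():
            for col in ("bold", "fpet", "asl", "blood", "motion"):
                assert (tmp_path / row[col]).exists()

    def test_coupling_true_respects_config(self):
        cfg = small(coupling_subject_sd=0.0)
        gt = make_ground_truth(cfg)
        groups = cfg.subject_groups()
        for (i, time, cond), rho in gt.coupling_true.items():
            assert rho == pytest.approx(cfg.coupling[(groups[i], time, cond)])

    def test_cmrglu_follows_conversion_identity(self):
        cfg = small()
        gt = make_ground_truth(cfg)
        np.testing.assert_allclose(
            gt.cmrglu_true, gt.ki_true * cfg.glu_plasma / cfg.lc * 100.0, rtol=1e-12
        )

    def test_coupling_profile_matches_base_construction_at_m1(self):
        cfg = small(coupling_subject_sd=0.0)
        gt = make_ground_truth(cfg)
        a = coupling_profile(cfg, gt, 0, "M1", "rest")
        np.testing.assert_allclose(a, 0.5 * gt.weights_true, atol=1e-12)
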