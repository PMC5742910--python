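"""Synthetic map generator: determinism, class exactness, calibration, cohorts."""

import dataclasses

import numpy as np
import pytest

import benmap as bm
from benmap.synthetic import CONTROL_RECRUITED, _MAX_SEED

SMALL = bm.MapGenConfig(image_size=(64, 64), seed=5)
#: Single-retained-class config: grey tissue only, no activation, no noise.
FLAT = bm.MapGenConfig(image_size=(64, 64), activation_fraction=0.0,
                       artifact_fraction=0.0, white_matter_fraction=0.0,
                       intensity_heterogeneity=0.0, seed=5)


class TestMapGenConfig:
    @pytest.mark.parametrize("kw", [
        {"activation_fraction": -0.1},
        {"activation_fraction": 0.6, "artifact_fraction": 0.5},
        {"artifact_fraction": 1.2},
        {"image_size": (0, 10)},
        {"intensity_heterogeneity": -1.0},
        {"noise_cap_fraction": 0.5},
        {"blob_scale": 0.0},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(bm.ConfigurationError):
            bm.MapGenConfig(**kw)


class TestGenerateComponentMap:
    def test_seeded_determinism(self):
        cfg = dataclasses.replace(SMALL, seed=42)
        a = bm.generate_component_map(cfg)
        b = bm.generate_component_map(cfg)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        np.testing.assert_array_equal(a.true_labels, b.true_labels)
        c = bm.generate_component_map(dataclasses.replace(cfg, seed=43))
        assert not np.array_equal(a.pixels, c.pixels)

    def test_no_activation_config_has_no_blue_or_red(self):
        cfg = dataclasses.replace(SMALL, activation_fraction=0.0,
                                  artifact_fraction=0.0)
        img = bm.generate_component_map(cfg)
        seg = bm.segment_colors(img)
        assert seg.class_counts["blue"] == 0
        assert seg.class_counts["red"] == 0
        assert seg.class_counts["grey"] > 0

    def test_zero_heterogeneity_single_class_gives_zero_ben(self):
        img = bm.generate_component_map(FLAT)
        res = bm.image_ben(img)
        assert res.entropy_bits == 0.0 and res.ben == 0.0

    def test_fractions_are_exact_and_located(self):
        cfg = dataclasses.replace(SMALL, activation_fraction=0.1,
                                  artifact_fraction=0.03)
        img = bm.generate_component_map(cfg)
        lab = img.true_labels
        blue, red = bm.DEFAULT_PALETTE.index("blue"), bm.DEFAULT_PALETTE.index("red")
        n_brain = (lab != bm.DEFAULT_PALETTE.index("background")).sum()
        assert (lab == blue).sum() == round(0.1 * n_brain)
        assert (lab == red).sum() == round(0.03 * n_brain)
        h = lab.shape[0]
        rows_blue = np.nonzero((lab == blue).any(axis=1))[0]
        rows_red = np.nonzero((lab == red).any(axis=1))[0]
        assert rows_blue.min() >= 2 * h / 3          # occipital placement
        assert rows_red.max() < 2 * h / 3            # artifact elsewhere

    @pytest.mark.parametrize("d", [0.0, 5.0, 20.0, 60.0])
    def test_segmentation_recovers_ground_truth_under_noise(self, d):
        cfg = dataclasses.replace(SMALL, intensity_heterogeneity=d)
        img = bm.generate_component_map(cfg)
        seg = bm.segment_colors(img)
        np.testing.assert_array_equal(seg.labels, img.true_labels)

    def test_activation_fraction_too_large_for_region(self):
        with pytest.raises(bm.ConfigurationError, match="lower-third"):
            bm.generate_component_map(
                dataclasses.replace(SMALL, activation_fraction=0.9)
            )


class TestCalibration:
    def test_curve_is_monotone_and_spans_targets(self):
        grid, means = bm.heterogeneity_curve(SMALL)
        assert (np.diff(means) >= 0).all()
        assert means[0] < 0.56 < 0.64 < means[-1]

    def test_calibrated_dispersion_hits_target(self):
        d = bm.calibrate_heterogeneity(0.64, SMALL, tol=0.02)
        # independent Monte-Carlo check with fresh seeds
        rng = np.random.default_rng(999)
        bens = [
            bm.image_ben(bm.generate_component_map(dataclasses.replace(
                SMALL, intensity_heterogeneity=d,
                seed=int(rng.integers(0, _MAX_SEED))))).ben
            for _ in range(50)
        ]
        assert np.mean(bens) == pytest.approx(0.64, abs=0.02)

    def test_dispersion_ordering_follows_targets(self):
        d_lo = bm.calibrate_heterogeneity(0.56, SMALL)
        d_hi = bm.calibrate_heterogeneity(0.64, SMALL)
        assert 0 < d_lo < d_hi

    def test_zero_target_on_flat_config_returns_zero_dispersion(self):
        assert bm.calibrate_heterogeneity(0.0, FLAT) == 0.0

    def test_unreachable_target_names_achievable_range(self):
        with pytest.raises(bm.CalibrationError, match="achievable range"):
            bm.calibrate_heterogeneity(0.02, SMALL)


class TestCohortGeneration:
    def test_default_gender_by_group_table_is_exact(self, default_cohort):
        t = bm.ContingencyTable2x2.from_labels(
            default_cohort.table["group"], default_cohort.table["gender"]
        )
        assert (t.a, t.b, t.c, t.d) == (20, 5, 8, 11)

    def test_group_sizes_images_and_age_ranges(self, default_cohort):
        tab = default_cohort.table
        assert (tab["group"] == "ADHD").sum() == 25
        assert (tab["group"] == "control").sum() == 19
        assert all(len(v) == 2 for v in default_cohort.images.values())
        adhd = tab[tab["group"] == "ADHD"]
        ctrl = tab[tab["group"] == "control"]
        assert adhd["age"].between(20, 50).all()
        assert ctrl["age"].between(18, 46).all()

    def test_recruitment_counts_flag_follows_recruited_composition(self):
        cfg = bm.CohortGenConfig(seed=0, use_recruitment_counts=True)
        assert cfg.control == CONTROL_RECRUITED
        assert cfg.control.n == 20 and cfg.control.gender_counts == (8, 12)

    def test_seeded_determinism_of_subject_table(self):
        spec = dataclasses.replace(bm.synthetic.ADHD_DEFAULT, n=4,
                                   gender_counts=(3, 1))
        ctrl = dataclasses.replace(bm.synthetic.CONTROL_DEFAULT, n=4,
                                   gender_counts=(2, 2))
        cfg = bm.CohortGenConfig(adhd=spec, control=ctrl, seed=21)
        a = bm.generate_cohort(cfg, SMALL)
        b = bm.generate_cohort(cfg, SMALL)
        assert a.table.equals(b.table)
        for sid in a.images:
            for ia, ib in zip(a.images[sid], b.images[sid]):
                np.testing.assert_array_equal(ia.pixels, ib.pixels)

    def test_empty_cohort_then_downstream_raises_empty_group(self):
        spec = dataclasses.replace(bm.synthetic.ADHD_DEFAULT, n=0,
                                   gender_counts=(0, 0))
        ctrl = dataclasses.replace(bm.synthetic.CONTROL_DEFAULT, n=0,
                                   gender_counts=(0, 0))
        cohort = bm.generate_cohort(bm.CohortGenConfig(adhd=spec, control=ctrl),
                                    SMALL)
        assert cohort.table.empty
        with pytest.raises(ValueError, match="empty"):
            bm.BrainEntropyModel.from_cohort(cohort)

    def test_gender_counts_must_sum_to_n(self):
        with pytest.raises(bm.ConfigurationError, match="gender counts"):
            dataclasses.replace(bm.synthetic.ADHD_DEFAULT, gender_counts=(20, 4))

    def test_write_emits_pngs_and_csv(self, tmp_path):
        spec = dataclasses.replace(bm.synthetic.ADHD_DEFAULT, n=2,
                                   gender_counts=(1, 1))
        ctrl = dataclasses.replace(bm.synthetic.CONTROL_DEFAULT, n=2,
                                   gender_counts=(1, 1))
        cohort = bm.generate_cohort(bm.CohortGenConfig(adhd=spec, control=ctrl,
                                                       seed=3), SMALL)
        csv_path = cohort.write(tmp_path)
        assert csv_path.exists()
        header = csv_path.read_text().splitlines()[0]
        assert header == "subject_id,group,age,gender,image_1,image_2"
        assert len(list((tmp_path / "images").glob("*.png"))) == 8
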