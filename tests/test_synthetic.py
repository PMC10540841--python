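import numpy as np
import pytest

from nutriface.geometry import align, eye_centers, interocular_angle
from nutriface.synthetic import (
    CohortSpec,
    face_layout,
    generate_cohort,
    records_from_metadata,
    render_face,
    sample_subject,
)


class TestCohortSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_subjects": 1},
            {"n_subjects": 10, "prevalence": 0.0},
            {"n_subjects": 10, "prevalence": 1.0},
            {"n_subjects": 10, "elderly_fraction": 1.5},
            {"n_subjects": 10, "effect_size": -1.0},
            {"n_subjects": 10, "canvas_size": 64},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortSpec(**kwargs)


class TestDeterminism:
    def test_bit_identical_rendering(self):
        spec = CohortSpec(n_subjects=3, seed=42, canvas_size=128)
        p = sample_subject(spec, 1)
        img1, lm1, m1 = render_face(p, 128)
        img2, lm2, m2 = render_face(p, 128)
        assert np.array_equal(img1, img2)
        assert np.array_equal(lm1, lm2)
        assert np.array_equal(m1, m2)

    def test_subject_sampling_pure(self):
        spec = CohortSpec(n_subjects=5, seed=7)
        assert sample_subject(spec, 3) == sample_subject(spec, 3)
        assert sample_subject(spec, 3) != sample_subject(spec, 4)

    def test_seed_changes_cohort(self):
        a = CohortSpec(n_subjects=30, seed=1)
        b = CohortSpec(n_subjects=30, seed=2)
        la = [sample_subject(a, i).at_risk for i in range(30)]
        lb = [sample_subject(b, i).at_risk for i in range(30)]
        assert la != lb


class TestLabelStructure:
    def test_prevalence_converges(self):
        spec = CohortSpec(n_subjects=5000, seed=3)
        labels = np.array(
            [sample_subject(spec, i).at_risk for i in range(5000)]
        )
        p = spec.prevalence
        sd = np.sqrt(p * (1 - p) / 5000)
        assert abs(labels.mean() - p) < 3 * sd

    def test_score_label_consistency(self):
        spec = CohortSpec(n_subjects=200, seed=9)
        for i in range(200):
            s = sample_subject(spec, i)
            assert 0 <= s.nrs_score <= 5
            assert s.at_risk == (s.nrs_score >= 3)

    def test_attributes_independent_of_label(self):
        # generator draws demographics independently; quick sanity via chi2
        from nutriface.stats import yates_chi2

        spec = CohortSpec(n_subjects=2000, seed=13)
        subs = [sample_subject(spec, i) for i in range(2000)]
        at_risk = np.array([s.at_risk for s in subs])
        male = np.array([s.gender == "male" for s in subs])
        table = [
            [int((male & at_risk).sum()), int((male & ~at_risk).sum())],
            [int((~male & at_risk).sum()), int((~male & ~at_risk).sum())],
        ]
        _, p = yates_chi2(table)
        assert p > 0.001


class TestRenderGeometry:
    def test_no_jitter_eyes_horizontal(self):
        spec = CohortSpec(
            n_subjects=50,
            seed=3,
            jitter_rotation_deg=0.0,
            jitter_translation_px=0.0,
            canvas_size=256,
        )
        for i in range(10):
            _, lm, _ = render_face(sample_subject(spec, i), 256)
            left, right = eye_centers(lm)
            assert abs(left[1] - right[1]) < 0.5

    def test_rotation_jitter_sets_interocular_angle(self):
        from dataclasses import replace

        spec = CohortSpec(n_subjects=5, seed=21, canvas_size=256)
        p = replace(sample_subject(spec, 0), rotation_deg=10.0)
        _, lm, _ = render_face(p, 256)
        assert interocular_angle(*eye_centers(lm)) == pytest.approx(10.0, abs=0.5)

    def test_mask_between_eyes_and_mouth(self):
        spec = CohortSpec(
            n_subjects=5,
            seed=2,
            jitter_rotation_deg=0.0,
            jitter_translation_px=0.0,
            canvas_size=256,
        )
        layout = face_layout(256)
        for i in range(5):
            _, lm, mask = render_face(sample_subject(spec, i), 256)
            ys, xs = np.nonzero(mask == 255)
            assert len(ys) > 0
            eye_rows = lm[36:48, 1]
            mouth_rows = lm[48:68, 1]
            assert ys.min() > eye_rows.max() - 1e-9
            assert ys.max() < mouth_rows.min()
            # disjoint from the eye ellipse interiors
            for ec in (layout["eye_left"], layout["eye_right"]):
                r = layout["eye_radii"]
                inside = ((xs - ec[0]) / r[0]) ** 2 + ((ys - ec[1]) / r[1]) ** 2 <= 1
                assert not inside.any()

    def test_alignment_recovers_horizontal(self, small_cohort_rendered):
        _, rendered = small_cohort_rendered
        for _, img, lm, _ in rendered:
            _, lm2 = align(img, lm)
            left, right = eye_centers(lm2)
            assert abs(left[1] - right[1]) < 0.5

    def test_canvas_too_small_rejected(self):
        spec = CohortSpec(n_subjects=2, seed=0)
        with pytest.raises(ValueError):
            render_face(sample_subject(spec, 0), 100)


class TestAppearanceSignal:
    def test_zero_effect_classes_indistinguishable(self):
        """Permutation test on mean ROI intensity at effect 0 is null."""
        spec = CohortSpec(n_subjects=60, seed=7, effect_size=0.0, canvas_size=128)
        means, labels = [], []
        for i in range(60):
            p = sample_subject(spec, i)
            img, _, mask = render_face(p, 128)
            means.append(img[mask == 255].mean())
            labels.append(p.at_risk)
        means = np.array(means)
        labels = np.array(labels)
        assert labels.any() and not labels.all()
        obs = abs(means[labels].mean() - means[~labels].mean())
        rng = np.random.default_rng(0)
        null = []
        for _ in range(999):
            perm = rng.permutation(labels)
            null.append(abs(means[perm].mean() - means[~perm].mean()))
        p_value = (1 + sum(n >= obs for n in null)) / 1000
        assert p_value > 0.01

    def test_effect_two_separable_by_intensity_threshold(self):
        spec = CohortSpec(n_subjects=200, seed=17, effect_size=2.0, canvas_size=256)
        means, labels = [], []
        for i in range(200):
            p = sample_subject(spec, i)
            img, _, mask = render_face(p, 256)
            means.append(img[mask == 255].mean())
            labels.append(p.at_risk)
        means = np.array(means)
        labels = np.array(labels, dtype=bool)
        thresholds = np.unique(means)
        acc = max(
            max(((means >= t) == labels).mean(), ((means < t) == labels).mean())
            for t in thresholds
        )
        assert acc >= 0.8


class TestCohortFiles:
    def test_generate_cohort_round_trip(self, tmp_path):
        spec = CohortSpec(n_subjects=6, seed=5, canvas_size=128)
        records = generate_cohort(spec, tmp_path)
        assert len(records) == 6
        splits = {r.split for r in records}
        assert splits == {"train", "test"}
        loaded = records_from_metadata(tmp_path / "metadata.csv")
        assert [r.sample_id for r in loaded] == [r.sample_id for r in records]
        for rec, orig in zip(loaded, records):
            assert rec.image_path.exists()
            assert rec.mask_path.exists()
            assert np.allclose(rec.landmarks, orig.landmarks)

    def test_mask_file_binary(self, tmp_path):
        from nutriface.io import load_mask

        spec = CohortSpec(n_subjects=4, seed=5, canvas_size=128)
        records = generate_cohort(spec, tmp_path)
        mask = load_mask(records[0].mask_path)
        assert set(np.unique(mask)) <= {0, 255}
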