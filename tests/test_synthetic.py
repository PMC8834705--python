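import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from motionseq.dtw import DTWConfig, motion_distance
from motionseq.motion_io import motion_to_quaternions, read_bvh
from motionseq.synthetic import (
    DEFAULT_DURATIONS,
    GeneratorConfig,
    _draw_duration,
    _rng_for,
    generate_cohort,
    load_cohort,
    make_student_motion,
    make_teacher_template,
)

BAND = DTWConfig(window_fraction=0.2)


def zero_perturb_config(**kw):
    scales = {g: (0.0, 0.0, 0.0) for g in ("teacher", "good", "pass", "fail")}
    return GeneratorConfig(perturb_scales=scales, **kw)


class TestTeacherTemplate:
    def test_deterministic_per_seed_and_class(self):
        cfg = GeneratorConfig(seed=5, frame_rate=15.0)
        a = make_teacher_template(3, cfg)
        b = make_teacher_template(3, cfg)
        np.testing.assert_array_equal(a.motion.euler, b.motion.euler)
        assert a.motion.n_frames == b.motion.n_frames

    def test_distinct_classes_are_separated(self):
        cfg = GeneratorConfig(seed=5, frame_rate=15.0)
        q1 = motion_to_quaternions(make_teacher_template(1, cfg).motion)
        q2 = motion_to_quaternions(make_teacher_template(2, cfg).motion)
        assert motion_distance(q1, q2, BAND).overall > 0.0

    def test_class_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            make_teacher_template(9, GeneratorConfig())

    def test_class8_duration_distribution(self):
        # sample mean of 200 duration draws within 3 standard errors of
        # the configured 2.94 s mean for the shortest motion
        cfg = GeneratorConfig(seed=11)
        rng = _rng_for(cfg, 8, 99)
        draws = np.array([_draw_duration(cfg, 8, rng) for _ in range(200)])
        mean, sd = DEFAULT_DURATIONS[8]
        assert abs(draws.mean() - mean) < 3 * sd / np.sqrt(200)


class TestStudentMotion:
    def test_zero_perturbation_is_time_resampled_teacher(self):
        cfg = zero_perturb_config(seed=3, frame_rate=60.0)
        template = make_teacher_template(8, cfg)
        student = make_student_motion(template, "pass", cfg, _rng_for(cfg, 8, 50))
        d = motion_distance(
            motion_to_quaternions(student.motion),
            motion_to_quaternions(template.motion),
            BAND,
        )
        assert d.overall < 0.02  # only linear-resampling residue remains

    def test_zero_warp_frame_count_follows_duration(self):
        cfg = zero_perturb_config(seed=3, frame_rate=15.0)
        template = make_teacher_template(2, cfg)
        # twin rng streams: replicate the internal duration draw exactly
        duration = _draw_duration(cfg, 2, _rng_for(cfg, 2, 51))
        student = make_student_motion(template, "good", cfg, _rng_for(cfg, 2, 51))
        assert student.motion.n_frames == max(int(round(duration * 15.0)), 4)
        assert student.motion.frame_time == pytest.approx(1.0 / 15.0)

    def test_fail_grade_is_farther_than_good_grade(self):
        # Monte-Carlo over 50 draws per grade: fail distances dominate
        cfg = GeneratorConfig(seed=9, frame_rate=15.0)
        template = make_teacher_template(8, cfg)
        tq = motion_to_quaternions(template.motion)

        def distances(grade, offset):
            out = []
            for i in range(50):
                s = make_student_motion(template, grade, cfg, _rng_for(cfg, 8, offset, i))
                out.append(motion_distance(motion_to_quaternions(s.motion), tq, BAND).overall)
            return np.array(out)

        d_good = distances("good", 100)
        d_pass = distances("pass", 200)
        d_fail = distances("fail", 300)
        assert d_fail.mean() > d_pass.mean() > d_good.mean()
        assert mannwhitneyu(d_fail, d_pass, alternative="greater").pvalue < 0.01
        assert mannwhitneyu(d_pass, d_good, alternative="greater").pvalue < 0.01

    def test_unknown_grade_rejected(self):
        cfg = GeneratorConfig(seed=1)
        template = make_teacher_template(1, cfg)
        with pytest.raises(ValueError, match="grade"):
            make_student_motion(template, "excellent", cfg, _rng_for(cfg, 1, 0))

    def test_student_template_must_be_teacher(self):
        cfg = GeneratorConfig(seed=1, frame_rate=15.0)
        template = make_teacher_template(1, cfg)
        student = make_student_motion(template, "good", cfg, _rng_for(cfg, 1, 1))
        with pytest.raises(ValueError, match="teacher"):
            make_student_motion(student, "good", cfg, _rng_for(cfg, 1, 2))


class TestGeneratorConfig:
    def test_grade_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="grade mix"):
            GeneratorConfig(grade_mix={1: (0.5, 0.2, 0.2)})

    def test_perturbation_ordering_enforced(self):
        scales = dict(GeneratorConfig().perturb_scales)
        scales["fail"] = (0.1, 0.1, 0.01)  # weaker than pass
        with pytest.raises(ValueError, match="increase"):
            GeneratorConfig(perturb_scales=scales)

    def test_warp_strength_bounded(self):
        scales = dict(GeneratorConfig().perturb_scales)
        scales["fail"] = (20.0, 30.0, 1.0)
        with pytest.raises(ValueError, match="warp"):
            GeneratorConfig(perturb_scales=scales)


class TestCohort:
    def test_study_size_cohort_layout(self, study_cohort):
        assert len(study_cohort) == 784  # (3 teachers + 95 students) x 8
        teachers = [m for m in study_cohort if m.role == "teacher"]
        assert len(teachers) == 24
        for class_id in range(1, 9):
            members = [m for m in study_cohort if m.class_id == class_id]
            assert len(members) == 98

    def test_grade_counts_follow_mix(self, study_cohort):
        # class 8 has no fail grades; class 1 splits 16/57/22
        c8 = [m.grade for m in study_cohort if m.class_id == 8 and m.role == "student"]
        assert c8.count("fail") == 0 and c8.count("good") == 61
        c1 = [m.grade for m in study_cohort if m.class_id == 1 and m.role == "student"]
        assert (c1.count("good"), c1.count("pass"), c1.count("fail")) == (16, 57, 22)

    def test_degenerate_grade_mix_all_pass(self):
        cfg = GeneratorConfig(
            seed=2,
            frame_rate=15.0,
            n_students=4,
            grade_mix={c: (0.0, 1.0, 0.0) for c in range(1, 9)},
        )
        cohort = generate_cohort(cfg)
        grades = {m.grade for m in cohort if m.role == "student"}
        assert grades == {"pass"}

    def test_same_seed_byte_identical_label_files(self, tmp_path):
        cfg = GeneratorConfig(seed=4, frame_rate=15.0, n_students=2,
                              duration_mean_sd={8: DEFAULT_DURATIONS[8]},
                              grade_mix={8: DEFAULT_GRADE_MIX_8()},)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_cohort(cfg, out_dir=d1)
        generate_cohort(cfg, out_dir=d2)
        assert (d1 / "labels.tsv").read_bytes() == (d2 / "labels.tsv").read_bytes()

    def test_written_files_parse_and_validate(self, tmp_path):
        cfg = GeneratorConfig(seed=4, frame_rate=15.0, n_students=2,
                              duration_mean_sd={8: DEFAULT_DURATIONS[8]},
                              grade_mix={8: DEFAULT_GRADE_MIX_8()},)
        out = tmp_path / "cohort"
        cohort = generate_cohort(cfg, out_dir=out)
        reloaded = load_cohort(out)
        assert len(reloaded) == len(cohort)
        for orig, back in zip(cohort, reloaded):
            m = back.motion
            assert m.n_frames >= 1 and np.isfinite(m.euler).all()
            np.testing.assert_allclose(m.euler, orig.motion.euler, atol=1e-6)
            assert back.grade == orig.grade and back.role == orig.role

    def test_unperturbed_students_classified_by_nearest_template(self):
        cfg = zero_perturb_config(seed=6, frame_rate=15.0, n_students=3)
        cohort = generate_cohort(cfg)
        templates = {
            m.class_id: motion_to_quaternions(m.motion)
            for m in cohort
            if m.role == "teacher" and m.subject_id.endswith("_r1")
        }
        students = [m for m in cohort if m.role == "student"]
        for s in students:
            q = motion_to_quaternions(s.motion)
            dists = {c: motion_distance(q, t, BAND).overall for c, t in templates.items()}
            assert min(dists, key=dists.get) == s.class_id


def DEFAULT_GRADE_MIX_8():
    from motionseq.synthetic import DEFAULT_GRADE_MIX

    return DEFAULT_GRADE_MIX[8]
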