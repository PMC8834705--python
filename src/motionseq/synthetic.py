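"""Synthetic motion-cohort generator.

Emulates the study layout this package targets: 8 exercise motion classes
(each a fixed choreography), a teacher who performs every class 3 times,
and a body of students whose performances are graded good / pass / fail.
Real recordings of this kind are rarely shareable (whole-body motion data
identifies its subject), so the generator provides a labelled stand-in
with the same statistical shape:

* per-class durations drawn from the class's duration distribution
  (defaults: the published per-motion means and SDs, e.g. motion 8 is a
  short 2.94 +/- 1.01 s movement while motion 2 runs 21.72 +/- 4.01 s);
* grade frequencies matching the published per-motion grade marginals
  (motion 8 has no fails: it is the easy one);
* grades defined *by construction*: a student motion is the teacher
  template warped in time, corrupted with smooth amplitude noise, and
  offset on a random joint subset, with strictly increasing perturbation
  magnitudes from good to pass to fail.

Each joint channel of a class template is a smooth sum of 1-3 sinusoids
with class-specific random amplitudes, frequencies and phases; distinct
classes are therefore well separated in pose space.  All randomness flows
from a single seed through per-(class, subject) substreams, so a cohort is
reproducible and stable under partial regeneration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .motion_io import MotionSequence, SkeletonModel, read_bvh, write_bvh

__all__ = [
    "GeneratorConfig",
    "LabelledMotion",
    "default_skeleton",
    "make_teacher_template",
    "make_student_motion",
    "generate_cohort",
    "load_cohort",
    "DEFAULT_DURATIONS",
    "DEFAULT_GRADE_MIX",
    "DEFAULT_PERTURB_SCALES",
]

GRADES = ("good", "pass", "fail")

# per-class (mean, sd) duration in seconds
DEFAULT_DURATIONS: dict[int, tuple[float, float]] = {
    1: (12.13, 2.80),
    2: (21.72, 4.01),
    3: (16.58, 3.78),
    4: (15.09, 3.94),
    5: (19.43, 4.67),
    6: (16.40, 3.86),
    7: (13.17, 3.50),
    8: (2.94, 1.01),
}

# per-class (good, pass, fail) proportions of student grades
_GRADE_COUNTS = {
    1: (16, 57, 22),
    2: (21, 53, 21),
    3: (26, 58, 11),
    4: (22, 58, 15),
    5: (20, 57, 18),
    6: (23, 55, 17),
    7: (29, 59, 7),
    8: (61, 34, 0),
}
DEFAULT_GRADE_MIX: dict[int, tuple[float, float, float]] = {
    c: tuple(v / 95.0 for v in counts) for c, counts in _GRADE_COUNTS.items()
}

# per-grade (amplitude-noise SD deg, systematic joint offset deg, warp strength)
# Good performances deviate by a degree or two; failing ones show the
# ~10-15 degree joint-angle errors and strong timing drift typical of
# novices.  Teacher repetitions carry only trace variability.
DEFAULT_PERTURB_SCALES: dict[str, tuple[float, float, float]] = {
    "teacher": (0.8, 0.0, 0.03),
    "good": (1.5, 2.0, 0.05),
    "pass": (4.0, 6.0, 0.15),
    "fail": (10.0, 15.0, 0.35),
}

_JOINTS = [
    ("Hips", -1, (0.0, 95.0, 0.0)),
    ("Spine", 0, (0.0, 12.0, 0.0)),
    ("Chest", 1, (0.0, 14.0, 0.0)),
    ("Neck", 2, (0.0, 12.0, 0.0)),
    ("Head", 3, (0.0, 10.0, 0.0)),
    ("LeftUpperArm", 2, (18.0, 8.0, 0.0)),
    ("LeftForearm", 5, (28.0, 0.0, 0.0)),
    ("LeftHand", 6, (25.0, 0.0, 0.0)),
    ("RightUpperArm", 2, (-18.0, 8.0, 0.0)),
    ("RightForearm", 8, (-28.0, 0.0, 0.0)),
    ("RightHand", 9, (-25.0, 0.0, 0.0)),
    ("LeftThigh", 0, (9.0, -5.0, 0.0)),
    ("LeftShin", 11, (0.0, -42.0, 0.0)),
    ("LeftFoot", 12, (0.0, -40.0, 0.0)),
    ("RightThigh", 0, (-9.0, -5.0, 0.0)),
    ("RightShin", 14, (0.0, -42.0, 0.0)),
    ("RightFoot", 15, (0.0, -40.0, 0.0)),
]


def default_skeleton() -> SkeletonModel:
    """The fixed 17-joint tree (offsets in cm) used for synthetic cohorts."""
    return SkeletonModel(
        joint_names=[j[0] for j in _JOINTS],
        parent_index=np.array([j[1] for j in _JOINTS]),
        offsets=np.array([j[2] for j in _JOINTS], dtype=float),
    )


@dataclass
class GeneratorConfig:
    seed: int = 0
    frame_rate: float = 120.0
    duration_mean_sd: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DURATIONS)
    )
    n_students: int = 95
    grade_mix: dict[int, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GRADE_MIX)
    )
    perturb_scales: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PERTURB_SCALES)
    )

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_students < 1:
            raise ValueError("n_students must be >= 1")
        for c, mix in self.grade_mix.items():
            if len(mix) != 3 or any(p < 0 for p in mix) or abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"grade mix for class {c} must be 3 non-negative proportions summing to 1")
        for grade in GRADES:
            if grade not in self.perturb_scales:
                raise ValueError(f"perturb_scales missing grade '{grade}'")
            if not 0.0 <= self.perturb_scales[grade][2] < 1.0:
                raise ValueError("warp strength must lie in [0, 1)")
        g, p, f = (np.array(self.perturb_scales[x], dtype=float) for x in GRADES)
        all_zero = not (g.any() or p.any() or f.any())
        ordered = np.all(g <= p) and np.all(p <= f) and (all_zero or g.sum() < p.sum() < f.sum())
        if not ordered:
            raise ValueError("perturbation magnitudes must increase good -> pass -> fail")

    @property
    def classes(self) -> list[int]:
        return sorted(self.duration_mean_sd)


@dataclass
class LabelledMotion:
    motion: MotionSequence
    class_id: int
    role: str
    subject_id: str
    grade: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ("teacher", "student"):
            raise ValueError("role must be 'teacher' or 'student'")
        if self.role == "teacher" and self.grade is not None:
            raise ValueError("teacher motions carry no grade")
        if self.role == "student" and self.grade not in GRADES:
            raise ValueError(f"unknown grade '{self.grade}'")


def _rng_for(config: GeneratorConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=key))


def _draw_duration(config: GeneratorConfig, class_id: int, rng) -> float:
    mean, sd = config.duration_mean_sd[class_id]
    return float(max(rng.normal(mean, sd), 0.6))


def _template_curves(config: GeneratorConfig, class_id: int):
    """Class-specific smooth curve parameters for each joint channel."""
    rng = _rng_for(config, class_id, 0)
    J = len(_JOINTS)
    params = []
    for j in range(J):
        ch_params = []
        for _ in range(3):
            mean = rng.uniform(-25.0, 25.0)
            n_harm = int(rng.integers(1, 4))
            amps = rng.uniform(8.0, 35.0, size=n_harm) / (1.0 + np.arange(n_harm))
            freqs = rng.uniform(0.5, 2.5) * (1.0 + np.arange(n_harm)) + rng.uniform(
                -0.2, 0.2, size=n_harm
            )
            phases = rng.uniform(0.0, 2.0 * np.pi, size=n_harm)
            ch_params.append((mean, amps, freqs, phases))
        params.append(ch_params)
    return params


def _eval_curves(params, u: np.ndarray) -> np.ndarray:
    """Evaluate template curves at normalised phase u in [0, 1]."""
    F = len(u)
    J = len(params)
    euler = np.empty((F, J, 3))
    for j in range(J):
        for c in range(3):
            mean, amps, freqs, phases = params[j][c]
            val = np.full(F, mean)
            for a, f, ph in zip(amps, freqs, phases):
                val += a * np.sin(2.0 * np.pi * f * u + ph)
            euler[:, j, c] = val
    return euler


def make_teacher_template(class_id: int, config: GeneratorConfig) -> LabelledMotion:
    """The latent ideal performance of one class; deterministic per
    (seed, class_id)."""
    if class_id not in config.duration_mean_sd:
        raise ValueError(f"class_id {class_id} out of range")
    rng = _rng_for(config, class_id, 1)
    duration = _draw_duration(config, class_id, rng)
    F = max(int(round(duration * config.frame_rate)), 4)
    u = np.linspace(0.0, 1.0, F)
    euler = _eval_curves(_template_curves(config, class_id), u)
    root = np.zeros((F, 3))
    root[:, 1] = 95.0 + 2.0 * np.sin(2.0 * np.pi * u)  # slight vertical bob
    motion = MotionSequence(default_skeleton(), 1.0 / config.frame_rate, euler, root)
    return LabelledMotion(motion, class_id, "teacher", f"T{class_id}")


def _monotone_warp(u: np.ndarray, strength: float, rng) -> np.ndarray:
    """Strictly increasing random re-parameterisation of [0, 1]; identity
    when strength is 0."""
    if strength == 0.0:
        return u
    knots = 5
    raw = rng.gamma(2.0, 1.0, size=knots)
    cum = np.concatenate([[0.0], np.cumsum(raw)])
    cum /= cum[-1]
    grid = np.linspace(0.0, 1.0, knots + 1)
    warped = np.interp(u, grid, cum)
    return (1.0 - strength) * u + strength * warped


def _smooth_noise(rng, F: int, sd: float) -> np.ndarray:
    """Band-limited noise with the requested pointwise SD."""
    if sd == 0.0 or F < 2:
        return np.zeros(F)
    u = np.linspace(0.0, 1.0, F)
    val = np.zeros(F)
    for _ in range(3):
        f = rng.uniform(0.5, 4.0)
        ph = rng.uniform(0.0, 2.0 * np.pi)
        val += rng.normal(0.0, 1.0) * np.sin(2.0 * np.pi * f * u + ph)
    s = val.std()
    return val * (sd / s) if s > 0 else np.zeros(F)


def _resample_channels(arr: np.ndarray, phase: np.ndarray) -> np.ndarray:
    """Sample (F, ...) channel data at fractional phase positions."""
    F = arr.shape[0]
    t = phase * (F - 1)
    flat = arr.reshape(F, -1)
    out = np.empty((len(phase), flat.shape[1]))
    src = np.arange(F, dtype=float)
    for c in range(flat.shape[1]):
        out[:, c] = np.interp(t, src, flat[:, c])
    return out.reshape((len(phase),) + arr.shape[1:])


def _perturb(
    template: MotionSequence,
    scales: tuple[float, float, float],
    duration: float,
    frame_rate: float,
    rng,
) -> MotionSequence:
    amp_sd, offset_deg, warp_strength = scales
    F = max(int(round(duration * frame_rate)), 4)
    u = np.linspace(0.0, 1.0, F)
    phase = _monotone_warp(u, warp_strength, rng)
    euler = _resample_channels(template.euler, phase)
    root = _resample_channels(template.root_translation, phase)
    J = euler.shape[1]
    if amp_sd > 0:
        for j in range(J):
            for c in range(3):
                euler[:, j, c] += _smooth_noise(rng, F, amp_sd)
    if offset_deg > 0:
        mask = rng.random(J) < 0.3
        if not mask.any():
            mask[rng.integers(J)] = True
        for j in np.flatnonzero(mask):
            c = int(rng.integers(3))
            euler[:, j, c] += offset_deg * rng.choice([-1.0, 1.0])
    return MotionSequence(template.skeleton, 1.0 / frame_rate, euler, root)


def make_student_motion(
    template: LabelledMotion,
    grade: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
    subject_id: str = "S?",
) -> LabelledMotion:
    """A graded student performance derived from a teacher template by
    time warping, smooth amplitude noise, and joint-angle offsets with
    grade-indexed magnitudes; the duration is re-drawn from the class
    distribution."""
    if template.role != "teacher":
        raise ValueError("template must be a teacher motion")
    if grade not in GRADES:
        raise ValueError(f"unknown grade '{grade}'")
    duration = _draw_duration(config, template.class_id, rng)
    motion = _perturb(
        template.motion, config.perturb_scales[grade], duration, config.frame_rate, rng
    )
    return LabelledMotion(motion, template.class_id, "student", subject_id, grade)


def _grade_allocation(config: GeneratorConfig, class_id: int) -> list[str]:
    """Deterministic largest-remainder allocation of grades to students,
    shuffled by the class substream."""
    n = config.n_students
    props = np.array(config.grade_mix[class_id], dtype=float)
    counts = np.floor(props * n).astype(int)
    rem = props * n - counts
    while counts.sum() < n:
        i = int(np.argmax(rem))
        counts[i] += 1
        rem[i] = -1.0
    grades = [g for g, c in zip(GRADES, counts) for _ in range(c)]
    rng = _rng_for(config, class_id, 2)
    rng.shuffle(grades)
    return grades


def generate_cohort(config: GeneratorConfig, out_dir=None):
    """Full labelled cohort: 3 teacher repetitions plus n_students graded
    performances per class.

    If ``out_dir`` is given, each motion is written as a BVH file and a
    tab-delimited label file ``labels.tsv`` (columns subject_id, class_id,
    role, grade, file) is written alongside; two runs with the same seed
    produce byte-identical label files.

    Returns the list of :class:`LabelledMotion`.
    """
    cohort: list[LabelledMotion] = []
    for class_id in config.classes:
        template = make_teacher_template(class_id, config)
        cohort.append(LabelledMotion(template.motion, class_id, "teacher", f"T{class_id}_r1"))
        for r in (2, 3):
            rng = _rng_for(config, class_id, 3, r)
            duration = _draw_duration(config, class_id, rng)
            rep = _perturb(
                template.motion,
                config.perturb_scales["teacher"],
                duration,
                config.frame_rate,
                rng,
            )
            cohort.append(LabelledMotion(rep, class_id, "teacher", f"T{class_id}_r{r}"))
        grades = _grade_allocation(config, class_id)
        for i, grade in enumerate(grades, start=1):
            rng = _rng_for(config, class_id, 4, i)
            cohort.append(
                make_student_motion(template, grade, config, rng, f"S{class_id}_{i:03d}")
            )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for lm in cohort:
            fname = f"{lm.subject_id}.bvh"
            write_bvh(lm.motion, out / fname)
            rows.append(
                {
                    "subject_id": lm.subject_id,
                    "class_id": lm.class_id,
                    "role": lm.role,
                    "grade": lm.grade if lm.grade is not None else "",
                    "file": fname,
                }
            )
        pd.DataFrame(rows).to_csv(out / "labels.tsv", sep="\t", index=False)
    return cohort


def load_cohort(label_dir) -> list[LabelledMotion]:
    """Read a cohort back from a directory written by :func:`generate_cohort`
    (or any directory holding BVH files plus a ``labels.tsv``)."""
    d = Path(label_dir)
    labels = pd.read_csv(d / "labels.tsv", sep="\t", keep_default_na=False)
    cohort = []
    for row in labels.itertuples(index=False):
        grade = row.grade if row.grade else None
        cohort.append(
            LabelledMotion(
                motion=read_bvh(d / row.file),
                class_id=int(row.class_id),
                role=row.role,
                subject_id=str(row.subject_id),
                grade=grade,
            )
        )
    return cohort
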