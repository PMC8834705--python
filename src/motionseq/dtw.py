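"""Windowed dynamic time warping on per-joint quaternion trajectories.

Each joint of a candidate motion is aligned independently against the same
joint of a reference motion by DTW with step set {(1,0), (0,1), (1,1)} and
a Sakoe-Chiba band of half-width ceil(window_fraction * max(n, m)) around
the slope-corrected diagonal.  The per-joint distance is the minimum
cumulative cost divided by the optimal warping path's cell count, and the
overall motion distance D is the mean of the per-joint distances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .motion_io import QuaternionSequence

__all__ = [
    "DTWConfig",
    "DistanceProfile",
    "dtw_joint",
    "joint_distance",
    "motion_distance",
    "build_assessment_features",
    "build_recognition_features",
]

_INF = np.inf


@dataclass
class DTWConfig:
    """window_fraction: Sakoe-Chiba half-width as a fraction of max(n, m)
    (the warping window, default 10%).  local_metric: 'euclidean' on
    canonical [w,x,y,z] 4-vectors (default) or 'angle' (geodesic rotation
    angle).  scalar_features: assessment features as the single overall
    distance D instead of the 17 per-joint distances."""

    window_fraction: float = 0.10
    local_metric: str = "euclidean"
    scalar_features: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.window_fraction <= 1.0:
            raise ValueError("window_fraction must be in (0, 1]")
        if self.local_metric not in ("euclidean", "angle"):
            raise ValueError("local_metric must be 'euclidean' or 'angle'")


@dataclass
class DistanceProfile:
    """Per-joint path-normalised DTW distances and their mean."""

    per_joint: np.ndarray
    path_lengths: np.ndarray
    overall: float

    def __post_init__(self) -> None:
        self.per_joint = np.asarray(self.per_joint, dtype=float)
        self.path_lengths = np.asarray(self.path_lengths, dtype=int)
        if np.any(self.per_joint < 0):
            raise ValueError("distances must be non-negative")


@njit(cache=False)
def _dtw_kernel(A, B, halfwidth, use_angle):  # pragma: no cover - compiled
    """Banded DTW for J joints sharing lengths (n, m).

    A: (J, n, d), B: (J, m, d).  Returns (cum[J], plen[J]); cum[j] is inf
    if the band disconnects the corners.
    """
    J, n, d = A.shape
    m = B.shape[1]
    cum = np.empty(J)
    plen = np.zeros(J, dtype=np.int64)
    slope = (m - 1.0) / (n - 1.0) if n > 1 else 0.0
    for j in range(J):
        D = np.full((n, m), _INF)
        for i in range(n):
            center = slope * i if n > 1 else 0.0
            lo = int(max(0.0, math.ceil(center - halfwidth)))
            hi = int(min(m - 1.0, math.floor(center + halfwidth)))
            for jj in range(lo, hi + 1):
                if use_angle:
                    dot = 0.0
                    for c in range(d):
                        dot += A[j, i, c] * B[j, jj, c]
                    if dot > 1.0:
                        dot = 1.0
                    elif dot < -1.0:
                        dot = -1.0
                    cost = 2.0 * math.acos(abs(dot))
                else:
                    s = 0.0
                    for c in range(d):
                        diff = A[j, i, c] - B[j, jj, c]
                        s += diff * diff
                    cost = math.sqrt(s)
                if i == 0 and jj == 0:
                    D[0, 0] = cost
                    continue
                best = _INF
                if i > 0 and jj > 0 and D[i - 1, jj - 1] < best:
                    best = D[i - 1, jj - 1]
                if i > 0 and D[i - 1, jj] < best:
                    best = D[i - 1, jj]
                if jj > 0 and D[i, jj - 1] < best:
                    best = D[i, jj - 1]
                if best < _INF:
                    D[i, jj] = cost + best
        cum[j] = D[n - 1, m - 1]
        if not np.isfinite(cum[j]):
            continue
        # traceback, preferring the diagonal on ties, to count path cells
        i, jj = n - 1, m - 1
        count = 1
        while i > 0 or jj > 0:
            best = _INF
            bi, bj = i, jj
            if i > 0 and jj > 0 and D[i - 1, jj - 1] <= best:
                best = D[i - 1, jj - 1]
                bi, bj = i - 1, jj - 1
            if i > 0 and D[i - 1, jj] < best:
                best = D[i - 1, jj]
                bi, bj = i - 1, jj
            if jj > 0 and D[i, jj - 1] < best:
                best = D[i, jj - 1]
                bi, bj = i, jj - 1
            i, jj = bi, bj
            count += 1
        plen[j] = count
    return cum, plen


def _run_banded(A: np.ndarray, B: np.ndarray, config: DTWConfig):
    """Run the kernel, widening the band if it disconnects the corners."""
    n, m = A.shape[1], B.shape[1]
    w = max(1, math.ceil(config.window_fraction * max(n, m)))
    use_angle = config.local_metric == "angle"
    while True:
        cum, plen = _dtw_kernel(
            np.ascontiguousarray(A, dtype=np.float64),
            np.ascontiguousarray(B, dtype=np.float64),
            float(w),
            use_angle,
        )
        if np.isfinite(cum).all():
            return cum, plen
        if w >= max(n, m):  # full window is always feasible
            raise RuntimeError("DTW failed on a full window")  # unreachable
        w = min(2 * w, max(n, m))
        warnings.warn(
            f"DTW band too narrow to connect corners for lengths ({n}, {m}); "
            f"widened to half-width {w}",
            stacklevel=3,
        )


def dtw_joint(a: np.ndarray, b: np.ndarray, config: DTWConfig | None = None):
    """Banded DTW of two single-joint trajectories (n, d) and (m, d).

    Returns (cumulative_distance, path_length): the minimum cumulative
    local cost over monotone paths within the band, and the number of
    cells on the optimal path.
    """
    config = config or DTWConfig()
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] < 1 or b.shape[0] < 1:
        raise ValueError("trajectories must be non-empty")
    cum, plen = _run_banded(a[None, :, :], b[None, :, :], config)
    return float(cum[0]), int(plen[0])


def joint_distance(a: np.ndarray, b: np.ndarray, config: DTWConfig | None = None) -> float:
    """Path-normalised DTW distance: cumulative cost / path length."""
    cum, plen = dtw_joint(a, b, config)
    return cum / plen


def motion_distance(
    student: QuaternionSequence,
    teacher: QuaternionSequence,
    config: DTWConfig | None = None,
) -> DistanceProfile:
    """Per-joint path-normalised distances and their mean D."""
    config = config or DTWConfig()
    if student.n_joints != teacher.n_joints:
        raise ValueError(
            f"joint-count mismatch: {student.n_joints} vs {teacher.n_joints}"
        )
    A = np.transpose(student.quat, (1, 0, 2))  # (J, n, 4)
    B = np.transpose(teacher.quat, (1, 0, 2))
    cum, plen = _run_banded(A, B, config)
    per_joint = cum / plen
    return DistanceProfile(per_joint=per_joint, path_lengths=plen, overall=float(per_joint.mean()))


def build_assessment_features(
    motion: QuaternionSequence,
    teacher_refs: list[QuaternionSequence],
    config: DTWConfig | None = None,
) -> np.ndarray:
    """Per-joint distances to a class's teacher repetitions, averaged over
    the repetitions (17-dim), or the scalar overall distance if the config
    selects scalar features."""
    config = config or DTWConfig()
    if not teacher_refs:
        raise ValueError("teacher_refs must be non-empty")
    profiles = [motion_distance(motion, ref, config) for ref in teacher_refs]
    per_joint = np.mean([p.per_joint for p in profiles], axis=0)
    if config.scalar_features:
        return np.array([per_joint.mean()])
    return per_joint


def build_recognition_features(
    motion: QuaternionSequence,
    teacher_library: dict[int, list[QuaternionSequence]],
    config: DTWConfig | None = None,
) -> np.ndarray:
    """Overall distance D to each class's teacher reference (averaged over
    that class's repetitions); one component per class, in class-id order."""
    config = config or DTWConfig()
    if not teacher_library:
        raise ValueError("teacher library is empty")
    feats = []
    for class_id in sorted(teacher_library):
        refs = teacher_library[class_id]
        if not refs:
            raise ValueError(f"no teacher reference for class {class_id}")
        dists = [motion_distance(motion, ref, config).overall for ref in refs]
        feats.append(float(np.mean(dists)))
    return np.array(feats)
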