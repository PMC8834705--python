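"""Keyframe extraction by k-means pose clustering and reconstruction scoring.

A motion of N frames is compressed to k = round(C_rate * N) keyframes by
clustering the per-frame 51-dim pose vectors (17 joints x 3 coordinates)
with k-means (Euclidean distance) and keeping, for each centroid, the
original frame nearest to it.  The full sequence is then rebuilt by linear
interpolation between flanking keyframes and scored by the mean per-frame
posture distance (sum over joints of the Euclidean joint displacement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .motion_io import PositionSequence

__all__ = [
    "CompressionConfig",
    "KeyframeResult",
    "compute_k",
    "extract_keyframes",
    "interpolate_frame",
    "reconstruct",
    "reconstruction_error",
    "compression_sweep",
]


@dataclass
class CompressionConfig:
    """Settings for keyframe extraction.

    c_rate : fraction of frames to keep, in (0, 1].
    kmeans_max_iter, kmeans_restarts : k-means budget (restart-best-of-R
        with seeded k-means++ initialisation, which spreads the initial
        centroids over distinct frames).
    """

    c_rate: float = 0.15
    kmeans_max_iter: int = 50
    kmeans_restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.c_rate <= 1.0:
            raise ValueError("c_rate must be in (0, 1]")
        if self.kmeans_max_iter < 1 or self.kmeans_restarts < 1:
            raise ValueError("k-means budget must be positive")


@dataclass
class KeyframeResult:
    k: int
    indices: np.ndarray
    key_positions: np.ndarray
    reconstruction_error: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.k != len(self.indices):
            raise ValueError("k must equal the number of keyframe indices")
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError("indices must be strictly increasing")
        if self.reconstruction_error < 0:
            raise ValueError("reconstruction error must be non-negative")


def compute_k(c_rate: float, n_frames: int) -> int:
    """Number of keyframes k = C_rate * N, rounded half-up, clamped to
    [1, N] (and to >= 2 whenever N >= 2 so both endpoints can be kept)."""
    if not 0.0 < c_rate <= 1.0:
        raise ValueError("c_rate must be in (0, 1]")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    k = int(math.floor(c_rate * n_frames + 0.5))
    k = max(1, min(k, n_frames))
    if n_frames >= 2:
        k = max(k, 2)
    return k


def extract_keyframes(positions: PositionSequence, config: CompressionConfig) -> KeyframeResult:
    """Select keyframes by k-means on pose vectors.

    For each cluster centroid the nearest original frame becomes a
    keyframe; collisions are backfilled with the next-nearest unused frame
    so exactly k distinct frames result.  The first and last frames are
    force-included (replacing the worst-matching keyframes) so that every
    non-keyframe has flanking keyframes for interpolation.
    """
    X = positions.as_vectors()
    N = X.shape[0]
    k = compute_k(config.c_rate, N)
    if k > N:
        raise ValueError("k exceeds the number of frames")

    if k == N:
        indices = np.arange(N)
        quality = np.zeros(N)
    else:
        km = KMeans(
            n_clusters=k,
            n_init=config.kmeans_restarts,
            max_iter=config.kmeans_max_iter,
            random_state=config.seed,
        ).fit(X)
        d = np.linalg.norm(X[None, :, :] - km.cluster_centers_[:, None, :], axis=2)
        chosen: list[int] = []
        used = np.zeros(N, dtype=bool)
        qual: list[float] = []
        for c in range(k):
            order = np.argsort(d[c], kind="stable")
            for f in order:
                if not used[f]:
                    used[f] = True
                    chosen.append(int(f))
                    qual.append(float(d[c, f]))
                    break
        indices = np.array(chosen)
        quality = np.array(qual)
        # force-include endpoints, evicting the worst-matching keyframes
        for endpoint in (0, N - 1):
            if endpoint not in indices:
                evictable = np.array([i not in (0, N - 1) for i in indices])
                worst = np.flatnonzero(evictable)[np.argmax(quality[evictable])]
                indices[worst] = endpoint
                quality[worst] = 0.0
        order = np.argsort(indices)
        indices = indices[order]

    key_positions = positions.pos[indices]
    err = _error_for(positions, indices)
    return KeyframeResult(k=k, indices=indices, key_positions=key_positions, reconstruction_error=err)


def interpolate_frame(p1: np.ndarray, p2: np.ndarray, t1: float, t: float, t2: float) -> np.ndarray:
    """Linear blend of two keyframe poses: u(t) = (t2 - t)/(t2 - t1),
    p_t = u p1 + (1 - u) p2, valid for t1 < t < t2."""
    if not t1 < t < t2:
        raise ValueError("t must lie strictly between t1 and t2")
    u = (t2 - t) / (t2 - t1)
    return u * np.asarray(p1, dtype=float) + (1.0 - u) * np.asarray(p2, dtype=float)


def reconstruct(original: PositionSequence, indices: np.ndarray) -> PositionSequence:
    """Rebuild all frames: keyframes verbatim, non-keyframes linearly
    interpolated between flanking keyframes (time = frame index)."""
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        raise ValueError("at least one keyframe is required")
    N = original.n_frames
    t = np.arange(N, dtype=float)
    flat = original.pos.reshape(N, -1)
    out = np.empty_like(flat)
    for c in range(flat.shape[1]):
        out[:, c] = np.interp(t, indices.astype(float), flat[indices, c])
    return PositionSequence(out.reshape(original.pos.shape))


def _error_for(original: PositionSequence, indices: np.ndarray) -> float:
    rebuilt = reconstruct(original, indices)
    disp = np.linalg.norm(original.pos - rebuilt.pos, axis=2)  # (N, joints)
    return float(disp.sum(axis=1).mean())


def reconstruction_error(original: PositionSequence, keyframes: KeyframeResult) -> float:
    """Mean per-frame posture distance between the original motion and its
    reconstruction: Dis_i = sum_j ||p1_ij - p2_ij||, Error = mean_i Dis_i."""
    return _error_for(original, keyframes.indices)


def compression_sweep(
    positions: PositionSequence,
    rates,
    kmeans_max_iter: int = 50,
    kmeans_restarts: int = 5,
    seed: int = 0,
) -> dict[float, float]:
    """Reconstruction error at each compression rate (e.g. 5%..25%)."""
    table: dict[float, float] = {}
    for r in rates:
        cfg = CompressionConfig(
            c_rate=r,
            kmeans_max_iter=kmeans_max_iter,
            kmeans_restarts=kmeans_restarts,
            seed=seed,
        )
        table[float(r)] = extract_keyframes(positions, cfg).reconstruction_error
    return table
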