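"""BVH motion I/O, quaternion conversion, and forward kinematics.

A skeletal motion is a hierarchy of joints (HIERARCHY section of a BVH
file) plus per-frame channel data (MOTION section).  Rotations are stored
as Euler angles in degrees and are interpreted throughout the package with
a fixed z, y, x application order: the local rotation of a joint with
angles (alpha, beta, gamma) about the x, y and z axes is

    R = Rz(gamma) @ Ry(beta) @ Rx(alpha)

and the equivalent unit quaternion is the product qz(gamma) * qy(beta) *
qx(alpha).  The file's declared channel order only decides how numbers are
read off each frame line; the application order above is fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "SkeletonModel",
    "MotionSequence",
    "QuaternionSequence",
    "PositionSequence",
    "BVHParseError",
    "read_bvh",
    "write_bvh",
    "euler_to_quaternion",
    "canonicalize",
    "motion_to_quaternions",
    "forward_kinematics",
]

_ROT_AXIS = {"Xrotation": 0, "Yrotation": 1, "Zrotation": 2}
_POS_AXIS = {"Xposition": 0, "Yposition": 1, "Zposition": 2}


class BVHParseError(ValueError):
    """Raised when a BVH file is structurally malformed."""


@dataclass
class SkeletonModel:
    """Joint tree: names, parent indices (root = -1), rest offsets in cm.

    ``channel_order`` lists, per joint, the channel labels exactly as they
    appear (or should appear) in the BVH file, e.g.
    ``("Zrotation", "Yrotation", "Xrotation")`` for a non-root joint.
    """

    joint_names: list[str]
    parent_index: np.ndarray
    offsets: np.ndarray
    channel_order: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.parent_index = np.asarray(self.parent_index, dtype=int)
        self.offsets = np.asarray(self.offsets, dtype=float)
        n = len(self.joint_names)
        if self.parent_index.shape != (n,):
            raise ValueError("parent_index length must match joint count")
        if self.offsets.shape != (n, 3):
            raise ValueError("offsets must be (n_joints, 3)")
        roots = np.flatnonzero(self.parent_index < 0)
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root joint, found {len(roots)}")
        if roots[0] != 0:
            raise ValueError("root joint must be first")
        # topological order: every child appears after its parent
        if np.any(self.parent_index[1:] >= np.arange(1, n)):
            raise ValueError("joints must be listed in topological order")
        if not self.channel_order:
            self.channel_order = [
                (
                    "Xposition", "Yposition", "Zposition",
                    "Zrotation", "Yrotation", "Xrotation",
                )
            ] + [("Zrotation", "Yrotation", "Xrotation")] * (n - 1)

    @property
    def n_joints(self) -> int:
        return len(self.joint_names)


@dataclass
class MotionSequence:
    """Per-frame Euler rotations (degrees) + root translation (cm).

    ``euler`` has shape (frames, joints, 3); column j holds the rotation
    angle about axis j in (x, y, z), applied in z, y, x order.
    """

    skeleton: SkeletonModel
    frame_time: float
    euler: np.ndarray
    root_translation: np.ndarray

    def __post_init__(self) -> None:
        self.euler = np.asarray(self.euler, dtype=float)
        self.root_translation = np.asarray(self.root_translation, dtype=float)
        if self.euler.ndim != 3 or self.euler.shape[1:] != (self.skeleton.n_joints, 3):
            raise ValueError("euler must be (frames, n_joints, 3)")
        if self.euler.shape[0] < 1:
            raise ValueError("motion must contain at least one frame")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be positive")
        if self.root_translation.shape != (self.n_frames, 3):
            raise ValueError("root_translation must be (frames, 3)")
        if not (np.isfinite(self.euler).all() and np.isfinite(self.root_translation).all()):
            raise ValueError("motion data must be finite")

    @property
    def n_frames(self) -> int:
        return self.euler.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_time


@dataclass
class QuaternionSequence:
    """Unit quaternions [w, x, y, z] per frame per joint, w >= 0."""

    quat: np.ndarray

    def __post_init__(self) -> None:
        self.quat = np.asarray(self.quat, dtype=float)
        if self.quat.ndim != 3 or self.quat.shape[2] != 4:
            raise ValueError("quat must be (frames, joints, 4)")

    @property
    def n_frames(self) -> int:
        return self.quat.shape[0]

    @property
    def n_joints(self) -> int:
        return self.quat.shape[1]


@dataclass
class PositionSequence:
    """Global 3D joint coordinates (cm) per frame."""

    pos: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.ndim != 3 or self.pos.shape[2] != 3:
            raise ValueError("pos must be (frames, joints, 3)")
        if not np.isfinite(self.pos).all():
            raise ValueError("positions must be finite")

    @property
    def n_frames(self) -> int:
        return self.pos.shape[0]

    def as_vectors(self) -> np.ndarray:
        """Flatten to (frames, joints*3) pose vectors (51-dim for 17 joints)."""
        return self.pos.reshape(self.pos.shape[0], -1)


# ---------------------------------------------------------------------------
# quaternions


def euler_to_quaternion(alpha, beta, gamma):
    """Convert Euler angles (radians, rotations about x, y, z) to [w,x,y,z].

    The rotation is applied in z, y, x order, so the quaternion is the
    product qz(gamma) * qy(beta) * qx(alpha), expanded in closed form:

        w = cos(g/2)cos(b/2)cos(a/2) + sin(g/2)sin(b/2)sin(a/2)
        x = cos(g/2)cos(b/2)sin(a/2) - sin(g/2)sin(b/2)cos(a/2)
        y = cos(g/2)sin(b/2)cos(a/2) + sin(g/2)cos(b/2)sin(a/2)
        z = sin(g/2)cos(b/2)cos(a/2) - cos(g/2)sin(b/2)sin(a/2)

    Accepts scalars or broadcastable arrays; returns shape (..., 4).
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    ca, sa = np.cos(alpha / 2), np.sin(alpha / 2)
    cb, sb = np.cos(beta / 2), np.sin(beta / 2)
    cg, sg = np.cos(gamma / 2), np.sin(gamma / 2)
    w = cg * cb * ca + sg * sb * sa
    x = cg * cb * sa - sg * sb * ca
    y = cg * sb * ca + sg * cb * sa
    z = sg * cb * ca - cg * sb * sa
    return np.stack([w, x, y, z], axis=-1)


def canonicalize(q: np.ndarray) -> np.ndarray:
    """Resolve the q / -q double cover: flip sign so w > 0.

    If w == 0, the sign is fixed so the first nonzero component is
    positive.  Works on arrays of shape (..., 4).
    """
    q = np.asarray(q, dtype=float)
    norms = np.linalg.norm(q, axis=-1)
    if np.any(norms == 0):
        raise ValueError("cannot canonicalize a zero quaternion")
    flat = q.reshape(-1, 4)
    first = np.argmax(np.abs(flat) > 0, axis=1)  # first nonzero component
    lead = flat[np.arange(flat.shape[0]), first]
    sign = np.where(lead < 0, -1.0, 1.0)
    return (flat * sign[:, None]).reshape(q.shape)


def motion_to_quaternions(motion: MotionSequence, canonical: bool = True) -> QuaternionSequence:
    """Convert all joint Euler angles (degrees) to canonical quaternions."""
    rad = np.deg2rad(motion.euler)
    q = euler_to_quaternion(rad[..., 0], rad[..., 1], rad[..., 2])
    if canonical:
        q = canonicalize(q)
    return QuaternionSequence(q)


# ---------------------------------------------------------------------------
# forward kinematics


def forward_kinematics(motion: MotionSequence) -> PositionSequence:
    """Global joint positions from local rotations and rest offsets.

    Joint j's global position is its parent's global transform applied to
    the rest offset; the root takes the per-frame root translation.
    """
    skel = motion.skeleton
    F, J = motion.n_frames, skel.n_joints
    # intrinsic Z-Y-X with angles (gamma, beta, alpha) == Rz(g) @ Ry(b) @ Rx(a)
    ang = motion.euler[:, :, ::-1].reshape(-1, 3)
    local = Rotation.from_euler("ZYX", ang, degrees=True).as_matrix().reshape(F, J, 3, 3)
    global_rot = np.empty((F, J, 3, 3))
    pos = np.empty((F, J, 3))
    global_rot[:, 0] = local[:, 0]
    pos[:, 0] = motion.root_translation
    for j in range(1, J):
        p = skel.parent_index[j]
        if p >= j:
            raise ValueError("cyclic or non-topological joint hierarchy")
        pos[:, j] = pos[:, p] + np.einsum("fab,b->fa", global_rot[:, p], skel.offsets[j])
        global_rot[:, j] = global_rot[:, p] @ local[:, j]
    return PositionSequence(pos)


# ---------------------------------------------------------------------------
# BVH reading


def read_bvh(path) -> MotionSequence:
    """Parse a BVH file into a :class:`MotionSequence`.

    The parser is dialect-tolerant: any per-joint channel order declared in
    the file is accepted; End Sites are skipped.  A skeleton that does not
    have 17 joints triggers a warning (the pipeline core is
    skeleton-agnostic) but is read normally.
    """
    with open(path) as fh:
        tokens = fh.read().split()
    if not tokens or tokens[0].upper() != "HIERARCHY":
        raise BVHParseError(f"{path}: file does not start with HIERARCHY")

    names: list[str] = []
    parents: list[int] = []
    offsets: list[list[float]] = []
    channels: list[tuple[str, ...]] = []

    i = 1
    stack: list[int] = []

    def expect(tok: str) -> None:
        nonlocal i
        if i >= len(tokens) or tokens[i] != tok:
            got = tokens[i] if i < len(tokens) else "<eof>"
            raise BVHParseError(f"{path}: expected '{tok}', got '{got}'")
        i += 1

    while i < len(tokens) and tokens[i].upper() != "MOTION":
        tok = tokens[i]
        up = tok.upper()
        if up in ("ROOT", "JOINT"):
            i += 1
            name = tokens[i]
            i += 1
            parents.append(stack[-1] if stack else -1)
            names.append(name)
            expect("{")
            expect("OFFSET")
            offsets.append([float(tokens[i + k]) for k in range(3)])
            i += 3
            expect("CHANNELS")
            nch = int(tokens[i])
            i += 1
            ch = tuple(tokens[i: i + nch])
            for c in ch:
                if c not in _ROT_AXIS and c not in _POS_AXIS:
                    raise BVHParseError(f"{path}: unknown channel '{c}'")
            i += nch
            channels.append(ch)
            stack.append(len(names) - 1)
        elif up == "END":  # "End Site"
            i += 2
            expect("{")
            expect("OFFSET")
            i += 3
            expect("}")
        elif tok == "}":
            if not stack:
                raise BVHParseError(f"{path}: unbalanced '}}'")
            stack.pop()
            i += 1
        else:
            raise BVHParseError(f"{path}: unexpected token '{tok}' in HIERARCHY")
    if i >= len(tokens):
        raise BVHParseError(f"{path}: missing MOTION section")
    if stack:
        raise BVHParseError(f"{path}: unclosed joint block")
    if not names:
        raise BVHParseError(f"{path}: no joints declared")
    i += 1  # MOTION
    if tokens[i].rstrip(":") != "Frames":
        raise BVHParseError(f"{path}: expected 'Frames:' line")
    i += 1
    if tokens[i] == ":":
        i += 1
    n_frames = int(tokens[i])
    i += 1
    if tokens[i] != "Frame" or tokens[i + 1].rstrip(":") != "Time":
        raise BVHParseError(f"{path}: expected 'Frame Time:' line")
    i += 2
    if tokens[i] == ":":
        i += 1
    frame_time = float(tokens[i])
    i += 1

    values = np.array(tokens[i:], dtype=float)
    n_channels = sum(len(c) for c in channels)
    if values.size != n_frames * n_channels:
        raise BVHParseError(
            f"{path}: MOTION data has {values.size} values, expected "
            f"{n_frames} frames x {n_channels} channels"
        )
    values = values.reshape(n_frames, n_channels)

    J = len(names)
    if J != 17:
        warnings.warn(
            f"{path}: skeleton has {J} joints (pipeline default is 17)",
            stacklevel=2,
        )
    euler = np.zeros((n_frames, J, 3))
    root_t = np.zeros((n_frames, 3))
    col = 0
    for j, ch in enumerate(channels):
        for c in ch:
            if c in _ROT_AXIS:
                euler[:, j, _ROT_AXIS[c]] = values[:, col]
            elif j == 0:
                root_t[:, _POS_AXIS[c]] = values[:, col]
            col += 1

    skel = SkeletonModel(names, np.array(parents), np.array(offsets), channels)
    return MotionSequence(skel, frame_time, euler, root_t)


def write_bvh(motion: MotionSequence, path) -> str:
    """Write a MotionSequence as standard BVH text; inverse of read_bvh
    within the printed precision (6 decimals)."""
    skel = motion.skeleton
    children: list[list[int]] = [[] for _ in range(skel.n_joints)]
    for j in range(1, skel.n_joints):
        children[skel.parent_index[j]].append(j)

    lines: list[str] = ["HIERARCHY"]

    def emit(j: int, depth: int) -> None:
        ind = "  " * depth
        kw = "ROOT" if depth == 0 else "JOINT"
        lines.append(f"{ind}{kw} {skel.joint_names[j]}")
        lines.append(f"{ind}{{")
        off = skel.offsets[j]
        lines.append(f"{ind}  OFFSET {off[0]:.6f} {off[1]:.6f} {off[2]:.6f}")
        ch = skel.channel_order[j]
        lines.append(f"{ind}  CHANNELS {len(ch)} " + " ".join(ch))
        if children[j]:
            for c in children[j]:
                emit(c, depth + 1)
        else:
            lines.append(f"{ind}  End Site")
            lines.append(f"{ind}  {{")
            lines.append(f"{ind}    OFFSET 0.000000 0.000000 0.000000")
            lines.append(f"{ind}  }}")
        lines.append(f"{ind}}}")

    emit(0, 0)
    lines.append("MOTION")
    lines.append(f"Frames: {motion.n_frames}")
    lines.append(f"Frame Time: {motion.frame_time:.8f}")
    for f in range(motion.n_frames):
        vals: list[float] = []
        for j, ch in enumerate(skel.channel_order):
            for c in ch:
                if c in _ROT_AXIS:
                    vals.append(motion.euler[f, j, _ROT_AXIS[c]])
                else:
                    vals.append(motion.root_translation[f, _POS_AXIS[c]] if j == 0 else 0.0)
        lines.append(" ".join(f"{v:.6f}" for v in vals))
    text = "\n".join(lines) + "\n"
    with open(path, "w") as fh:
        fh.write(text)
    return str(path)
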