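"""Frame-labelled rigid-transform algebra for tracked-tool navigation.

All coordinates are millimetres.  Transforms are stored as homogeneous 4x4
matrices with the column-vector convention ``p_parent = M @ p_child``; every
transform carries its parent and child frame labels so that an invalid chain
(e.g. composing a world<-probe transform with a world<-needle transform) is a
programming error, not a silent wrong answer.

Frames used throughout the package follow optical-tracking practice:

``world``
    the tracking camera's fixed frame,
``sono``
    the rigid tracking tool clamped to the ultrasound probe,
``image``
    the metric ultrasound image plane (z = 0 by construction),
``needle`` / ``tip``
    the needle's tracking tool and its calibrated tip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "FrameMismatchError",
    "RigidTransform",
    "PixelPoint",
    "PoseSample",
    "identity",
    "from_rotation_translation",
    "translation_transform",
    "rotation_about_axis",
    "compose",
    "invert",
    "transform_point",
    "pose_to_transform",
    "pixel_to_image_mm",
    "needle_tip_world",
    "read_pose_log",
    "write_pose_log",
]

_ORTHONORMALITY_TOL = 1e-9
_QUAT_NORM_TOL = 1e-6


class FrameMismatchError(ValueError):
    """Raised when two transforms (or a transform and a point) do not chain."""


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {R.shape}")
    err = np.abs(R.T @ R - np.eye(3)).max()
    if err > _ORTHONORMALITY_TOL:
        # bounded drift policy: snap to the nearest rotation (polar decomposition)
        R = nearest_rotation(R)
        err = np.abs(R.T @ R - np.eye(3)).max()
        if err > _ORTHONORMALITY_TOL:
            raise ValueError("matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("rotation must be proper (det +1), got a reflection")
    return R


def nearest_rotation(M: np.ndarray) -> np.ndarray:
    """Nearest proper rotation in the Frobenius norm (polar decomposition)."""
    U, _, Vt = np.linalg.svd(np.asarray(M, dtype=float))
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


@dataclass(frozen=True)
class RigidTransform:
    """A rigid map from ``child_frame`` coordinates to ``parent_frame`` ones.

    Parameters
    ----------
    parent_frame, child_frame
        Frame labels; composition requires the inner labels to match.
    matrix
        Homogeneous 4x4; the upper-left 3x3 must be a proper rotation.
    """

    parent_frame: str
    child_frame: str
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.shape != (4, 4):
            raise ValueError(f"homogeneous matrix must be 4x4, got {M.shape}")
        R = _check_rotation(M[:3, :3])
        M = M.copy()
        M[:3, :3] = R
        M[3] = (0.0, 0.0, 0.0, 1.0)
        object.__setattr__(self, "matrix", M)
        self.matrix.setflags(write=False)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return compose(self, other)

    def inv(self) -> "RigidTransform":
        return invert(self)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map point(s) from the child frame into the parent frame."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation


class PixelPoint(NamedTuple):
    """0-based pixel location: ``col`` lateral (rightwards), ``row`` axial (depth)."""

    col: float
    row: float


@dataclass(frozen=True)
class PoseSample:
    """One timestamped tracked-tool pose as reported by the camera.

    Quaternion order is scalar-first ``(w, x, y, z)``; translation in mm.
    """

    timestamp: float
    tool_id: str
    quaternion: tuple[float, float, float, float]
    translation: tuple[float, float, float]

    def __post_init__(self) -> None:
        q = np.asarray(self.quaternion, dtype=float)
        if q.shape != (4,):
            raise ValueError("quaternion must have 4 components (w, x, y, z)")
        if abs(np.linalg.norm(q) - 1.0) > _QUAT_NORM_TOL:
            raise ValueError(
                f"quaternion norm {np.linalg.norm(q):.6g} deviates from 1 "
                f"beyond {_QUAT_NORM_TOL}"
            )


def identity(parent: str = "world", child: str | None = None) -> RigidTransform:
    return RigidTransform(parent, child if child is not None else parent, np.eye(4))


def from_rotation_translation(
    R: np.ndarray,
    t: Sequence[float],
    parent: str = "world",
    child: str = "tool",
) -> RigidTransform:
    M = np.eye(4)
    M[:3, :3] = R
    M[:3, 3] = np.asarray(t, dtype=float)
    return RigidTransform(parent, child, M)


def translation_transform(
    t: Sequence[float], parent: str = "world", child: str = "tool"
) -> RigidTransform:
    return from_rotation_translation(np.eye(3), t, parent, child)


def rotation_about_axis(
    axis: str | Sequence[float],
    angle_deg: float,
    t: Sequence[float] = (0.0, 0.0, 0.0),
    parent: str = "world",
    child: str = "tool",
) -> RigidTransform:
    """Rotation of ``angle_deg`` about a named axis ('x'|'y'|'z') or 3-vector."""
    if isinstance(axis, str):
        R = Rotation.from_euler(axis, angle_deg, degrees=True)
    else:
        a = np.asarray(axis, dtype=float)
        a = a / np.linalg.norm(a)
        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * a)
    return from_rotation_translation(R.as_matrix(), t, parent, child)


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Chain ``a`` (X<-Y) with ``b`` (Y<-Z) into X<-Z."""
    if a.child_frame != b.parent_frame:
        raise FrameMismatchError(
            f"cannot chain {a.parent_frame}<-{a.child_frame} "
            f"with {b.parent_frame}<-{b.child_frame}"
        )
    return RigidTransform(a.parent_frame, b.child_frame, a.matrix @ b.matrix)


def invert(t: RigidTransform) -> RigidTransform:
    R = t.rotation.T
    M = np.eye(4)
    M[:3, :3] = R
    M[:3, 3] = -R @ t.translation
    return RigidTransform(t.child_frame, t.parent_frame, M)


def transform_point(t: RigidTransform, p: Sequence[float]) -> np.ndarray:
    """Map a point expressed in ``t.child_frame`` into ``t.parent_frame``."""
    return t.apply(np.asarray(p, dtype=float))


def pose_to_transform(
    s: PoseSample, parent: str = "world", child: str | None = None
) -> RigidTransform:
    """Convert a tracking sample into a world<-tool transform."""
    w, x, y, z = s.quaternion
    # scipy uses scalar-last (x, y, z, w)
    R = Rotation.from_quat([x, y, z, w]).as_matrix()
    return from_rotation_translation(
        R, s.translation, parent, child if child is not None else s.tool_id
    )


def pixel_to_image_mm(
    spacing: tuple[float, float], p: PixelPoint | Sequence[float]
) -> np.ndarray:
    """Embed a pixel into the metric image plane (z = 0).

    ``spacing`` is (mm/px lateral, mm/px axial); the image frame origin is the
    top-left pixel, x grows laterally with ``col`` and y with depth (``row``).
    """
    lateral, axial = float(spacing[0]), float(spacing[1])
    if lateral <= 0 or axial <= 0:
        raise ValueError(f"pixel spacing must be positive, got {spacing}")
    col, row = (p.col, p.row) if isinstance(p, PixelPoint) else (p[0], p[1])
    return np.array([col * lateral, row * axial, 0.0])


def needle_tip_world(
    world_T_needle: RigidTransform, needle_T_tip: RigidTransform
) -> np.ndarray:
    """Tip position in world coordinates: translation of world<-needle<-tip."""
    return compose(world_T_needle, needle_T_tip).translation


# ---------------------------------------------------------------------------
# pose-log I/O: CSV with header timestamp,tool_id,qw,qx,qy,qz,tx,ty,tz
# (JSON-lines with the same keys is accepted too)

_POSE_COLUMNS = ["timestamp", "tool_id", "qw", "qx", "qy", "qz", "tx", "ty", "tz"]


def read_pose_log(path) -> list[PoseSample]:
    path = str(path)
    if path.endswith((".jsonl", ".ndjson", ".json")):
        df = pd.read_json(path, lines=True)
    else:
        df = pd.read_csv(path)
    missing = set(_POSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pose log is missing columns: {sorted(missing)}")
    return [
        PoseSample(
            timestamp=float(r.timestamp),
            tool_id=str(r.tool_id),
            quaternion=(float(r.qw), float(r.qx), float(r.qy), float(r.qz)),
            translation=(float(r.tx), float(r.ty), float(r.tz)),
        )
        for r in df.itertuples(index=False)
    ]


def write_pose_log(samples: Iterable[PoseSample], path) -> None:
    rows = [
        (s.timestamp, s.tool_id, *s.quaternion, *s.translation) for s in samples
    ]
    pd.DataFrame(rows, columns=_POSE_COLUMNS).to_csv(path, index=False)
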