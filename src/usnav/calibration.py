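"""Probe (image-to-tool) and pivot (tip) calibration.

Probe calibration determines the pixel spacing and the rigid transform
``sono_T_image`` that maps metric image-plane coordinates into the frame of
the tracking tool mounted on the probe, from fiducials of known world
position imaged at known probe poses.  Pivot calibration determines the
needle tip's fixed offset in the needle-tool frame by rotating the tool about
the stationary tip.

Both are classic point-based least-squares problems; the solvers here are
closed-form (distance-ratio scale estimate + Kabsch for the probe, one linear
system for the pivot) and recover noiseless synthetic inputs to machine
precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .transforms import (
    PixelPoint,
    PoseSample,
    RigidTransform,
    from_rotation_translation,
    invert,
    nearest_rotation,
    pose_to_transform,
)

__all__ = [
    "ProbeCalibration",
    "TipCalibration",
    "DegenerateGeometryError",
    "calibrate_probe",
    "pivot_calibrate_needle",
    "calibration_report",
    "read_fiducial_observations",
]

_PIVOT_MIN_SINGULAR_VALUE = 1e-6


class DegenerateGeometryError(ValueError):
    """Calibration geometry does not determine the parameters."""


@dataclass(frozen=True)
class ProbeCalibration:
    """Result of probe calibration.

    Attributes
    ----------
    spacing
        (mm/px lateral, mm/px axial).
    sono_T_image
        Rigid map from the metric image plane into the probe-tool frame.
    residual_rms
        Fiducial registration error: RMS distance (mm) between mapped pixel
        fiducials and their tool-frame positions.
    """

    spacing: tuple[float, float]
    sono_T_image: RigidTransform
    residual_rms: float

    def __post_init__(self) -> None:
        if min(self.spacing) <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be >= 0")


@dataclass(frozen=True)
class TipCalibration:
    """Needle-tip offset (mm, needle-tool frame) with pivot-fit RMS residual."""

    tip_offset: tuple[float, float, float]
    residual_rms: float

    def __post_init__(self) -> None:
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be >= 0")

    @property
    def needle_T_tip(self) -> RigidTransform:
        return from_rotation_translation(
            np.eye(3), self.tip_offset, parent="needle", child="tip"
        )


def calibrate_probe(
    observations: Sequence[tuple[PixelPoint | Sequence[float], Sequence[float], RigidTransform]],
) -> ProbeCalibration:
    """Solve for pixel spacing and ``sono_T_image`` from fiducial captures.

    Each observation is ``(pixel, world_point, world_T_sono)``: a fiducial of
    known world position seen at a known pixel while the probe tool was at the
    given pose.  World fiducials are first mapped into the tool ("sono") frame;
    the anisotropic pixel scales are then estimated from pairwise distances
    (a rigid map preserves them, so ``|d_ij|^2 = sx^2 dcol^2 + sy^2 drow^2``),
    and the remaining rigid transform is a standard absolute-orientation
    (Kabsch) fit between the scaled pixel points and the tool-frame points.

    Raises
    ------
    DegenerateGeometryError
        Fewer than 3 fiducials, collinear pixels, or a configuration that
        leaves a spacing or the rotation unobservable.
    """
    if len(observations) < 3:
        raise DegenerateGeometryError(
            f"probe calibration needs >= 3 fiducials, got {len(observations)}"
        )
    px = np.array(
        [[float(o[0][0]), float(o[0][1])] for o in observations]
    )  # (n, 2) col,row
    sono = np.array(
        [invert(o[2]).apply(np.asarray(o[1], dtype=float)) for o in observations]
    )  # (n, 3)

    # collinearity check on pixel coordinates
    centered = px - px.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8 * max(1.0, np.abs(px).max())) < 2:
        raise DegenerateGeometryError("fiducial pixels are collinear")

    # pairwise squared distances: linear system for (sx^2, sy^2)
    i, j = np.triu_indices(len(px), k=1)
    dpix = px[i] - px[j]
    A = dpix**2  # columns: dcol^2, drow^2
    b = np.sum((sono[i] - sono[j]) ** 2, axis=1)
    scales_sq, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.any(scales_sq <= 0):
        raise DegenerateGeometryError(
            "pixel spacing unobservable (no spread along one image axis)"
        )
    spacing = tuple(np.sqrt(scales_sq))

    # Kabsch between scaled planar pixel points and tool-frame points
    img = np.column_stack([px * spacing, np.zeros(len(px))])
    img_c = img - img.mean(axis=0)
    sono_c = sono - sono.mean(axis=0)
    H = img_c.T @ sono_c
    U, S, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    R = nearest_rotation(R)
    t = sono.mean(axis=0) - R @ img.mean(axis=0)

    residuals = sono - (img @ R.T + t)
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return ProbeCalibration(
        spacing=(float(spacing[0]), float(spacing[1])),
        sono_T_image=from_rotation_translation(R, t, parent="sono", child="image"),
        residual_rms=rms,
    )


def pivot_calibrate_needle(
    poses: Sequence[RigidTransform],
) -> tuple[TipCalibration, np.ndarray]:
    """Pivot calibration: tip offset in the tool frame plus the world pivot.

    With the tip held stationary at the unknown world point ``w`` while the
    tool rotates, every pose satisfies ``R_i p + t_i = w``; stacking gives the
    linear system ``[R_i  -I] [p; w] = -t_i`` solved by least squares.

    Returns
    -------
    (TipCalibration, pivot_point)
        The tool-frame tip offset with its RMS residual, and the estimated
        stationary world point.
    """
    if len(poses) < 3:
        raise DegenerateGeometryError(
            f"pivot calibration needs >= 3 poses, got {len(poses)}"
        )
    n = len(poses)
    A = np.zeros((3 * n, 6))
    b = np.zeros(3 * n)
    for k, T in enumerate(poses):
        A[3 * k : 3 * k + 3, :3] = T.rotation
        A[3 * k : 3 * k + 3, 3:] = -np.eye(3)
        b[3 * k : 3 * k + 3] = -T.translation
    smin = np.linalg.svd(A, compute_uv=False)[-1]
    if smin < _PIVOT_MIN_SINGULAR_VALUE:
        raise DegenerateGeometryError(
            "rotation diversity insufficient: pivot is unobservable "
            f"(smallest singular value {smin:.2e})"
        )
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    p, w = x[:3], x[3:]
    res = np.array([T.rotation @ p + T.translation - w for T in poses])
    rms = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    return TipCalibration(tip_offset=tuple(p), residual_rms=rms), w


def calibration_report(cal: ProbeCalibration | TipCalibration) -> dict:
    """JSON-serializable summary of a calibration result."""
    if isinstance(cal, ProbeCalibration):
        return {
            "kind": "probe",
            "spacing_mm_per_px": list(cal.spacing),
            "sono_T_image": {
                "rotation": cal.sono_T_image.rotation.tolist(),
                "translation_mm": cal.sono_T_image.translation.tolist(),
            },
            "residual_rms_mm": cal.residual_rms,
        }
    if isinstance(cal, TipCalibration):
        return {
            "kind": "tip",
            "tip_offset_mm": list(cal.tip_offset),
            "residual_rms_mm": cal.residual_rms,
        }
    raise TypeError(f"not a calibration result: {type(cal).__name__}")


def read_fiducial_observations(path):
    """Read fiducial captures from CSV.

    Columns: ``col,row,wx,wy,wz,qw,qx,qy,qz,tx,ty,tz`` — pixel, world fiducial,
    and the probe-tool pose (quaternion wxyz + translation) at capture.
    """
    df = pd.read_csv(path)
    obs = []
    for r in df.itertuples(index=False):
        pose = PoseSample(
            timestamp=0.0,
            tool_id="probe",
            quaternion=(r.qw, r.qx, r.qy, r.qz),
            translation=(r.tx, r.ty, r.tz),
        )
        obs.append(
            (
                PixelPoint(float(r.col), float(r.row)),
                np.array([r.wx, r.wy, r.wz], dtype=float),
                pose_to_transform(pose, parent="world", child="sono"),
            )
        )
    return obs
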