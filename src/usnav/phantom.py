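"""Synthetic evaluation phantom, tracking noise and B-mode-like rendering.

Emulates the physical accuracy-evaluation setup: a hollow sphere of 16 mm
inner diameter containing an 8 mm spherical hypoechoic target, with two
surface notch markers 19 mm apart on a line through the centre.  Tracked
poses carry isotropic Gaussian translation noise (0.25 mm per axis by
default, the quoted intrinsic error of the optical tracker), and rendered
frames carry multiplicative log-normal speckle.  Every stochastic operation
is reproducible from its seed.

The renderer is geometric, not physical: a pixel is lesion-dark when its
world point (via the calibrated pixel -> image -> sono -> world chain) lies
inside the target sphere, and background otherwise.  No shell wall, beam
profile, attenuation or shadowing is modelled — the pipeline under test only
consumes lesion/background contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .calibration import ProbeCalibration
from .navigation import register_target
from .segmentation import DetectionParams, detect_lesion
from .transforms import (
    PixelPoint,
    PoseSample,
    RigidTransform,
    compose,
    from_rotation_translation,
    invert,
)

__all__ = [
    "PhantomScene",
    "NoiseModel",
    "TrialRecord",
    "build_eval_phantom",
    "simulate_pose_stream",
    "render_bmode",
    "simulate_trial",
]

#: Evaluation-phantom geometry (mm): hollow-sphere inner radius, target radius,
#: notch-marker separation.
SHELL_INNER_RADIUS_MM = 8.0
TARGET_RADIUS_MM = 4.0
MARKER_SEPARATION_MM = 19.0

#: Quoted intrinsic error of the optical tracking system (mm, per axis).
TRACKER_SIGMA_MM = 0.25


@dataclass(frozen=True)
class PhantomScene:
    """Evaluation-phantom geometry in world coordinates (mm).

    The hollow sphere and the target are concentric; the two notch markers sit
    on the surface line through the centre, 19 mm apart, and their midpoint
    defines the ground-truth reference.
    """

    shell_center: np.ndarray
    shell_inner_radius: float
    rf_center: np.ndarray
    rf_radius: float
    marker_a: np.ndarray
    marker_b: np.ndarray
    lesion_contrast: float = 0.1
    background_level: float = 0.6

    def __post_init__(self) -> None:
        for name in ("shell_center", "rf_center", "marker_a", "marker_b"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        sep = np.linalg.norm(self.marker_a - self.marker_b)
        if abs(sep - MARKER_SEPARATION_MM) > 1e-9:
            raise ValueError(f"marker separation {sep} != {MARKER_SEPARATION_MM} mm")
        mid = 0.5 * (self.marker_a + self.marker_b)
        if np.linalg.norm(mid - self.shell_center) > 1e-9:
            raise ValueError("marker midpoint must coincide with the shell centre")
        if not self.rf_radius < self.shell_inner_radius:
            raise ValueError("target must fit inside the hollow sphere")


@dataclass(frozen=True)
class NoiseModel:
    """Noise settings: tracking translation sigma (mm/axis), rotational sigma
    (rad/axis, off by default), speckle sigma (log-normal, unit mean)."""

    tracking_sigma: float = TRACKER_SIGMA_MM
    rotation_sigma: float = 0.0
    speckle_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tracking_sigma < 0 or self.rotation_sigma < 0 or self.speckle_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class TrialRecord:
    """One simulated accuracy trial: measured world target vs ground truth."""

    trial_id: int
    measured: np.ndarray
    ground_truth: np.ndarray
    deviation: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "measured", np.asarray(self.measured, float))
        object.__setattr__(self, "ground_truth", np.asarray(self.ground_truth, float))


def build_eval_phantom(
    center,
    axis=(0.0, 1.0, 0.0),
    shell_inner_radius: float = SHELL_INNER_RADIUS_MM,
    rf_radius: float = TARGET_RADIUS_MM,
    lesion_contrast: float = 0.1,
    background_level: float = 0.6,
) -> PhantomScene:
    """Construct the evaluation phantom at ``center`` with markers along ``axis``.

    The notch markers are placed at ``center +- 9.5 mm`` along the (unit)
    marker axis so their separation is 19 mm and their midpoint is the centre.
    """
    center = np.asarray(center, dtype=float)
    axis = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
        raise ValueError("marker axis must be a unit vector")
    half = MARKER_SEPARATION_MM / 2.0
    return PhantomScene(
        shell_center=center,
        shell_inner_radius=shell_inner_radius,
        rf_center=center,
        rf_radius=rf_radius,
        marker_a=center + half * axis,
        marker_b=center - half * axis,
        lesion_contrast=lesion_contrast,
        background_level=background_level,
    )


def _perturb_pose(
    T: RigidTransform, noise: NoiseModel, rng: np.random.Generator
) -> RigidTransform:
    t = T.translation + rng.normal(0.0, noise.tracking_sigma, size=3)
    R = T.rotation
    if noise.rotation_sigma > 0:
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec(rng.normal(0, noise.rotation_sigma, 3)).as_matrix() @ R
    return from_rotation_translation(R, t, T.parent_frame, T.child_frame)


def simulate_pose_stream(
    trajectory: Callable[[float], RigidTransform],
    duration: float,
    rate: float,
    noise: NoiseModel = NoiseModel(),
    tool_id: str = "needle",
) -> list[PoseSample]:
    """Sample a pose trajectory at ``rate`` Hz with tracking noise.

    ``trajectory(t)`` returns the true world<-tool pose at time ``t``;
    translations are perturbed by independent zero-mean Gaussians with
    ``noise.tracking_sigma`` per axis.  Deterministic given ``noise.seed``.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if rate <= 0:
        raise ValueError("rate must be positive")
    from scipy.spatial.transform import Rotation

    rng = noise.rng()
    n = int(round(duration * rate))
    samples = []
    for k in range(n):
        t = k / rate
        T = _perturb_pose(trajectory(t), noise, rng)
        x, y, z, w = Rotation.from_matrix(T.rotation).as_quat()
        samples.append(
            PoseSample(
                timestamp=t,
                tool_id=tool_id,
                quaternion=(w, x, y, z),
                translation=tuple(T.translation),
            )
        )
    return samples


def render_bmode(
    scene: PhantomScene,
    world_T_sono: RigidTransform,
    cal: ProbeCalibration,
    image_shape: tuple[int, int] = (128, 128),
    noise: NoiseModel = NoiseModel(),
) -> tuple[np.ndarray, PixelPoint | None]:
    """Render a B-mode-like frame of the scene and its analytic ground truth.

    Every pixel is embedded into the metric image plane and mapped to world
    coordinates through ``world_T_sono o sono_T_image``; pixels inside the
    target sphere get the lesion intensity, the rest the background level,
    then unit-mean log-normal speckle multiplies the frame.

    Returns
    -------
    (image, ground_truth)
        The frame in [0, 1] and the analytic pixel projection of the in-plane
        disc centre, or ``None`` when the image plane misses the target.
    """
    rows, cols = image_shape
    sx, sy = cal.spacing
    world_T_image = compose(world_T_sono, cal.sono_T_image)

    cc, rr = np.meshgrid(np.arange(cols), np.arange(rows))
    pts_image = np.stack(
        [cc.ravel() * sx, rr.ravel() * sy, np.zeros(rows * cols)], axis=1
    )
    pts_world = world_T_image.apply(pts_image)
    inside = np.sum((pts_world - scene.rf_center) ** 2, axis=1) <= scene.rf_radius**2
    img = np.full(rows * cols, scene.background_level)
    img[inside] = scene.lesion_contrast
    img = img.reshape(rows, cols)

    if noise.speckle_sigma > 0:
        rng = noise.rng()
        sigma = noise.speckle_sigma
        speckle = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=img.shape)
        img = img * speckle
    img = np.clip(img, 0.0, 1.0)

    # analytic centre: target centre in image-plane coordinates; the in-plane
    # disc centre is its orthogonal projection onto z = 0
    c_img = invert(world_T_image).apply(scene.rf_center)
    if abs(c_img[2]) >= scene.rf_radius:
        return img, None
    return img, PixelPoint(col=float(c_img[0] / sx), row=float(c_img[1] / sy))


def simulate_trial(
    scene: PhantomScene,
    world_T_sono: RigidTransform,
    cal: ProbeCalibration,
    noise: NoiseModel = NoiseModel(),
    trial_id: int = 0,
    image_shape: tuple[int, int] = (128, 128),
    detection_params: DetectionParams = DetectionParams(),
) -> TrialRecord:
    """One accuracy trial: render -> segment -> register on a noisy pose.

    The frame is rendered from the *true* probe pose (the physics), while the
    registration uses a noise-perturbed copy of that pose (the tracker
    measurement); the deviation is the Euclidean distance from the registered
    centre to the scene's true target centre.

    Raises
    ------
    ValueError
        When the probe plane does not intersect the target.
    """
    _, truth = render_bmode(scene, world_T_sono, cal, image_shape, noise=NoiseModel(
        tracking_sigma=0, speckle_sigma=0))
    if truth is None:
        raise ValueError("probe image plane does not intersect the target")
    rng = noise.rng()
    speckle_noise = NoiseModel(
        tracking_sigma=0.0,
        speckle_sigma=noise.speckle_sigma,
        seed=int(rng.integers(2**31 - 1)),
    )
    img, _ = render_bmode(scene, world_T_sono, cal, image_shape, noise=speckle_noise)
    seg = detect_lesion(img, detection_params)
    measured_pose = _perturb_pose(world_T_sono, noise, rng)
    target = register_target(seg, cal, measured_pose)
    deviation = float(np.linalg.norm(target.m - scene.rf_center))
    return TrialRecord(
        trial_id=trial_id,
        measured=target.m,
        ground_truth=scene.rf_center,
        deviation=deviation,
    )
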