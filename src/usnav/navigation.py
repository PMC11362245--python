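"""Target registration and acoustic needle guidance.

Two workflows mirror the intraoperative use of a tracked freehand probe:

1. **Target marking** — on button press, the lesion centre found in the 2-D
   frame is mapped through the calibrated chain
   ``world <- sono <- image`` into world coordinates and stored as a sphere
   (centre ``m``, radius ``r``).
2. **Navigation** — at every tracker update the extended needle line is
   classified against that sphere into three tiers, each tied to a fixed
   audio frequency, so the operator can aim by ear without looking away from
   the patient:

   ========  =========================================  =========
   return    geometry                                   tone
   ========  =========================================  =========
   2         line hits the sphere (distance <= r)       440 Hz
   1         near miss (r < distance <= near_factor*r)  350 Hz
   0         miss, or target behind the tip             200 Hz
   ========  =========================================  =========

The hit test is the line-sphere membership condition
``(x - m_x)^2 + (y - m_y)^2 + (z - m_z)^2 = r^2`` evaluated via the
perpendicular distance from the needle line to ``m``; ray semantics apply
(an intersection behind the tip is a miss, because pointing away from the
patient cannot be a hit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calibration import ProbeCalibration, TipCalibration
from .segmentation import DetectionParams, SegmentationResult, detect_lesion
from .transforms import (
    PoseSample,
    RigidTransform,
    compose,
    pixel_to_image_mm,
    pose_to_transform,
    transform_point,
)

__all__ = [
    "TargetSphere",
    "NeedleLine",
    "AlignmentResult",
    "ToneEvent",
    "TargetBehindTipError",
    "TONE_FREQUENCIES",
    "register_target",
    "classify_alignment",
    "insertion_depth",
    "tone_for",
    "needle_line_from_pose",
    "run_session",
    "render_tone_wav",
]

#: Fixed tier-to-frequency mapping (Hz): miss, near, hit.
TONE_FREQUENCIES = {0: 200.0, 1: 350.0, 2: 440.0}

DEFAULT_UPDATE_RATE_HZ = 20.0

#: Needle shaft direction in the needle-tool frame (unit vector).
DEFAULT_SHAFT_AXIS = (0.0, 0.0, 1.0)


class TargetBehindTipError(ValueError):
    """The target lies behind the needle tip; no insertion depth exists."""


@dataclass(frozen=True)
class TargetSphere:
    """Registered lesion: world-frame centre ``m`` (mm) and radius ``r`` (mm)."""

    m: np.ndarray
    r: float

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.shape != (3,) or not np.all(np.isfinite(m)):
            raise ValueError("centre m must be a finite 3-vector")
        if not self.r > 0:
            raise ValueError(f"radius must be positive, got {self.r}")
        object.__setattr__(self, "m", m)

    def contains(self, p: Sequence[float]) -> bool:
        return float(np.sum((np.asarray(p, float) - self.m) ** 2)) <= self.r**2

    def to_json_dict(self) -> dict:
        return {"m": self.m.tolist(), "r": float(self.r)}


@dataclass(frozen=True)
class NeedleLine:
    """Tracked needle: tip position (mm, world) and unit shaft direction."""

    tip: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        tip = np.asarray(self.tip, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            raise ValueError("needle direction must be non-zero")
        if abs(norm - 1.0) > 1e-9:
            d = d / norm
        object.__setattr__(self, "tip", tip)
        object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class AlignmentResult:
    """Three-tier alignment classification of the needle line vs the target.

    ``line_distance`` is the perpendicular distance (mm) from the extended
    needle line to the sphere centre; ``depth`` is the along-axis distance
    from the tip to the closest approach to the centre (None when the target
    is behind the tip); ``surface_distance`` is the distance to the proximal
    sphere surface along the shaft, defined only for a hit (tier 2).
    """

    return_value: int
    line_distance: float
    depth: float | None
    forward: bool
    surface_distance: float | None = None


@dataclass(frozen=True)
class ToneEvent:
    timestamp: float
    frequency: float
    return_value: int
    changed: bool = False

    def __post_init__(self) -> None:
        if TONE_FREQUENCIES[self.return_value] != self.frequency:
            raise ValueError(
                f"frequency {self.frequency} does not match tier {self.return_value}"
            )


def register_target(
    image: np.ndarray | SegmentationResult,
    cal: ProbeCalibration,
    world_T_sono: RigidTransform,
    detection_params: DetectionParams = DetectionParams(),
) -> TargetSphere:
    """Map the lesion seen in one frame into a world-frame sphere.

    The centre is the segmentation centroid pushed through
    ``world_T_image = world_T_sono o sono_T_image`` after metric embedding of
    the pixel; the radius is half the circle-equivalent diameter scaled by the
    mean pixel spacing (the sphere model ignores in-plane anisotropy beyond
    that).

    ``image`` may be a raw frame (segmented here) or an already computed
    :class:`~usnav.segmentation.SegmentationResult`, e.g. from an external
    network mask.
    """
    seg = (
        image
        if isinstance(image, SegmentationResult)
        else detect_lesion(image, detection_params)
    )
    world_T_image = compose(world_T_sono, cal.sono_T_image)
    m = transform_point(world_T_image, pixel_to_image_mm(cal.spacing, seg.centroid))
    r = seg.equivalent_diameter_px * float(np.mean(cal.spacing)) / 2.0
    return TargetSphere(m=m, r=r)


def classify_alignment(
    line: NeedleLine, target: TargetSphere, near_factor: float = 2.0
) -> AlignmentResult:
    """Classify needle alignment into miss (0) / near (1) / hit (2).

    A hit requires the extended line to pass within the sphere radius of the
    centre *and* the target to lie ahead of the tip; the near band extends to
    ``near_factor * r`` (boundaries inclusive).
    """
    if not near_factor > 1:
        raise ValueError(f"near_factor must exceed 1, got {near_factor}")
    to_center = target.m - line.tip
    along = float(to_center @ line.direction)
    perp = to_center - along * line.direction
    line_distance = float(np.linalg.norm(perp))
    forward = along > 0

    if forward and line_distance <= target.r:
        rv = 2
    elif forward and line_distance <= near_factor * target.r:
        rv = 1
    else:
        rv = 0

    surface = None
    if rv == 2:
        surface = along - float(np.sqrt(target.r**2 - line_distance**2))
    return AlignmentResult(
        return_value=rv,
        line_distance=line_distance,
        depth=along if forward else None,
        forward=forward,
        surface_distance=surface,
    )


def insertion_depth(line: NeedleLine, target: TargetSphere) -> tuple[float, float | None]:
    """Insertion depth (mm) announced at the start of navigation.

    Returns ``(depth, surface_distance)``: the along-shaft distance from the
    tip to the closest approach to the sphere centre, and — when the line
    actually intersects the sphere — the distance to the proximal surface
    (the entry depth), from the line-sphere quadratic.

    Raises
    ------
    TargetBehindTipError
        When the target centre lies behind the tip.
    """
    res = classify_alignment(line, target)
    if not res.forward:
        raise TargetBehindTipError("target lies behind the needle tip")
    return float(res.depth), res.surface_distance


def tone_for(return_value: int) -> float:
    """Audio frequency (Hz) for an alignment tier: 0->200, 1->350, 2->440."""
    try:
        return TONE_FREQUENCIES[return_value]
    except KeyError:
        raise ValueError(f"return value must be 0, 1 or 2, got {return_value}") from None


def needle_line_from_pose(
    world_T_needle: RigidTransform,
    tip_cal: TipCalibration,
    shaft_axis: Sequence[float] = DEFAULT_SHAFT_AXIS,
) -> NeedleLine:
    """Build the world-frame needle line from a tracked pose and tip offset."""
    tip = world_T_needle.apply(np.asarray(tip_cal.tip_offset, dtype=float))
    direction = world_T_needle.rotation @ np.asarray(shaft_axis, dtype=float)
    return NeedleLine(tip=tip, direction=direction)


def run_session(
    pose_stream: Sequence[PoseSample],
    tip_cal: TipCalibration,
    target: TargetSphere,
    rate: float = DEFAULT_UPDATE_RATE_HZ,
    near_factor: float = 2.0,
    shaft_axis: Sequence[float] = DEFAULT_SHAFT_AXIS,
) -> list[tuple[float, AlignmentResult, ToneEvent]]:
    """Replay a needle pose stream at a fixed feedback rate.

    The stream is evaluated at ticks ``t0 + k / rate`` from the first to the
    last timestamp, using the most recent pose at or before each tick — the
    discrete analogue of a guidance loop recomputing feedback at every tracker
    update.  A tone event is emitted on every tick (continuous feedback); its
    ``changed`` flag marks tier transitions.

    Raises
    ------
    ValueError
        On an unsorted stream or non-positive rate.
    """
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    if not pose_stream:
        return []
    times = np.array([s.timestamp for s in pose_stream])
    if np.any(np.diff(times) < 0):
        raise ValueError("pose stream must be sorted by timestamp")

    t0, t_end = times[0], times[-1]
    n_ticks = int(np.floor((t_end - t0) * rate + 1e-9)) + 1
    log: list[tuple[float, AlignmentResult, ToneEvent]] = []
    prev_rv: int | None = None
    for k in range(n_ticks):
        tick = t0 + k / rate
        idx = int(np.searchsorted(times, tick + 1e-12, side="right")) - 1
        sample = pose_stream[idx]
        world_T_needle = pose_to_transform(sample, parent="world", child="needle")
        line = needle_line_from_pose(world_T_needle, tip_cal, shaft_axis)
        res = classify_alignment(line, target, near_factor=near_factor)
        tone = ToneEvent(
            timestamp=float(tick),
            frequency=tone_for(res.return_value),
            return_value=res.return_value,
            changed=prev_rv is not None and res.return_value != prev_rv,
        )
        prev_rv = res.return_value
        log.append((float(tick), res, tone))
    return log


def render_tone_wav(
    events: Sequence[ToneEvent], path, sample_rate: int = 44100, amplitude: float = 0.4
) -> None:
    """Render a tone-event sequence to a mono 16-bit WAV file (convenience).

    Each event sounds until the next one (the last gets the median interval).
    """
    import wave

    if not events:
        raise ValueError("no tone events to render")
    times = np.array([e.timestamp for e in events])
    durations = np.diff(times)
    default = float(np.median(durations)) if len(durations) else 0.05
    durations = np.append(durations, default)
    chunks = []
    for event, dur in zip(events, durations):
        n = max(1, int(round(dur * sample_rate)))
        t = np.arange(n) / sample_rate
        chunks.append(amplitude * np.sin(2 * np.pi * event.frequency * t))
    signal = np.concatenate(chunks)
    pcm = (np.clip(signal, -1, 1) * 32767).astype("<i2")
    with wave.open(str(path), "wb") as fh:
        fh.setnchannels(1)
        fh.setsampwidth(2)
        fh.setframerate(sample_rate)
        fh.writeframes(pcm.tobytes())
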