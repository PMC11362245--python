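"""Surgical-accuracy analysis of navigation trials on the evaluation phantom.

Given the two needle-probed notch markers (whose midpoint defines the "true"
reference centre) and a table of registered world-frame target positions,
this module computes per-trial Euclidean deviations, the mean measured
position E, the surgical deviation of E from the reference, and the hit
count (trials whose measured point lies inside the target sphere), and
exports a "globe model" — the 3-D scene of hollow sphere, target, reference
and measured points — for plotting.

Rounding convention
-------------------
Printed coordinates carry 2 decimals and E carries 1; to reproduce the
original analysis arithmetically the reference centre is rounded to the
printed 2 decimals before deviations are taken, and the surgical deviation
is the distance from the *1-decimal-rounded* E to the reference.  Rounding
is half-away-from-zero.  Unrounded variants are available via the
``decimals`` / ``unrounded`` switches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EvalTrial",
    "EvaluationReport",
    "round_half_away",
    "reference_center",
    "deviation",
    "mean_position",
    "max_surgical_deviation",
    "hit_count",
    "evaluate_table",
    "load_eval_trials",
    "load_eval_markers",
    "globe_model",
    "plot_globe",
]


def round_half_away(x, decimals: int):
    """Round half-away-from-zero (the convention of printed tables).

    Operates on scalars or arrays; exact on values that are short decimal
    fractions (e.g. tracker output printed with 2 decimals).
    """
    q = Decimal(1).scaleb(-decimals)

    def _one(v: float) -> float:
        return float(Decimal(str(round(float(v), 12))).quantize(q, ROUND_HALF_UP))

    arr = np.asarray(x, dtype=float)
    out = np.vectorize(_one)(arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


@dataclass
class EvalTrial:
    """One accuracy trial: the registered target position in world mm."""

    trial_id: int
    measured: np.ndarray
    deviation: float | None = None

    def __post_init__(self) -> None:
        self.measured = np.asarray(self.measured, dtype=float)
        if self.measured.shape != (3,):
            raise ValueError("measured position must be a 3-vector")


@dataclass
class EvaluationReport:
    """Aggregate accuracy report for a set of trials."""

    reference: np.ndarray
    trials: list[EvalTrial]
    mean_position: np.ndarray
    max_surgical_deviation: float
    hit_count: int
    hit_radius: float
    shell_inner_radius: float = 8.0
    marker_a: np.ndarray | None = None
    marker_b: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "reference": np.asarray(self.reference).tolist(),
            "mean_position": np.asarray(self.mean_position).tolist(),
            "max_surgical_deviation_mm": self.max_surgical_deviation,
            "hit_count": self.hit_count,
            "n_trials": len(self.trials),
            "hit_radius_mm": self.hit_radius,
            "trials": [
                {
                    "trial_id": t.trial_id,
                    "measured": t.measured.tolist(),
                    "deviation_mm": t.deviation,
                }
                for t in self.trials
            ],
            **self.extras,
        }


def reference_center(marker_a, marker_b) -> np.ndarray:
    """Midpoint of the two needle-probed notch markers: the "true" centre."""
    a = np.asarray(marker_a, dtype=float)
    b = np.asarray(marker_b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("marker positions must be finite")
    return 0.5 * (a + b)


def deviation(p, ref) -> float:
    """Euclidean distance (mm) between a measured point and the reference."""
    return float(np.linalg.norm(np.asarray(p, float) - np.asarray(ref, float)))


def mean_position(points: Sequence, decimals: int | None = 1) -> np.ndarray:
    """Component-wise mean position E, rounded half-away-from-zero.

    ``decimals=None`` returns the unrounded mean.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("mean_position of an empty point list")
    mean = pts.reshape(-1, 3).mean(axis=0)
    return mean if decimals is None else round_half_away(mean, decimals)


def max_surgical_deviation(points: Sequence, ref, unrounded: bool = False) -> float:
    """Surgical deviation (mm): distance from the mean position E to the reference.

    By default E is first rounded to 1 decimal — the arithmetic path of the
    printed analysis; ``unrounded=True`` uses the exact mean instead.
    """
    E = mean_position(points, decimals=None if unrounded else 1)
    return deviation(E, ref)


def hit_count(points: Sequence, ref, radius: float) -> int:
    """Number of measured points within ``radius`` of the reference.

    ``radius`` is the target-sphere radius: a count of trials whose measured
    centre lies inside the target (4 mm for the 8 mm evaluation target).
    """
    if not radius > 0:
        raise ValueError(f"radius must be positive, got {radius}")
    return int(sum(deviation(p, ref) <= radius for p in np.asarray(points, float).reshape(-1, 3)))


def evaluate_table(
    trials: Sequence[EvalTrial],
    marker_a,
    marker_b,
    hit_radius: float = 4.0,
    shell_inner_radius: float = 8.0,
    reference_decimals: int | None = 2,
    unrounded: bool = False,
) -> EvaluationReport:
    """Full accuracy analysis of a trial table.

    Computes the reference centre from the markers (rounded to
    ``reference_decimals``, the precision at which tracker coordinates are
    reported; ``None`` keeps the exact midpoint), fills every trial's
    Euclidean deviation, and aggregates E, the surgical deviation and the hit
    count.
    """
    if len(trials) == 0:
        raise ValueError("no trials to evaluate")
    ref = reference_center(marker_a, marker_b)
    if reference_decimals is not None:
        ref = round_half_away(ref, reference_decimals)
    pts = np.array([t.measured for t in trials])
    filled = [
        EvalTrial(t.trial_id, t.measured, deviation(t.measured, ref)) for t in trials
    ]
    return EvaluationReport(
        reference=ref,
        trials=filled,
        mean_position=mean_position(pts, decimals=None if unrounded else 1),
        max_surgical_deviation=round(
            max_surgical_deviation(pts, ref, unrounded=unrounded), 4
        ),
        hit_count=hit_count(pts, ref, hit_radius),
        hit_radius=hit_radius,
        shell_inner_radius=shell_inner_radius,
        marker_a=np.asarray(marker_a, float),
        marker_b=np.asarray(marker_b, float),
    )


# ---------------------------------------------------------------------------
# packaged evaluation-phantom data (ten navigated trials + probed markers)


def load_eval_trials() -> pd.DataFrame:
    """The packaged ten-trial accuracy table (world mm + reported deviation)."""
    with resources.files("usnav.data").joinpath("eval_trials.csv").open() as fh:
        return pd.read_csv(fh)


def load_eval_markers() -> dict:
    """The packaged needle-probed marker positions and phantom geometry."""
    with resources.files("usnav.data").joinpath("eval_markers.json").open() as fh:
        return json.load(fh)


def trials_from_dataframe(df: pd.DataFrame) -> list[EvalTrial]:
    return [
        EvalTrial(int(r.trial_id), np.array([r.x, r.y, r.z]))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# globe model: 3-D scene export / plot


def globe_model(report: EvaluationReport) -> dict:
    """JSON scene: hollow sphere, target sphere, reference and measured points."""
    return {
        "hollow_sphere": {
            "center": np.asarray(report.reference).tolist(),
            "radius_mm": report.shell_inner_radius,
        },
        "target": {
            "center": np.asarray(report.reference).tolist(),
            "radius_mm": report.hit_radius,
        },
        "reference_point": np.asarray(report.reference).tolist(),
        "mean_position": np.asarray(report.mean_position).tolist(),
        "measured_points": [t.measured.tolist() for t in report.trials],
    }


def plot_globe(report: EvaluationReport, path) -> None:
    """Render the globe model to a PNG (matplotlib 3-D scatter + wire spheres)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="3d")
    u, v = np.meshgrid(np.linspace(0, 2 * np.pi, 24), np.linspace(0, np.pi, 12))
    ref = np.asarray(report.reference)
    for radius, color, alpha in (
        (report.shell_inner_radius, "green", 0.15),
        (report.hit_radius, "peru", 0.25),
    ):
        ax.plot_wireframe(
            ref[0] + radius * np.cos(u) * np.sin(v),
            ref[1] + radius * np.sin(u) * np.sin(v),
            ref[2] + radius * np.cos(v),
            color=color,
            alpha=alpha,
            linewidth=0.5,
        )
    pts = np.array([t.measured for t in report.trials])
    ax.scatter(*pts.T, color="tab:blue", s=25, label="measured")
    ax.scatter(*ref, color="red", s=60, marker="x", label="reference")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_zlabel("z (mm)")
    ax.legend(loc="upper left")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
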