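"""Per-cross-peak titration trajectories and direction-change detection.

In the fast-exchange regime a cross-peak sits at the population-weighted
average of the free and bound positions, so a single binding mode moves the
peak along a straight line as metal is added.  A change of direction along
the titration path is therefore evidence for a second binding mode with a
different bound-state shift vector.

Geometry is computed in the same weighted plane as the CSP metric: for an
HSQC series the 13C coordinate is multiplied by sqrt(alpha) so squared
distances carry the conventional alpha weighting; TOCSY coordinates are
unweighted.  The detector measures the turning angle between successive
displacement vectors, merging sub-threshold (noise-level) steps into the
following step, and reports the titration ratio at the vertex of the first
turn exceeding the angular threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_io import Assignment, SpectrumType, TitrationSeries, ValidationError
from .csp import DEFAULT_ALPHA

DEFAULT_TURN_THRESHOLD_DEG = 30.0
DEFAULT_MIN_STEP_PPM = 0.005  # 1H-equivalent ppm after axis weighting


@dataclass(frozen=True)
class Trajectory:
    """Ordered positions of one cross-peak across the titration.

    ``axis_weights`` are the coordinate multipliers applied to (F1, F2)
    before any geometry: (sqrt(alpha), 1) for an HSQC series (F1 = 13C),
    (1, 1) for TOCSY.  ``gap_ratios`` lists titration points at which the
    peak was not visible (excluded from ``points``).
    """

    assignment: Assignment
    points: tuple[tuple[float, float, float], ...]  # (ratio, f1_ppm, f2_ppm)
    axis_weights: tuple[float, float] = (1.0, 1.0)
    gap_ratios: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        ratios = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(ratios, ratios[1:])):
            raise ValidationError("trajectory ratios must be strictly increasing")
        if len(self.points) < 3:
            raise ValidationError(
                f"insufficient points for curvature analysis: {len(self.points)} < 3"
            )

    @property
    def has_gaps(self) -> bool:
        return bool(self.gap_ratios)

    def weighted_coords(self) -> np.ndarray:
        """(n, 2) array of axis-weighted coordinates, titration order."""
        w1, w2 = self.axis_weights
        return np.array([(w1 * f1, w2 * f2) for _, f1, f2 in self.points])

    @property
    def ratios(self) -> tuple[float, ...]:
        return tuple(p[0] for p in self.points)


@dataclass(frozen=True)
class BreakpointResult:
    """Outcome of direction-change detection on one trajectory."""

    has_break: bool
    break_ratio: float | None
    max_turn_deg: float
    turn_angles_deg: tuple[float, ...] = ()
    zero_motion: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_turn_deg <= 180.0:
            raise ValidationError("max_turn_deg must lie in [0, 180]")


def default_axis_weights(
    spectrum_type: SpectrumType, alpha: float = DEFAULT_ALPHA
) -> tuple[float, float]:
    if spectrum_type is SpectrumType.HSQC_CH:
        return (math.sqrt(alpha), 1.0)
    return (1.0, 1.0)


def extract_trajectory(
    series: TitrationSeries,
    assignment: Assignment,
    alpha: float = DEFAULT_ALPHA,
) -> Trajectory:
    """Collect one assignment's present peaks across the series, in ratio order.

    Missing points are excluded and recorded in ``gap_ratios``.  Raises when
    fewer than three points remain.
    """
    points: list[tuple[float, float, float]] = []
    gaps: list[float] = []
    for peaklist in series.points:
        peak = peaklist.peak(assignment)
        if peak is None or not peak.present:
            gaps.append(peaklist.ratio)
        else:
            points.append((peaklist.ratio, peak.f1_ppm, peak.f2_ppm))
    if len(points) < 3:
        raise ValidationError(
            f"insufficient points for {assignment}: {len(points)} present (< 3)"
        )
    return Trajectory(
        assignment=assignment,
        points=tuple(points),
        axis_weights=default_axis_weights(series.spectrum_type, alpha),
        gap_ratios=tuple(gaps),
    )


def _merged_steps(
    coords: np.ndarray, ratios: tuple[float, ...], min_step: float
) -> list[tuple[np.ndarray, float]]:
    """Displacement vectors with sub-threshold steps merged into the following step.

    Returns (vector, vertex_ratio) pairs, where vertex_ratio is the titration
    ratio of the point at which the (merged) step ends.
    """
    steps = [
        (coords[i + 1] - coords[i], ratios[i + 1]) for i in range(len(coords) - 1)
    ]
    merged: list[tuple[np.ndarray, float]] = []
    carry = np.zeros(2)
    for vec, end_ratio in steps:
        total = carry + vec
        if np.linalg.norm(total) < min_step:
            carry = total
            continue
        merged.append((total, end_ratio))
        carry = np.zeros(2)
    # a trailing short remainder is appended to the last accepted step
    if np.any(carry) and merged:
        last_vec, _ = merged[-1]
        merged[-1] = (last_vec + carry, steps[-1][1])
    return merged


def detect_direction_change(
    trajectory: Trajectory,
    turn_threshold_deg: float = DEFAULT_TURN_THRESHOLD_DEG,
    min_step_ppm: float = DEFAULT_MIN_STEP_PPM,
) -> BreakpointResult:
    """Detect a change of direction along a titration trajectory.

    Computes the turning angle between successive displacement vectors in the
    axis-weighted plane; steps shorter than ``min_step_ppm`` are merged into
    the following step as a noise guard.  ``has_break`` is true iff any angle
    reaches ``turn_threshold_deg``; ``break_ratio`` is the ratio at the vertex
    of the first qualifying turn (the last point before the new direction).
    """
    if turn_threshold_deg <= 0 or min_step_ppm <= 0:
        raise ValidationError("thresholds must be > 0")
    coords = trajectory.weighted_coords()
    merged = _merged_steps(coords, trajectory.ratios, min_step_ppm)
    if len(merged) == 0:
        return BreakpointResult(False, None, 0.0, (), zero_motion=True)
    angles: list[float] = []
    vertices: list[float] = []
    for (v1, end_ratio), (v2, _) in zip(merged, merged[1:]):
        cos = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        angles.append(math.degrees(math.acos(max(-1.0, min(1.0, cos)))))
        vertices.append(end_ratio)
    if not angles:
        return BreakpointResult(False, None, 0.0, ())
    max_turn = max(angles)
    break_ratio = None
    has_break = False
    for angle, vertex in zip(angles, vertices):
        if angle >= turn_threshold_deg:
            has_break = True
            break_ratio = vertex
            break
    return BreakpointResult(has_break, break_ratio, max_turn, tuple(angles))


def trajectory_dataframe(trajectory: Trajectory):
    import pandas as pd

    return pd.DataFrame(trajectory.points, columns=["ratio", "f1_ppm", "f2_ppm"])
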