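"""Locomotor-trajectory metrics for 60-fps larval tracking.

Distance is the per-frame Euclidean step length
``D_i = sqrt((x_{i+1}-x_i)^2 + (y_{i+1}-y_i)^2)`` summed over the frames of
an epoch. Movement-phase segmentation bins displacements into whole seconds
and extracts maximal runs of seconds containing movement, so sub-second
pauses never break a phase and phases are separated by at least one immobile
second. Turning is the law-of-cosines angle at each trajectory vertex,
summed over active frames and divided by the total path length.
"""
from __future__ import annotations

import numpy as np

from .types import (
    DegenerateInputError,
    EpochDef,
    LarvaQuantError,
    MovementPhase,
    Trajectory,
    TurningResult,
    UndefinedRatioError,
)

__all__ = [
    "frame_displacements",
    "total_distance",
    "per_second_movement_flags",
    "segment_phases",
    "interior_angle",
    "turning_per_distance",
    "standard_epochs",
]

#: Duration of the baseline analysis window, seconds.
BASELINE_S = 115
#: Pre-/post-shock comparison window, seconds.
SHOCK_WINDOW_S = 5


def frame_displacements(traj: Trajectory) -> np.ndarray:
    """Euclidean step length between consecutive frames (length n_frames-1)."""
    if traj.n_frames < 2:
        raise LarvaQuantError("need at least 2 frames")
    return np.hypot(np.diff(traj.x), np.diff(traj.y))


def total_distance(traj: Trajectory, epoch: EpochDef) -> float:
    """Total path length (cm) over the frames of an epoch.

    Sums the displacements between consecutive frames that both lie inside
    the half-open epoch, so an epoch must contain at least 2 frames.
    """
    epoch.validate_for(traj.n_frames)
    if len(epoch) < 2:
        raise LarvaQuantError("epoch must span at least 2 frames")
    d = frame_displacements(traj)
    return float(np.sum(d[epoch.start_frame : epoch.end_frame - 1]))


def standard_epochs(traj: Trajectory) -> dict[str, EpochDef]:
    """The analysis epochs: 115-s baseline plus 5-s pre-/post-shock windows.

    Pre/post windows are only defined when the trajectory carries a shock
    annotation and the recording is long enough on both sides.
    """
    fps = traj.fps
    epochs: dict[str, EpochDef] = {}
    baseline_end = int(round(BASELINE_S * fps))
    epochs["baseline"] = EpochDef(0, min(baseline_end, traj.n_frames))
    if traj.shock_frame is not None:
        w = int(round(SHOCK_WINDOW_S * fps))
        s = traj.shock_frame
        if s - w >= 0:
            epochs["pre_shock"] = EpochDef(s - w, s)
        if s + w <= traj.n_frames:
            epochs["post_shock"] = EpochDef(s, s + w)
    return epochs


def per_second_movement_flags(
    traj: Trajectory, epsilon: float = 0.0
) -> np.ndarray:
    """Flag each whole second as containing movement.

    Displacements are binned into consecutive whole seconds (``fps`` frames
    per second; ``fps`` must be an integer) and second ``s`` is flagged iff
    the summed displacement over its frames exceeds ``epsilon`` cm. The
    trailing partial second is dropped.
    """
    fps = traj.fps
    if fps != int(fps):
        raise LarvaQuantError(
            f"per-second binning requires an integer fps, got {fps}"
        )
    fps = int(fps)
    if epsilon < 0:
        raise LarvaQuantError("epsilon must be >= 0")
    d = frame_displacements(traj)
    n_sec = len(d) // fps
    if n_sec < 1:
        raise LarvaQuantError("recording shorter than one second")
    binned = d[: n_sec * fps].reshape(n_sec, fps).sum(axis=1)
    return binned > epsilon


def segment_phases(flags: np.ndarray) -> list[MovementPhase]:
    """Extract movement phases from per-second movement flags.

    A phase commences at a movement second whose preceding second (if any)
    is immobile, and persists through each subsequent consecutive movement
    second. Returns the maximal runs of True as (start second, integer
    duration) records.
    """
    flags = np.asarray(flags, dtype=bool)
    if len(flags) == 0:
        raise LarvaQuantError("need at least one second of flags")
    padded = np.concatenate(([False], flags, [False])).astype(int)
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [MovementPhase(int(s), int(e - s)) for s, e in zip(starts, ends)]


def interior_angle(p1, p2, p3) -> float:
    """Law-of-cosines angle (degrees) at vertex p2 of a frame triple.

    With a = |p1 p2|, b = |p2 p3| and c = |p1 p3|,
    ``C = arccos((a^2 + b^2 - c^2) / (2ab))``, the cosine argument clamped
    to [-1, 1]. Straight-line motion gives 180 deg, a right-angle turn 90,
    and a full backtrack 0. Raises on a degenerate side (a or b zero);
    callers skip such frames.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    a = float(np.hypot(*(p2 - p1)))
    b = float(np.hypot(*(p3 - p2)))
    if a == 0 or b == 0:
        raise DegenerateInputError("zero-length side; no angle at this frame")
    c = float(np.hypot(*(p3 - p1)))
    cos_c = (a * a + b * b - c * c) / (2 * a * b)
    cos_c = min(1.0, max(-1.0, cos_c))
    return float(np.degrees(np.arccos(cos_c)))


def turning_per_distance(
    traj: Trajectory,
    epoch: EpochDef,
    epsilon: float = 0.0,
    mode: str = "interior_angle",
) -> TurningResult:
    """Summed turning over an epoch divided by total distance traveled.

    Iterates over consecutive frame triples starting with the second frame
    of the epoch. A vertex contributes when the larva is active there, i.e.
    both flanking displacements exceed ``epsilon``. ``mode='interior_angle'``
    sums the literal law-of-cosines angle C (180 deg for straight swimming);
    ``mode='heading_change'`` sums 180 - C, the change in heading (0 for
    straight swimming). The denominator is the total distance over the whole
    epoch.
    """
    if mode not in ("interior_angle", "heading_change"):
        raise LarvaQuantError(f"unknown turning mode {mode!r}")
    epoch.validate_for(traj.n_frames)
    if len(epoch) < 3:
        raise LarvaQuantError("epoch must span at least 3 frames")
    x = traj.x[epoch.start_frame : epoch.end_frame]
    y = traj.y[epoch.start_frame : epoch.end_frame]
    dx = np.diff(x)
    dy = np.diff(y)
    seg = np.hypot(dx, dy)
    a = seg[:-1]
    b = seg[1:]
    active = (a > epsilon) & (b > epsilon)
    # chord p1 -> p3 for each interior vertex
    cx = x[2:] - x[:-2]
    cy = y[2:] - y[:-2]
    c2 = cx * cx + cy * cy
    with np.errstate(divide="ignore", invalid="ignore"):
        cos_c = (a * a + b * b - c2) / (2 * a * b)
    cos_c = np.clip(cos_c, -1.0, 1.0)
    angles = np.degrees(np.arccos(cos_c[active]))
    if mode == "heading_change":
        angles = 180.0 - angles
    total_turn = float(np.sum(angles))
    dist = total_distance(traj, epoch)
    if dist == 0:
        raise UndefinedRatioError("total distance is 0; ratio undefined")
    return TurningResult(
        total_turn_deg=total_turn,
        distance_cm=dist,
        turn_per_cm=total_turn / dist,
        mode=mode,
        n_active_vertices=int(active.sum()),
    )
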