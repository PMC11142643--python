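"""Core data containers and error types shared across the pipeline.

All time series are stored as float numpy arrays; missing frames (e.g. the
laser-switch gaps in optogenetic sessions) are encoded as NaN and every
window-based operation skips them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LarvaQuantError",
    "DegenerateInputError",
    "UndefinedRatioError",
    "SchemaError",
    "FluorescenceTrace",
    "NormalizedTrace",
    "EpochDef",
    "PeakSet",
    "ResponseMetrics",
    "ImageStack",
    "ROIPolygon",
    "Trajectory",
    "MovementPhase",
    "TurningResult",
]


class LarvaQuantError(ValueError):
    """Base class for all pipeline errors."""


class DegenerateInputError(LarvaQuantError):
    """Input is structurally valid but analytically degenerate
    (constant trace, zero-area polygon, zero-variance group, ...)."""


class UndefinedRatioError(LarvaQuantError):
    """A ratio's denominator is zero (F_pre = 0, total distance = 0)."""


class SchemaError(LarvaQuantError):
    """A file does not conform to its documented schema."""


def _as_float_array(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise LarvaQuantError(f"expected a 1-D series, got shape {arr.shape}")
    return arr


@dataclass
class FluorescenceTrace:
    """Per-frame mean ROI fluorescence (arbitrary units).

    NaN entries mark missing frames. ``rate_hz`` is the acquisition rate.
    """

    roi_id: str
    rate_hz: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values)
        if self.rate_hz <= 0:
            raise LarvaQuantError(f"rate_hz must be > 0, got {self.rate_hz}")
        if len(self.values) == 0:
            raise LarvaQuantError("trace must have at least one frame")
        finite = self.values[~np.isnan(self.values)]
        if not np.all(np.isfinite(finite)):
            raise LarvaQuantError("non-missing trace values must be finite")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class NormalizedTrace:
    """A min-max normalized trace: dF/F as a fraction in [0, 1].

    The minimum of the non-missing values is 0 and the maximum is 1 (both
    attained). Percent dF/F is ``100 * values`` and is used only for display.
    """

    roi_id: str
    rate_hz: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values)
        if self.rate_hz <= 0:
            raise LarvaQuantError(f"rate_hz must be > 0, got {self.rate_hz}")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class EpochDef:
    """Half-open frame window [start_frame, end_frame)."""

    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_frame < self.end_frame):
            raise LarvaQuantError(
                f"invalid epoch [{self.start_frame}, {self.end_frame})"
            )

    def validate_for(self, n_frames: int) -> None:
        if self.end_frame > n_frames:
            raise LarvaQuantError(
                f"epoch [{self.start_frame}, {self.end_frame}) exceeds "
                f"trace length {n_frames}"
            )

    def __len__(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class PeakSet:
    """Detected calcium-event peaks on a normalized trace."""

    frames: np.ndarray  # strictly increasing frame indices
    prominences: np.ndarray  # dF/F fraction
    widths: np.ndarray  # frames, measured at half prominence

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.prominences = np.asarray(self.prominences, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if np.any(np.diff(self.frames) <= 0):
            raise LarvaQuantError("peak frames must be strictly increasing")

    @property
    def count(self) -> int:
        return len(self.frames)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class ResponseMetrics:
    """Evoked-response summary for one ROI."""

    ratio: float | None = None  # F_post / F_pre
    duration_s: float | None = None
    censored: bool = False
    onset_frame: int | None = None


@dataclass
class ImageStack:
    """A frame-major fluorescence image stack (frames, rows, cols)."""

    intensities: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise LarvaQuantError(
                f"stack must be 3-D (frames, rows, cols), got shape "
                f"{self.intensities.shape}"
            )
        if self.rate_hz <= 0:
            raise LarvaQuantError(f"rate_hz must be > 0, got {self.rate_hz}")
        if not np.all(np.isfinite(self.intensities)):
            raise LarvaQuantError("stack intensities must be finite")
        if np.any(self.intensities < 0):
            raise LarvaQuantError("stack intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class ROIPolygon:
    """A manually drawn polygonal ROI in 0-based (row, col) pixel coordinates."""

    roi_id: str
    vertices: np.ndarray  # (n, 2) ordered (row, col), n >= 3

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise LarvaQuantError("vertices must be an (n, 2) array of (row, col)")
        if self.vertices.shape[0] < 3:
            raise LarvaQuantError("polygon needs at least 3 vertices")


@dataclass
class Trajectory:
    """Per-frame larva centroid positions in cm at a fixed frame rate."""

    fps: float
    x: np.ndarray
    y: np.ndarray
    shock_frame: int | None = None

    def __post_init__(self) -> None:
        self.x = _as_float_array(self.x)
        self.y = _as_float_array(self.y)
        if self.fps <= 0:
            raise LarvaQuantError(f"fps must be > 0, got {self.fps}")
        if len(self.x) != len(self.y):
            raise LarvaQuantError("x and y must have equal length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise LarvaQuantError("positions must be finite")
        if self.shock_frame is not None and not (
            0 <= self.shock_frame < len(self.x)
        ):
            raise LarvaQuantError(
                f"shock_frame {self.shock_frame} outside [0, {len(self.x)})"
            )

    @property
    def n_frames(self) -> int:
        return len(self.x)

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class MovementPhase:
    """A maximal run of consecutive whole seconds each containing movement."""

    start_s: int
    duration_s: int

    def __post_init__(self) -> None:
        if self.start_s < 0 or self.duration_s < 1:
            raise LarvaQuantError(
                f"invalid phase (start_s={self.start_s}, "
                f"duration_s={self.duration_s})"
            )

    @property
    def end_s(self) -> int:
        return self.start_s + self.duration_s


@dataclass
class TurningResult:
    """Summed per-vertex turning over an epoch, normalized by path length."""

    total_turn_deg: float
    distance_cm: float
    turn_per_cm: float
    mode: str
    n_active_vertices: int = 0


@dataclass
class GroundTruthLog:
    """Ground truth emitted alongside every synthetic output."""

    event_frames: dict = field(default_factory=dict)  # roi_id -> array of frames
    oscillation_crest_frames: dict = field(default_factory=dict)
    phase_intervals: list = field(default_factory=list)  # (start_s, end_s)
    headings_deg: np.ndarray | None = None
    true_traces: dict = field(default_factory=dict)  # roi_id -> array
    stim_window: tuple | None = None  # (start_frame, end_frame) half-open
    roi_masks: dict = field(default_factory=dict)  # roi_id -> boolean mask
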