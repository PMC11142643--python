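"""File formats: CSV traces and trajectories, multi-frame TIFF stacks,
ROI-polygon JSON, and YAML configuration.

Schemas
-------
Trace CSV: header comment ``# rate_hz: <float>`` followed by a header row
and columns ``frame, roi_id, value``; missing frames serialize as empty
values. Trajectory CSV: header comments ``# fps: <float>`` and optionally
``# shock_frame: <int>``, then columns ``frame, x_cm, y_cm``. Frames must be
consecutive from 0. Floats are written with 12 significant digits so a
write/read round trip is lossless at double precision for all practical
values. Unknown columns warn; missing required columns fail.
"""
from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import (
    FluorescenceTrace,
    ImageStack,
    ROIPolygon,
    SchemaError,
    Trajectory,
)

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_stack_tiff",
    "read_stack_tiff",
    "read_roi_json",
    "write_roi_json",
    "read_config_yaml",
]

_FLOAT_FMT = "%.12g"


def _read_header_comments(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, value = body.split(":", 1)
                meta[key.strip()] = value.strip()
    return meta


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}")


def _check_consecutive_frames(frames: np.ndarray, path) -> None:
    expected = np.arange(len(frames))
    if not np.array_equal(frames, expected):
        bad = int(np.flatnonzero(frames != expected)[0])
        raise SchemaError(
            f"{path}: frame numbering must be consecutive from 0; first "
            f"mismatch at row {bad} (frame {frames[bad]}, expected {bad})"
        )


def write_traces_csv(traces: list[FluorescenceTrace], path) -> None:
    path = Path(path)
    rate = traces[0].rate_hz
    rows = []
    for t in traces:
        if t.rate_hz != rate:
            raise SchemaError("all traces in one file must share rate_hz")
        for frame, value in enumerate(t.values):
            rows.append((frame, t.roi_id, value))
    df = pd.DataFrame(rows, columns=["frame", "roi_id", "value"])
    with open(path, "w") as fh:
        fh.write(f"# rate_hz: {rate!r}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_traces_csv(path) -> list[FluorescenceTrace]:
    path = Path(path)
    meta = _read_header_comments(path)
    if "rate_hz" not in meta:
        raise SchemaError(f"{path}: missing '# rate_hz:' header comment")
    rate = float(meta["rate_hz"])
    df = pd.read_csv(path, comment="#")
    _check_columns(df, ["frame", "roi_id", "value"], path)
    traces = []
    for roi_id, sub in df.groupby("roi_id", sort=False):
        frames = sub["frame"].to_numpy()
        _check_consecutive_frames(frames, path)
        traces.append(
            FluorescenceTrace(
                roi_id=str(roi_id), rate_hz=rate,
                values=sub["value"].to_numpy(dtype=float),
            )
        )
    return traces


def write_trajectory_csv(traj: Trajectory, path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {"frame": np.arange(traj.n_frames), "x_cm": traj.x, "y_cm": traj.y}
    )
    with open(path, "w") as fh:
        fh.write(f"# fps: {traj.fps!r}\n")
        if traj.shock_frame is not None:
            fh.write(f"# shock_frame: {traj.shock_frame}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_trajectory_csv(path) -> Trajectory:
    path = Path(path)
    meta = _read_header_comments(path)
    if "fps" not in meta:
        raise SchemaError(f"{path}: missing '# fps:' header comment")
    fps = float(meta["fps"])
    shock = int(meta["shock_frame"]) if "shock_frame" in meta else None
    df = pd.read_csv(path, comment="#")
    _check_columns(df, ["frame", "x_cm", "y_cm"], path)
    _check_consecutive_frames(df["frame"].to_numpy(), path)
    x = df["x_cm"].to_numpy(dtype=float)
    y = df["y_cm"].to_numpy(dtype=float)
    bad = np.flatnonzero(~(np.isfinite(x) & np.isfinite(y)))
    if len(bad):
        raise SchemaError(
            f"{path}: non-finite position at row {int(bad[0])}"
        )
    return Trajectory(fps=fps, x=x, y=y, shock_frame=shock)


def write_stack_tiff(stack: ImageStack, path) -> None:
    """Write a stack as 16-bit multi-frame TIFF (values rounded and clipped
    to the uint16 range); the acquisition rate travels in the description."""
    path = Path(path)
    data = np.clip(np.round(stack.intensities), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path, data, description=json.dumps({"rate_hz": stack.rate_hz})
    )


def read_stack_tiff(path, rate_hz: float | None = None) -> ImageStack:
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        if rate_hz is None:
            desc = tif.pages[0].tags.get("ImageDescription")
            try:
                rate_hz = float(json.loads(desc.value)["rate_hz"])
            except Exception:
                raise SchemaError(
                    f"{path}: no rate_hz in TIFF description; pass rate_hz="
                )
    if data.ndim == 2:
        data = data[None]
    return ImageStack(intensities=data.astype(float), rate_hz=rate_hz)


def write_roi_json(rois: list[ROIPolygon], path) -> None:
    payload = [
        {"roi_id": r.roi_id, "vertices": r.vertices.tolist()} for r in rois
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_roi_json(path) -> list[ROIPolygon]:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: invalid JSON ({exc})") from exc
    rois = []
    for i, entry in enumerate(payload):
        if "roi_id" not in entry or "vertices" not in entry:
            raise SchemaError(
                f"{path}: ROI entry {i} needs 'roi_id' and 'vertices'"
            )
        rois.append(
            ROIPolygon(
                roi_id=str(entry["roi_id"]),
                vertices=np.asarray(entry["vertices"], dtype=float),
            )
        )
    return rois


def read_config_yaml(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a YAML mapping")
    return cfg
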