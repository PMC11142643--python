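"""ROI extraction from fluorescence image stacks.

The workflow mirrors manual ROI analysis: compute a high-contrast
maximum-intensity projection of the image series, draw polygon ROIs on it,
rasterize each polygon to a pixel mask, and average the stack intensities
over the mask per frame to get one fluorescence trace per ROI.
"""
from __future__ import annotations

import numpy as np

from .types import (
    DegenerateInputError,
    FluorescenceTrace,
    ImageStack,
    LarvaQuantError,
    ROIPolygon,
)

__all__ = ["max_intensity_projection", "rasterize_polygon", "roi_mean_trace"]


def max_intensity_projection(stack: ImageStack) -> np.ndarray:
    """Per-pixel maximum over all frames (the high-contrast reference image)."""
    if stack.n_frames < 1:
        raise LarvaQuantError("stack has no frames")
    return stack.intensities.max(axis=0)


def _points_in_polygon(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even-odd (crossing-number) point-in-polygon test, boundary inclusive.

    ``points`` is (m, 2) of (row, col); ``vertices`` is (n, 2). A point on a
    polygon edge counts as inside.
    """
    py, px = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    on_edge = np.zeros(len(points), dtype=bool)
    n = len(vertices)
    for i in range(n):
        r1, c1 = vertices[i]
        r2, c2 = vertices[(i + 1) % n]
        # boundary test: point on segment (r1,c1)-(r2,c2)
        dr, dc = r2 - r1, c2 - c1
        cross = (py - r1) * dc - (px - c1) * dr
        within = (
            (np.minimum(r1, r2) - 1e-12 <= py)
            & (py <= np.maximum(r1, r2) + 1e-12)
            & (np.minimum(c1, c2) - 1e-12 <= px)
            & (px <= np.maximum(c1, c2) + 1e-12)
        )
        on_edge |= (np.abs(cross) < 1e-9) & within
        # crossing number against a ray in +col direction
        cond = (r1 > py) != (r2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = c1 + (py - r1) * dc / np.where(dr == 0, np.inf, dr)
        inside ^= cond & (px < x_int)
    return inside | on_edge


def rasterize_polygon(
    poly: ROIPolygon, height: int, width: int
) -> np.ndarray:
    """Rasterize a polygon ROI to a boolean pixel mask.

    A pixel belongs to the mask when its center (integer row, col) falls
    inside the polygon under the even-odd rule; pixels whose centers lie
    exactly on the boundary are included. Raises
    :class:`DegenerateInputError` when no pixel center falls inside the
    frame-clipped polygon.
    """
    verts = poly.vertices
    rmin = max(0, int(np.floor(verts[:, 0].min())))
    rmax = min(height - 1, int(np.ceil(verts[:, 0].max())))
    cmin = max(0, int(np.floor(verts[:, 1].min())))
    cmax = min(width - 1, int(np.ceil(verts[:, 1].max())))
    mask = np.zeros((height, width), dtype=bool)
    if rmin > rmax or cmin > cmax:
        raise DegenerateInputError(
            f"ROI {poly.roi_id!r} has no rasterized area inside the frame"
        )
    rr, cc = np.meshgrid(
        np.arange(rmin, rmax + 1), np.arange(cmin, cmax + 1), indexing="ij"
    )
    pts = np.column_stack([rr.ravel().astype(float), cc.ravel().astype(float)])
    hit = _points_in_polygon(pts, verts.astype(float))
    mask[rr.ravel()[hit], cc.ravel()[hit]] = True
    if not mask.any():
        raise DegenerateInputError(
            f"ROI {poly.roi_id!r} has no rasterized area inside the frame"
        )
    return mask


def roi_mean_trace(
    stack: ImageStack, mask: np.ndarray, roi_id: str = "roi"
) -> FluorescenceTrace:
    """Mean intensity over the masked pixels, per frame."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.shape[1:]:
        raise LarvaQuantError(
            f"mask shape {mask.shape} does not match frame shape "
            f"{stack.shape[1:]}"
        )
    if not mask.any():
        raise DegenerateInputError("mask selects no pixels")
    values = stack.intensities[:, mask].mean(axis=1)
    return FluorescenceTrace(roi_id=roi_id, rate_hz=stack.rate_hz, values=values)
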