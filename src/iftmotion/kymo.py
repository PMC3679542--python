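"""Kymograph extraction along straight or evolving flagellar paths.

A kymograph stacks, per frame, the image intensity sampled along a
polyline traced over the flagellum, giving a 2D (time x arc length)
image in which a particle moving at v um/s appears as a ridge of slope
v.  For cells that reorient their flagella while gliding, the path is
specified as a set of keyframe polylines sharing a fixed common point
(the anchor); intermediate frames use vertex-wise linear interpolation
of the arc-length-resampled bounding keyframes, and rows are stacked so
that the anchor maps to the same arc-length coordinate in every frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.ndimage import map_coordinates

from .config import ConfigError
from .render import Movie

__all__ = ["FlagellarPath", "Kymograph", "interpolate_paths",
           "sample_kymograph"]

#: tolerance (px) within which keyframe polylines must share their anchor
COMMON_POINT_TOL_PX = 2.0


@dataclass
class FlagellarPath:
    """Keyframed flagellar polyline with a fixed anchor point.

    keyframes
        list of (frame index, (N, 2) array of (row, col) px vertices);
        frame indices strictly increasing; the first vertex is the base.
    anchor
        arc-length position (um) of the fixed common point, measured
        from the base; 0 anchors at the base itself.
    """

    keyframes: list[tuple[int, np.ndarray]]
    anchor: float = 0.0
    base_end: str = "first"

    def __post_init__(self) -> None:
        if not self.keyframes:
            raise ConfigError("FlagellarPath needs at least one keyframe")
        frames = [f for f, _ in self.keyframes]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ConfigError("keyframe frame indices must be strictly "
                              "increasing")
        for f, poly in self.keyframes:
            poly = np.asarray(poly, dtype=float)
            if poly.ndim != 2 or poly.shape[0] < 2 or poly.shape[1] != 2:
                raise ConfigError(f"keyframe {f}: polyline must be (N>=2, 2)")


@dataclass
class Kymograph:
    """2D intensity: axis 0 = time (s), axis 1 = arc length from base (um)."""

    data: np.ndarray
    pixel_size: float              # um per arc-length sample
    frame_interval: float          # s per row
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.data.shape[0] * self.frame_interval

    @property
    def length(self) -> float:
        return self.data.shape[1] * self.pixel_size


def _sample_at_arcs(poly: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Evaluate a polyline at arc-length positions u (px from the base)."""
    poly = np.asarray(poly, dtype=float)
    seg = np.diff(poly, axis=0)
    arc = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    if arc[-1] <= 0:
        raise ConfigError("polyline has zero length")
    return np.column_stack([np.interp(u, arc, poly[:, 0]),
                            np.interp(u, arc, poly[:, 1])])


def _arc_length(poly: np.ndarray) -> float:
    seg = np.diff(np.asarray(poly, dtype=float), axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def _point_at_arc(poly: np.ndarray, s_px: float) -> np.ndarray:
    poly = np.asarray(poly, dtype=float)
    seg = np.diff(poly, axis=0)
    arc = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    return np.array([np.interp(s_px, arc, poly[:, 0]),
                     np.interp(s_px, arc, poly[:, 1])])


def interpolate_paths(path: FlagellarPath, n_frames: int,
                      pixel_size: float = 1.0,
                      resample_step_px: float = 1.0) -> list[np.ndarray]:
    """Expand a keyframed path into one polyline per frame.

    Keyframe polylines are resampled at a fixed arc-length step from the
    base, truncated to the shortest keyframe so every frame shares the
    same arc-length grid (vertex j sits j*step px from the base in every
    frame, which is what keeps the anchor at a fixed coordinate); frames
    between two keyframes blend the bounding polylines vertex-wise,
    frames outside the keyframe span reuse the nearest keyframe.
    Consecutive keyframes must share the anchor point to within 2 px.
    Returns a list of ``n_frames`` (N, 2) arrays.
    """
    keyframes = [(f, np.asarray(p, dtype=float)) for f, p in path.keyframes]
    if keyframes[0][0] < 0 or keyframes[-1][0] >= n_frames:
        raise ConfigError("keyframe frame indices must lie in [0, n_frames)")

    min_len_px = min(_arc_length(p) for _, p in keyframes)
    n_pts = max(int(np.floor(min_len_px / resample_step_px)) + 1, 2)
    u = np.arange(n_pts) * resample_step_px
    resampled = [(f, _sample_at_arcs(p, u)) for f, p in keyframes]

    anchor_px = path.anchor / pixel_size
    for (fa, pa), (fb, pb) in zip(resampled, resampled[1:]):
        qa = _point_at_arc(pa, anchor_px)
        qb = _point_at_arc(pb, anchor_px)
        if np.hypot(*(qa - qb)) > COMMON_POINT_TOL_PX:
            raise ConfigError(
                f"keyframes {fa} and {fb} do not share a common point at "
                f"the anchor (offset {np.hypot(*(qa - qb)):.2f} px)")

    frames_idx = [f for f, _ in resampled]
    polys = [p for _, p in resampled]
    out: list[np.ndarray] = []
    for i in range(n_frames):
        if i <= frames_idx[0]:
            out.append(polys[0].copy())
        elif i >= frames_idx[-1]:
            out.append(polys[-1].copy())
        else:
            k = np.searchsorted(frames_idx, i, side="right") - 1
            f0, f1 = frames_idx[k], frames_idx[k + 1]
            w = (i - f0) / (f1 - f0)
            out.append((1.0 - w) * polys[k] + w * polys[k + 1])
    return out


def sample_kymograph(movie: Movie, paths: list[np.ndarray] | np.ndarray,
                     linewidth_px: int = 3) -> Kymograph:
    """Sample a kymograph from a movie along per-frame polylines.

    Each row is the bilinear interpolation of the corresponding frame at
    equal arc-length steps of one pixel along the polyline, averaged over
    ``linewidth_px`` parallel samples perpendicular to the local tangent.
    Out-of-bounds samples use edge padding.  A single polyline is reused
    for every frame.
    """
    if linewidth_px < 1:
        raise ConfigError("linewidth_px must be >= 1")
    n_frames = movie.n_frames
    if isinstance(paths, np.ndarray):
        paths = [paths] * n_frames
    if len(paths) != n_frames:
        raise ConfigError(f"need one path per frame ({n_frames}), got "
                          f"{len(paths)}")

    # common sample count across frames so the kymograph is rectangular;
    # samples sit at 1 px arc-length steps from the base in every frame
    n_samp = min(int(np.floor(_arc_length(p))) + 1 for p in paths)
    u = np.arange(n_samp, dtype=float)
    offsets = np.arange(linewidth_px, dtype=float) - (linewidth_px - 1) / 2.0

    rows = np.empty((n_frames, n_samp))
    for i in range(n_frames):
        pts = _sample_at_arcs(paths[i], u)
        tangent = np.gradient(pts, axis=0)
        norm = np.hypot(tangent[:, 0], tangent[:, 1])
        norm[norm == 0] = 1.0
        normal = np.column_stack([-tangent[:, 1], tangent[:, 0]]) / norm[:, None]
        acc = np.zeros(n_samp)
        frame = movie.data[i].astype(float)
        for off in offsets:
            coords = pts + off * normal
            acc += map_coordinates(frame, [coords[:, 0], coords[:, 1]],
                                   order=1, mode="nearest")
        rows[i] = acc / linewidth_px

    return Kymograph(rows, movie.pixel_size, movie.frame_interval,
                     meta=dict(movie.meta))
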