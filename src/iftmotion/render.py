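"""Render simulated ground truth to TIRF-like movies and kymographs.

Emitters (IFT trains and the bead) are drawn as 2D Gaussians of width
``psf_sigma`` at their subpixel positions along a flagellar path mapped
into the image; the camera model is Poisson shot noise on signal plus
background, followed by additive Gaussian read noise, quantized to
unsigned 16-bit counts.  ``render_kymograph`` renders the same emitters
directly on the (arc length x time) grid, bypassing the 2D image; it is
the fast path used for direction-analysis studies where the flagellar
geometry is not itself under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .config import ConfigError, SimConfig
from .synthetic import GroundTruth

__all__ = ["Movie", "straight_path", "render_movie", "render_kymograph"]


@dataclass
class Movie:
    """Intensity stack (time x row x col) with acquisition metadata."""

    data: np.ndarray               # (n_frames, n_rows, n_cols)
    pixel_size: float              # um
    frame_interval: float          # s
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


def straight_path(config: SimConfig, margin_px: int = 6,
                  row: float | None = None) -> np.ndarray:
    """Horizontal two-vertex polyline long enough for the flagellum.

    Returns an (N, 2) array of (row, col) pixel coordinates whose arc
    length covers ``flagellum_length`` with ``margin_px`` of padding on
    the left; the base maps to the first vertex.
    """
    n_cols = int(np.ceil(config.flagellum_length / config.pixel_size)) + 2 * margin_px
    r = float(row) if row is not None else float(margin_px)
    return np.array([[r, float(margin_px)],
                     [r, float(margin_px) + config.flagellum_length / config.pixel_size]])


def _emitters_per_frame(truth: GroundTruth, n_frames: int, dt: float,
                        include_bead: bool = True
                        ) -> list[list[tuple[float, float]]]:
    """Per-frame list of (arc position um, relative amplitude)."""
    out: list[list[tuple[float, float]]] = [[] for _ in range(n_frames)]
    for tr in truth.trains:
        idx = np.round(tr.t / dt).astype(int)
        for j, i in enumerate(idx):
            if 0 <= i < n_frames:
                out[i].append((float(tr.s[j]), 1.0))
    if include_bead and truth.bead is not None:
        idx = np.round(truth.bead.t / dt).astype(int)
        for j, i in enumerate(idx):
            if 0 <= i < n_frames:
                out[i].append((float(truth.bead.s[j]), 1.0))
    return out


def _path_geometry(path: np.ndarray, pixel_size: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative arc length (um) and vertices of a (row, col) polyline."""
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or path.shape[0] < 2 or path.shape[1] != 2:
        raise ConfigError("path must be an (N>=2, 2) polyline of (row, col)")
    seg = np.diff(path, axis=0)
    arc = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    return arc * pixel_size, path


def _point_on_path(arc_um: np.ndarray, verts: np.ndarray, s_um: float
                   ) -> tuple[float, float]:
    r = float(np.interp(s_um, arc_um, verts[:, 0]))
    c = float(np.interp(s_um, arc_um, verts[:, 1]))
    return r, c


def render_movie(truth: GroundTruth, config: SimConfig,
                 path: np.ndarray | None = None,
                 shape: tuple[int, int] | None = None,
                 include_bead: bool = True) -> Movie:
    """Render ground truth to a noisy 16-bit movie.

    Parameters
    ----------
    path
        (N, 2) polyline of (row, col) pixel coordinates along which the
        flagellum lies (base at the first vertex).  Default: a straight
        horizontal path with a 6 px margin.  Its arc length must cover
        ``flagellum_length``.
    shape
        Image (rows, cols); default fits the path with a margin.
    """
    cfg = config
    if path is None:
        path = straight_path(cfg)
    arc_um, verts = _path_geometry(path, cfg.pixel_size)
    if arc_um[-1] < cfg.flagellum_length - 1e-9:
        raise ConfigError("flagellar path is shorter than flagellum_length")
    if shape is None:
        margin = 6
        shape = (int(np.ceil(verts[:, 0].max())) + margin + 1,
                 int(np.ceil(verts[:, 1].max())) + margin + 1)

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(6)[5])
    n = cfg.n_frames
    dt = cfg.frame_interval
    sigma_px = max(cfg.psf_sigma / cfg.pixel_size, 1e-6)
    half = int(np.ceil(4 * sigma_px)) + 1
    per_frame = _emitters_per_frame(truth, n, dt, include_bead)

    frames = np.empty((n, shape[0], shape[1]), dtype=np.uint16)
    rows_g, cols_g = np.mgrid[-half:half + 1, -half:half + 1]
    for i in range(n):
        signal = np.zeros(shape, dtype=float)
        for s_um, amp in per_frame[i]:
            r, c = _point_on_path(arc_um, verts, s_um)
            ir, ic = int(round(r)), int(round(c))
            dr, dc = r - ir, c - ic
            patch = cfg.photon_rate * amp * np.exp(
                -((rows_g - dr) ** 2 + (cols_g - dc) ** 2) / (2 * sigma_px ** 2))
            r0, r1 = ir - half, ir + half + 1
            c0, c1 = ic - half, ic + half + 1
            pr0, pr1 = max(0, -r0), 2 * half + 1 - max(0, r1 - shape[0])
            pc0, pc1 = max(0, -c0), 2 * half + 1 - max(0, c1 - shape[1])
            if pr1 <= pr0 or pc1 <= pc0:
                continue
            signal[max(0, r0):min(shape[0], r1),
                   max(0, c0):min(shape[1], c1)] += patch[pr0:pr1, pc0:pc1]
        expected = signal + cfg.background_rate
        if cfg.photon_rate > 0 or cfg.background_rate > 0:
            counts = rng.poisson(expected).astype(float)
        else:
            counts = expected
        if cfg.read_noise > 0:
            counts = counts + rng.normal(0.0, cfg.read_noise, size=counts.shape)
        frames[i] = np.clip(np.rint(counts), 0, 65535).astype(np.uint16)

    meta = {"seed": cfg.seed, "pixel_size_um": cfg.pixel_size,
            "frame_interval_s": dt}
    return Movie(frames, cfg.pixel_size, dt, meta)


def render_kymograph(truth: GroundTruth, config: SimConfig,
                     include_bead: bool = False,
                     noise: bool = True) -> "np.ndarray":
    """Render ground truth directly as a (time x arc length) kymograph.

    Emitters appear as 1D Gaussians of width ``psf_sigma`` at their arc
    positions; the camera model matches :func:`render_movie`.  Returns a
    float array of shape (n_frames, n_position_bins) with bin width equal
    to the pixel size.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(7)[6])
    n = cfg.n_frames
    dt = cfg.frame_interval
    n_s = int(np.ceil(cfg.flagellum_length / cfg.pixel_size)) + 1
    s_grid = np.arange(n_s) * cfg.pixel_size
    sigma = max(cfg.psf_sigma, 1e-6)
    per_frame = _emitters_per_frame(truth, n, dt, include_bead)

    kymo = np.zeros((n, n_s))
    for i in range(n):
        for s_um, amp in per_frame[i]:
            kymo[i] += cfg.photon_rate * amp * np.exp(
                -((s_grid - s_um) ** 2) / (2 * sigma ** 2))
    expected = kymo + cfg.background_rate
    if noise:
        out = rng.poisson(expected).astype(float)
        if cfg.read_noise > 0:
            out = out + rng.normal(0.0, cfg.read_noise, size=out.shape)
        return np.clip(out, 0, None)
    return expected
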