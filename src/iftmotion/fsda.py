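"""Fourier-space direction analysis (FSDA) of kymographs.

A trajectory of velocity v appears in a kymograph K(t, s) as a ridge of
slope ds/dt = v, and concentrates its spectral energy on the line
f_t = -v f_s of the 2D Fourier plane.  Masking the wedge of frequencies
whose implied velocity -f_t/f_s falls in a chosen interval and inverse
transforming therefore isolates the trajectories in that velocity class.
Splitting the spectrum over a disjoint set of velocity bins (retrograde,
paused, anterograde by default) decomposes the kymograph into one
component image per class, from which paused-train kymographs, velocity
pseudo-colorings, and per-train velocity fits are derived.

Sign convention: positive velocity is anterograde (toward increasing arc
length, i.e. the flagellar tip).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter

from .config import ConfigError
from .kymo import Kymograph

__all__ = ["VelocityBins", "FsdaResult", "build_masks", "decompose",
           "velocity_colormap", "extract_tracks", "RidgeTrack"]

BACKGROUND = "background"


@dataclass
class VelocityBins:
    """Ordered, disjoint velocity intervals covering the whole real line.

    bins
        list of (label, (v_lo, v_hi)) in um/s, sorted, contiguous, with
        v_lo = -inf on the first and v_hi = +inf on the last.
    softness
        raised-cosine edge width as a fraction of each wedge's angular
        width; 0 gives hard-edged masks.
    """

    bins: list[tuple[str, tuple[float, float]]]
    softness: float = 0.1

    def __post_init__(self) -> None:
        if not self.bins:
            raise ConfigError("VelocityBins needs at least one bin")
        edges_lo = [b[1][0] for b in self.bins]
        edges_hi = [b[1][1] for b in self.bins]
        if edges_lo[0] != -math.inf or edges_hi[-1] != math.inf:
            raise ConfigError("bins must cover (-inf, +inf)")
        for (_, (lo, hi)) in self.bins:
            if not lo < hi:
                raise ConfigError(f"empty or inverted bin ({lo}, {hi})")
        for hi, lo in zip(edges_hi[:-1], edges_lo[1:]):
            if hi != lo:
                raise ConfigError("bins must be contiguous and disjoint")
        if not 0 <= self.softness < 0.5:
            raise ConfigError("softness must be in [0, 0.5)")

    @classmethod
    def standard(cls, v_min: float = 0.2, softness: float = 0.1
                 ) -> "VelocityBins":
        """Retrograde / paused / anterograde split at +-v_min um/s."""
        if v_min <= 0:
            raise ConfigError("v_min must be > 0")
        return cls([
            ("retrograde", (-math.inf, -v_min)),
            ("paused", (-v_min, v_min)),
            ("anterograde", (v_min, math.inf)),
        ], softness=softness)

    @property
    def labels(self) -> list[str]:
        return [b[0] for b in self.bins]


@dataclass
class FsdaResult:
    """Decomposition of a kymograph into velocity-class components."""

    components: dict[str, np.ndarray]   # per-bin real images, incl. background
    energy: dict[str, float]            # per-bin spectral energy fractions
    window: np.ndarray                  # 2D window applied before the FFT
    bins: VelocityBins
    pixel_size: float
    frame_interval: float

    def component_kymograph(self, label: str) -> Kymograph:
        return Kymograph(self.components[label], self.pixel_size,
                         self.frame_interval, meta={"component": label})


def _implied_angle(shape: tuple[int, int], pixel_size: float,
                   frame_interval: float) -> np.ndarray:
    """arctan of the velocity implied by each 2D frequency-plane point.

    Returns psi = arctan(-f_t / f_s) in (-pi/2, pi/2]; the f_s = 0 axis
    maps to +pi/2 (infinite speed).  The map is even under f -> -f, so
    any mask built from it is Hermitian-symmetric.
    """
    n_t, n_s = shape
    f_t = np.fft.fftfreq(n_t, d=frame_interval)[:, None]
    f_s = np.fft.fftfreq(n_s, d=pixel_size)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(f_s != 0, -f_t / f_s, np.inf)
    return np.arctan(v)


def _soft_interval(psi: np.ndarray, a: float, b: float, w: float
                   ) -> np.ndarray:
    """Raised-cosine membership of psi in the circular arc [a, b].

    The angle domain is the circle of period pi (psi = +pi/2 and -pi/2
    are the same spectral line); w is the edge half-width in radians.
    """
    period = math.pi
    mid = (a + b) / 2.0
    half = (b - a) / 2.0
    # circular distance from the interval midpoint
    d = np.abs((psi - mid + period / 2.0) % period - period / 2.0)
    if w <= 1e-9:
        # effectively hard-edged: include the boundary (adjacent bins
        # overlap there by one sample and the normalization splits it)
        return (d <= half + 1e-12).astype(float)
    out = np.zeros_like(psi, dtype=float)
    inside = d <= half - w
    edge = (d > half - w) & (d < half + w)
    out[inside] = 1.0
    out[edge] = 0.5 * (1.0 + np.cos(np.pi * (d[edge] - (half - w)) / (2 * w)))
    return out


def build_masks(bins: VelocityBins, shape: tuple[int, int],
                pixel_size: float, frame_interval: float
                ) -> dict[str, np.ndarray]:
    """Build Hermitian-symmetric spectral masks, one per velocity bin.

    At every non-DC frequency the masks sum to 1 (raised-cosine edges are
    renormalized so partition of unity holds exactly); the DC component
    is assigned to a separate ``background`` mask.
    """
    if shape[0] < 8 or shape[1] < 8:
        raise ConfigError("kymograph must be at least 8x8 for FSDA")
    psi = _implied_angle(shape, pixel_size, frame_interval)

    masks: dict[str, np.ndarray] = {}
    if bins.softness == 0:
        for label, (lo, hi) in bins.bins:
            a, b = math.atan(lo), math.atan(hi)
            if hi == math.inf:
                m = ((psi >= a) & (psi <= b)).astype(float)
            else:
                m = ((psi >= a) & (psi < b)).astype(float)
            masks[label] = m
    else:
        raw: dict[str, np.ndarray] = {}
        for label, (lo, hi) in bins.bins:
            a, b = math.atan(lo), math.atan(hi)
            w = bins.softness * (b - a)
            raw[label] = _soft_interval(psi, a, b, w)
        total = np.zeros(shape)
        for m in raw.values():
            total += m
        total[total == 0] = 1.0
        for label, m in raw.items():
            masks[label] = m / total

    # enforce exact Hermitian symmetry: the Nyquist row/column carry a
    # single slot for the +-f ambiguity, where the implied velocity is
    # sign-ambiguous; averaging with the flipped mask shares it equally
    # and preserves the partition of unity
    for label, m in masks.items():
        flipped = np.roll(np.flip(m, axis=(0, 1)), 1, axis=(0, 1))
        masks[label] = 0.5 * (m + flipped)

    bg = np.zeros(shape)
    bg[0, 0] = 1.0
    for m in masks.values():
        m[0, 0] = 0.0
    masks[BACKGROUND] = bg
    return masks


def decompose(kymo: Kymograph | np.ndarray, bins: VelocityBins,
              pixel_size: float | None = None,
              frame_interval: float | None = None,
              tukey_alpha: float = 0.25) -> FsdaResult:
    """Split a kymograph into velocity-class component images.

    The kymograph is windowed (2D Tukey, ``tukey_alpha``), Fourier
    transformed, multiplied by each bin's spectral mask and inverse
    transformed; the real parts are returned together with per-bin
    spectral energy fractions (which sum to 1 by Parseval).  The sum of
    all components (including background) equals the windowed input to
    numerical precision.
    """
    if isinstance(kymo, Kymograph):
        data = kymo.data
        pixel_size = kymo.pixel_size
        frame_interval = kymo.frame_interval
    else:
        data = np.asarray(kymo, dtype=float)
        if pixel_size is None or frame_interval is None:
            raise ConfigError("pixel_size and frame_interval are required "
                              "for a bare array")
    if not np.all(np.isfinite(data)):
        raise ConfigError("kymograph contains non-finite values")

    n_t, n_s = data.shape
    win = np.outer(signal.windows.tukey(n_t, tukey_alpha),
                   signal.windows.tukey(n_s, tukey_alpha))
    spec = np.fft.fft2(data * win)
    power = np.abs(spec) ** 2
    total_power = power.sum()

    masks = build_masks(bins, (n_t, n_s), pixel_size, frame_interval)
    components: dict[str, np.ndarray] = {}
    energy: dict[str, float] = {}
    for label, mask in masks.items():
        components[label] = np.fft.ifft2(spec * mask).real
        energy[label] = float((mask * power).sum() / total_power) \
            if total_power > 0 else 0.0
    return FsdaResult(components, energy, win, bins, pixel_size,
                      frame_interval)


def velocity_colormap(kymo: Kymograph | np.ndarray, bins: VelocityBins,
                      pixel_size: float | None = None,
                      frame_interval: float | None = None,
                      envelope_sigma: float = 2.0,
                      tie_tol: float = 1e-9) -> tuple[np.ndarray, list[str]]:
    """Label each kymograph pixel by its dominant velocity class.

    Components are envelope-smoothed (Gaussian of ``envelope_sigma`` px
    on the magnitude) and each pixel takes the label of the strongest
    component; ties within ``tie_tol`` of the maximum go to background.
    Returns (label image of int indices, label list); index -1 means
    background.
    """
    res = decompose(kymo, bins, pixel_size, frame_interval)
    labels = res.bins.labels
    env = np.stack([gaussian_filter(np.abs(res.components[lab]),
                                    envelope_sigma) for lab in labels])
    order = np.sort(env, axis=0)
    best = np.argmax(env, axis=0)
    tie = (order[-1] - order[-2]) <= tie_tol if len(labels) > 1 \
        else np.zeros(best.shape, bool)
    out = best.astype(int)
    out[tie] = -1
    return out, labels


@dataclass
class RidgeTrack:
    """A linked ridge in a single-direction component with a velocity fit."""

    t: np.ndarray                  # s
    s: np.ndarray                  # um
    velocity: float                # um/s, slope of the least-squares line
    intercept: float               # um at t = 0
    mean_intensity: float

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def length(self) -> float:
        return float(abs(self.s[-1] - self.s[0]))


def extract_tracks(component: Kymograph | np.ndarray,
                   min_length: float = 1.0, min_duration: float = 1.0,
                   pixel_size: float | None = None,
                   frame_interval: float | None = None,
                   threshold: float | None = None,
                   v_gate: float = 6.0, max_gap: int = 2
                   ) -> list[RidgeTrack]:
    """Detect and fit train trajectories in a single-direction component.

    Per time row, local intensity maxima above ``threshold`` (default:
    row-population mean + 3 s.d. of the component) are linked across rows
    by nearest-neighbour gating (maximum jump ``v_gate`` um/s plus 2 px
    slack, bridging up to ``max_gap`` missing rows); each linked ridge is
    fit with a least-squares line s(t) whose slope is the train velocity.
    Ridges spanning less than ``min_length`` um or ``min_duration`` s are
    discarded.
    """
    if isinstance(component, Kymograph):
        data = component.data
        pixel_size = component.pixel_size
        frame_interval = component.frame_interval
    else:
        data = np.asarray(component, dtype=float)
        if pixel_size is None or frame_interval is None:
            raise ConfigError("pixel_size and frame_interval are required "
                              "for a bare array")
    if data.size == 0:
        raise ConfigError("empty component")
    if threshold is None:
        threshold = float(data.mean() + 3.0 * data.std())

    gate0_px = v_gate * frame_interval / pixel_size + 2.0

    def predict(tr: dict, row: int) -> tuple[float, float]:
        """Predicted column and gate for a track at the given row."""
        gap = row - tr["rows"][-1]
        n_fit = min(len(tr["rows"]), 5)
        if n_fit >= 3:
            v = float(np.polyfit(tr["rows"][-n_fit:], tr["cols"][-n_fit:],
                                 1)[0])
            gate = max(2.5, 0.6 * abs(v) * gap + 1.5)
        else:
            v = tr["v_px"]
            gate = gate0_px * gap
        return tr["cols"][-1] + v * gap, gate

    active: list[dict] = []
    done: list[dict] = []
    for row in range(data.shape[0]):
        peaks, _ = signal.find_peaks(data[row], height=threshold, distance=3)
        peaks = list(peaks.astype(float))
        # globally greedy assignment by prediction error
        cand = []
        for ti, tr in enumerate(active):
            pred, gate = predict(tr, row)
            for j, p in enumerate(peaks):
                d = abs(p - pred)
                if d < gate:
                    cand.append((d, ti, j))
        cand.sort()
        claimed_p: set[int] = set()
        claimed_t: set[int] = set()
        for d, ti, j in cand:
            if ti in claimed_t or j in claimed_p:
                continue
            claimed_t.add(ti)
            claimed_p.add(j)
            tr = active[ti]
            tr["rows"].append(row)
            tr["cols"].append(peaks[j])
            tr["amps"].append(float(data[row, int(peaks[j])]))
            tr["v_px"] = ((tr["cols"][-1] - tr["cols"][0])
                          / (tr["rows"][-1] - tr["rows"][0]))
        still = []
        for tr in active:
            if row - tr["rows"][-1] > max_gap:
                done.append(tr)
            else:
                still.append(tr)
        active = still
        for j, p in enumerate(peaks):
            if j not in claimed_p:
                active.append({"rows": [row], "cols": [p],
                               "amps": [float(data[row, int(p)])],
                               "v_px": 0.0})
    done.extend(active)

    tracks: list[RidgeTrack] = []
    for tr in done:
        if len(tr["rows"]) < 2:
            continue
        t = np.asarray(tr["rows"], dtype=float) * frame_interval
        s = np.asarray(tr["cols"], dtype=float) * pixel_size
        if t[-1] - t[0] < min_duration or abs(s[-1] - s[0]) < min_length:
            continue
        slope, intercept = np.polyfit(t, s, 1)
        tracks.append(RidgeTrack(t, s, float(slope), float(intercept),
                                 float(np.mean(tr["amps"]))))
    tracks.sort(key=lambda tr: tr.t[0])
    return tracks
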