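"""Event-level statistics: localization, colocalization, pauses, gliding.

This module carries the statistical evidence chain from image-derived
tracks to conclusions: subpixel 2D Gaussian localization of diffraction
limited spots, correlation of bead and train trajectories, a
Kolmogorov-Smirnov colocalization test against a randomized null,
detection of train pauses and of cell-body gliding onsets, the
pause-to-gliding lag-time analysis with its exponential fit, a
Monte-Carlo test of the independence of pausing and gliding, and the
pause-intensity profile along the flagellum used for Ca2+ dose
comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.ndimage import label as nd_label

from .config import ConfigError
from .kymo import Kymograph

__all__ = [
    "Track", "PauseEvent", "GlideEvent", "FitError",
    "localize_gaussian", "correlate_tracks", "colocalization_test",
    "detect_pauses", "detect_gliding_onset", "lag_time_analysis",
    "independence_test", "pause_profile",
]

ANTEROGRADE = "anterograde"
RETROGRADE = "retrograde"
UNKNOWN = "unknown"


class FitError(RuntimeError):
    """A nonlinear fit failed to converge or produced a degenerate result."""


@dataclass
class Track:
    """Time-stamped positions of one entity (bead, train or cell body)."""

    id: int
    entity: str                    # "bead" | "train" | "cell_body"
    t: np.ndarray                  # s, strictly increasing
    position: np.ndarray           # um along the path (1D)
    intensity: np.ndarray | None = None
    localization_sd: np.ndarray | None = None
    direction: str = UNKNOWN
    flagellum: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.position.shape[:1]:
            raise ConfigError("t and position must be 1D and equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ConfigError("track times must be strictly increasing")
        if not np.all(np.isfinite(self.position)):
            raise ConfigError("track positions must be finite")


@dataclass
class PauseEvent:
    flagellum: int
    position: float                # um
    t_start: float
    t_end: float
    prior_direction: str = UNKNOWN
    track_id: int = -1

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class GlideEvent:
    onset: float                   # s
    direction: int                 # +1 / -1
    speed: float                   # um/s, >= 0
    t_end: float = math.nan
    pause_ids: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# localization

def _gauss2d(coords, amp, r0, c0, sigma, offset):
    r, c = coords
    return (amp * np.exp(-((r - r0) ** 2 + (c - c0) ** 2) / (2 * sigma ** 2))
            + offset)


def localize_gaussian(frame: np.ndarray, roi_center: tuple[int, int],
                      roi_halfwidth: int, max_iter: int = 500
                      ) -> tuple[tuple[float, float], float, float]:
    """Subpixel localization of one spot by symmetric 2D Gaussian fitting.

    Fits amp * exp(-((r-r0)^2+(c-c0)^2) / 2 sigma^2) + offset by
    nonlinear least squares inside the square ROI centred at
    ``roi_center`` (row, col) with half-width ``roi_halfwidth`` px.

    Returns ((row, col) subpixel centre, fitted sigma, amplitude).
    Raises :class:`FitError` on non-convergence or a non-positive
    amplitude (no spot above background).
    """
    frame = np.asarray(frame, dtype=float)
    r0, c0 = int(roi_center[0]), int(roi_center[1])
    h = int(roi_halfwidth)
    if h < 2:
        raise ConfigError("roi_halfwidth must be >= 2")
    if (r0 - h < 0 or c0 - h < 0 or r0 + h >= frame.shape[0]
            or c0 + h >= frame.shape[1]):
        raise ConfigError("ROI extends outside the frame")
    roi = frame[r0 - h:r0 + h + 1, c0 - h:c0 + h + 1]
    rr, cc = np.mgrid[r0 - h:r0 + h + 1, c0 - h:c0 + h + 1]

    offset0 = float(roi.min())
    amp0 = float(roi.max() - offset0)
    if amp0 <= 0:
        raise FitError("ROI has no intensity above its minimum")
    w = roi - offset0
    r_init = float((rr * w).sum() / w.sum())
    c_init = float((cc * w).sum() / w.sum())
    p0 = [amp0, r_init, c_init, max(1.0, h / 3.0), offset0]
    try:
        popt, _ = optimize.curve_fit(
            _gauss2d, (rr.ravel(), cc.ravel()), roi.ravel(), p0=p0,
            maxfev=max_iter * len(p0))
    except RuntimeError as exc:
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    amp, rfit, cfit, sigma, offset = popt
    if amp <= 0:
        raise FitError("fitted amplitude is not above background")
    if not (r0 - h <= rfit <= r0 + h and c0 - h <= cfit <= c0 + h):
        raise FitError("fitted centre escaped the ROI")
    return (float(rfit), float(cfit)), float(abs(sigma)), float(amp)


# ---------------------------------------------------------------------------
# correlation / colocalization

def correlate_tracks(a: Track, b: Track, window: float | None = None
                     ) -> tuple[float, int]:
    """Pearson correlation of two tracks over nearest-time paired samples.

    Samples are paired greedily by nearest time within half the median
    frame interval of ``a`` (or ``window`` if given); at least 5 pairs
    are required.  Returns (r, number of pairs).
    """
    tol = window if window is not None else float(np.median(np.diff(a.t)) / 2)
    idx = np.searchsorted(b.t, a.t)
    pairs_a, pairs_b = [], []
    for i, t in enumerate(a.t):
        for j in (idx[i] - 1, idx[i]):
            if 0 <= j < b.t.size and abs(b.t[j] - t) <= tol:
                pairs_a.append(a.position[i])
                pairs_b.append(b.position[j])
                break
    n = len(pairs_a)
    if n < 5:
        raise ConfigError(f"only {n} overlapping samples; need >= 5")
    pa, pb = np.asarray(pairs_a), np.asarray(pairs_b)
    if pa.std() == 0 or pb.std() == 0:
        raise ConfigError("zero variance in one of the tracks")
    r, _ = stats.pearsonr(pa, pb)
    return float(r), n


def colocalization_test(bead: Track, trains: list[Track], n_null: int = 100,
                        seed: int | None = None, stride: int = 1,
                        acquisition: tuple[float, float] | None = None
                        ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """KS test of bead-to-nearest-train distances against a randomized null.

    For every evaluated bead sample, the observed distance is
    ``|bead - nearest train moving in the same direction|`` (bead
    direction from the sign of its local displacement).  The null pools
    ``n_null`` randomizations in which every train track's start time is
    independently resampled uniformly (circularly within the acquisition
    window) with its geometry preserved, which destroys temporal
    registration between bead and trains but keeps all marginal
    statistics.  ``stride`` thins the evaluated bead samples to reduce
    serial correlation (the KS test assumes independent draws).

    Returns (observed distances, pooled null distances, KS statistic, p).
    """
    if n_null < 10:
        raise ConfigError("n_null must be >= 10")
    if not trains:
        raise ConfigError("need at least one train track")
    rng = np.random.default_rng(seed)
    t0 = acquisition[0] if acquisition else min(tr.t[0] for tr in trains)
    t1 = acquisition[1] if acquisition else max(tr.t[-1] for tr in trains)
    span = t1 - t0
    if span <= 0:
        raise ConfigError("empty acquisition window")

    bead_v = np.gradient(bead.position, bead.t)
    samples = np.arange(0, bead.t.size, max(int(stride), 1))

    def distances(shifts: np.ndarray) -> np.ndarray:
        out = []
        for i in samples:
            t, pos, v = bead.t[i], bead.position[i], bead_v[i]
            want = ANTEROGRADE if v >= 0 else RETROGRADE
            best = np.inf
            for tr, dt_shift in zip(trains, shifts):
                if tr.direction != want:
                    continue
                # circular time shift of the train's schedule: the shifted
                # train at absolute time t matches the original at tq
                # (identity, without wrapping, for the observed pass)
                tq = t if dt_shift == 0 else (t - dt_shift - t0) % span + t0
                if tr.t[0] <= tq <= tr.t[-1]:
                    p = float(np.interp(tq, tr.t, tr.position))
                    best = min(best, abs(pos - p))
            if np.isfinite(best):
                out.append(best)
        return np.asarray(out)

    observed = distances(np.zeros(len(trains)))
    if observed.size == 0:
        raise ConfigError("no bead sample had a same-direction train")
    null_pool = np.concatenate([
        distances(rng.uniform(0.0, span, size=len(trains)))
        for _ in range(n_null)])
    ks, p = stats.ks_2samp(observed, null_pool)
    return observed, null_pool, float(ks), float(p)


# ---------------------------------------------------------------------------
# pauses

def _central_velocity(t: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Central difference over a 3-sample window (one-sided at the ends)."""
    return np.gradient(x, t)


def detect_pauses(tracks: list[Track] | Kymograph,
                  v_thresh: float = 0.2, min_duration: float = 0.4,
                  acquisition_time: float | None = None,
                  n_flagella: int = 2,
                  component_percentile: float = 90.0
                  ) -> tuple[list[PauseEvent], dict[str, float]]:
    """Detect train pauses and estimate the pausing frequency.

    Track route: a pause is a maximal interval with |instantaneous
    velocity| < ``v_thresh`` (central difference over 3 samples) lasting
    at least ``min_duration`` within a track that moves before or after;
    tracks immotile for the whole acquisition are excluded.  The prior
    direction is taken from the preceding moving segment.

    Kymograph route (a paused-train component from FSDA): bright pixels
    above the ``component_percentile`` of the component are grouped into
    connected regions, each scored as one pause.

    Frequencies reported:
      ``frequency``           events / acquisition time (per cell)
      ``frequency_per_flagellum``   the same divided by ``n_flagella``
      ``frequency_corrected`` censoring-corrected rate accounting for
        pauses too short to detect, assuming exponential durations: with
        detectability cutoff c, the detected fraction is exp(-c/tau) and
        tau is estimated from the mean detected excess duration
        (memorylessness).
    """
    if isinstance(tracks, Kymograph):
        return _pauses_from_component(tracks, min_duration,
                                      component_percentile, n_flagella)
    events: list[PauseEvent] = []
    t_min, t_max = np.inf, -np.inf
    dt_med = None
    for tr in tracks:
        if tr.t.size < 3:
            continue
        t_min = min(t_min, tr.t[0])
        t_max = max(t_max, tr.t[-1])
        dt = float(np.median(np.diff(tr.t)))
        dt_med = dt if dt_med is None else min(dt_med, dt)
        v = _central_velocity(tr.t, tr.position)
        slow = np.abs(v) < v_thresh
        if slow.all():
            continue    # immotile for the whole acquisition: excluded
        lab, n_lab = nd_label(slow)
        for k in range(1, n_lab + 1):
            idx = np.flatnonzero(lab == k)
            dur = tr.t[idx[-1]] - tr.t[idx[0]]
            if dur < min_duration:
                continue
            prior = UNKNOWN
            before = np.flatnonzero(~slow[:idx[0]])
            if before.size:
                prior = ANTEROGRADE if v[before[-1]] > 0 else RETROGRADE
            events.append(PauseEvent(
                tr.flagellum, float(np.median(tr.position[idx])),
                float(tr.t[idx[0]]), float(tr.t[idx[-1]]), prior, tr.id))
    if acquisition_time is None:
        acquisition_time = (t_max - t_min) if t_max > t_min else math.nan
    freq = len(events) / acquisition_time if acquisition_time else math.nan

    freq_corr = freq
    if events and dt_med and acquisition_time:
        # Censoring correction for pauses too short to detect, assuming
        # exponential durations.  A pause spanning k frozen frames is
        # measured (via the 3-sample central-difference stencil) as a
        # span of exactly (k - 3)*dt, so detection requires
        # k >= ceil(min_duration/dt) + 3; averaging over the uniform
        # start phase, the effective duration cutoff is
        # c_eff = (ceil(min_duration/dt) + 3)*dt - dt/2, the detected
        # fraction is exp(-c_eff/tau), and by memorylessness the mean
        # measured excess over min_duration estimates tau - dt/2.
        durations = np.array([e.duration for e in events])
        tau = float((durations - min_duration).mean()) + dt_med / 2.0
        k_min = math.ceil(min_duration / dt_med - 1e-9) + 3
        c_eff = k_min * dt_med - dt_med / 2.0
        if tau > 0:
            freq_corr = freq / math.exp(-c_eff / tau)
    stats_out = {
        "n_events": float(len(events)),
        "acquisition_time": float(acquisition_time),
        "frequency": float(freq),
        "frequency_per_flagellum": float(freq / n_flagella),
        "frequency_corrected": float(freq_corr),
    }
    return events, stats_out


def _pauses_from_component(component: Kymograph, min_duration: float,
                           percentile: float, n_flagella: int
                           ) -> tuple[list[PauseEvent], dict[str, float]]:
    data = component.data
    thr = np.percentile(data, percentile)
    mask = data > thr
    lab, n_lab = nd_label(mask)
    events: list[PauseEvent] = []
    for k in range(1, n_lab + 1):
        rows, cols = np.nonzero(lab == k)
        dur = (rows.max() - rows.min()) * component.frame_interval
        if dur < min_duration:
            continue
        events.append(PauseEvent(
            0, float(np.median(cols)) * component.pixel_size,
            rows.min() * component.frame_interval,
            rows.max() * component.frame_interval, UNKNOWN))
    acq = component.duration
    freq = len(events) / acq if acq else math.nan
    return events, {
        "n_events": float(len(events)),
        "acquisition_time": float(acq),
        "frequency": float(freq),
        "frequency_per_flagellum": float(freq / n_flagella),
        "frequency_corrected": float(freq),
    }


# ---------------------------------------------------------------------------
# gliding

def detect_gliding_onset(body: Track, v_thresh: float = 0.3,
                         min_run: float = 0.3) -> list[GlideEvent]:
    """Detect gliding onsets in a cell-body displacement track.

    An event is a maximal interval with |velocity| >= ``v_thresh``
    covering at least ``min_run`` um; the onset is its first sample, the
    speed the slope of a least-squares line over the interval, the
    direction the slope's sign.
    """
    if body.t.size < 3:
        return []
    v = _central_velocity(body.t, body.position)
    moving = np.abs(v) >= v_thresh
    lab, n_lab = nd_label(moving)
    events: list[GlideEvent] = []
    for k in range(1, n_lab + 1):
        idx = np.flatnonzero(lab == k)
        run = abs(body.position[idx[-1]] - body.position[idx[0]])
        if run < min_run or idx.size < 2:
            continue
        slope = np.polyfit(body.t[idx], body.position[idx], 1)[0]
        events.append(GlideEvent(float(body.t[idx[0]]),
                                 1 if slope >= 0 else -1,
                                 float(abs(slope)),
                                 float(body.t[idx[-1]])))
    return events


def lag_time_analysis(pauses: list[PauseEvent], glides: list[GlideEvent],
                      leading_flagellum: int | None = None,
                      flagellum_signs: dict[int, int] | None = None
                      ) -> dict[str, object]:
    """Lag between the last retrograde pause and each gliding onset.

    For every onset the lag is ``onset - t_start`` of the most recent
    retrograde-direction pause in the leading flagellum (the flagellum
    whose anchors pull in the observed gliding direction, via
    ``flagellum_signs``; or a fixed ``leading_flagellum``).  Onsets with
    no preceding retrograde pause are flagged and excluded.

    The exponential fit is by maximum likelihood on the lags themselves
    (bin-free); for an exponential the ML mean is the sample mean.
    Returns lags, fitted tau, sample mean and SEM, and excluded onsets.
    """
    if not glides:
        raise ConfigError("need at least one glide event")
    signs = flagellum_signs or {0: 1, 1: -1}
    lags: list[float] = []
    excluded: list[GlideEvent] = []
    for g in glides:
        if leading_flagellum is not None:
            lead = leading_flagellum
        else:
            lead = next((f for f, s in signs.items() if s == g.direction), 0)
        candidates = [p for p in pauses
                      if p.prior_direction == RETROGRADE
                      and p.flagellum == lead
                      and p.t_start <= g.onset]
        if not candidates:
            excluded.append(g)
            continue
        last = max(candidates, key=lambda p: p.t_start)
        lags.append(g.onset - last.t_start)
    arr = np.asarray(lags)
    out: dict[str, object] = {
        "lags": arr,
        "n": int(arr.size),
        "excluded": excluded,
    }
    if arr.size:
        tau = float(arr.mean())        # exponential MLE
        out.update({"tau": tau, "mean": tau,
                    "sem": float(arr.std(ddof=1) / math.sqrt(arr.size))
                    if arr.size > 1 else math.nan})
    else:
        out.update({"tau": math.nan, "mean": math.nan, "sem": math.nan})
    return out


def independence_test(mean_lag: float, n: int, mean_interpause: float,
                      n_mc: int = 10 ** 6, seed: int | None = None) -> float:
    """Monte-Carlo test of pause/gliding-onset independence.

    Null hypothesis: gliding onsets are unrelated to pauses, so each lag
    is exponential with mean equal to the observed mean inter-pause
    interval.  The p-value is the (plus-one corrected) fraction of
    ``n_mc`` simulated n-sample mean lags at or below the observed mean
    lag (one-sided).
    """
    if n < 2:
        raise ConfigError("n must be >= 2")
    if n_mc < 10 ** 4:
        raise ConfigError("n_mc must be >= 1e4")
    if mean_lag <= 0 or mean_interpause <= 0:
        raise ConfigError("means must be positive")
    rng = np.random.default_rng(seed)
    # the mean of n iid Exp(mean m) draws is Gamma(n, m/n)
    sim_means = rng.gamma(shape=n, scale=mean_interpause / n, size=n_mc)
    hits = int(np.count_nonzero(sim_means <= mean_lag))
    return (hits + 1) / (n_mc + 1)


# ---------------------------------------------------------------------------
# Ca2+ pause profile

def pause_profile(pause_component: Kymograph, flagellum_length: float,
                  n_bins: int = 20, background_percentile: float = 50.0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged paused-train intensity vs normalized arc length.

    Pixels at or below the ``background_percentile`` of the component are
    treated as background and excluded (set to zero) before averaging
    over time; intensities are binned over normalized position [0, 1].

    Returns (bin centres, mean intensity per bin).
    """
    if flagellum_length <= 0:
        raise ConfigError("flagellum_length must be > 0")
    data = pause_component.data.copy()
    if data.size == 0:
        raise ConfigError("empty pause component")
    thr = np.percentile(data, background_percentile)
    data[data <= thr] = 0.0
    profile_px = data.mean(axis=0)
    s = np.arange(profile_px.size) * pause_component.pixel_size
    x = s / flagellum_length
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    out = np.zeros(n_bins)
    for i in range(n_bins):
        m = (x >= edges[i]) & (x < edges[i + 1])
        out[i] = profile_px[m].mean() if m.any() else 0.0
    return centres, out
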