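"""Optical-trap trace analysis: calibration, event scoring, drag fits.

Units are fixed throughout: displacement x in nm, trap stiffness kappa
in pN/nm, drag constant gamma in pN.s/um (so the relaxation time is
tau = gamma / (1000 * kappa) seconds), forces in pN.

Event taxonomy follows the fixed-trap assay: an excursion from the trap
center whose velocity plateaus for at least 100 ms at its peak is a
*stall*; a returning excursion whose plateau is shorter than 100 ms is a
*release*; a bead pulled beyond the detector's linear range (+-200 nm,
i.e. +-80 pN at kappa = 0.4 pN/nm) is an *escape*.  The drag constant of
the bead-membrane-train complex follows from the exponential recoil to
the trap center after motor detachment (gamma = kappa * tau) or from the
relaxation after each step of a square-wave trap oscillation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .config import ConfigError
from .trap_sim import TrapTrace

__all__ = [
    "ForceEvent", "DragFit", "StationarityError",
    "calibrate_stiffness", "classify_events", "peak_force_stats",
    "fit_recoil", "oscillation_drag", "motor_count", "drag_force",
]

#: conversion from kappa*tau (pN/nm * s) to gamma in pN.s/um
PN_PER_NM_S_TO_PN_S_PER_UM = 1000.0

STALL_MIN_S = 0.1


class StationarityError(RuntimeError):
    """Calibration segment is not stationary thermal motion."""


@dataclass
class ForceEvent:
    type: str                      # "stall" | "release" | "escape"
    direction: str                 # "anterograde" | "retrograde" | "unknown"
    peak_force: float              # pN
    stall_duration: float          # s at the plateau (0 for escapes)
    t_start: float
    t_end: float


@dataclass
class DragFit:
    gamma: float                   # pN.s/um
    tau: float                     # s
    r_squared: float
    segment: tuple[float, float]   # (t_start, t_end) of the fitted data
    gamma_sd: float = math.nan     # over pooled fits, where applicable
    gamma_sem: float = math.nan


# ---------------------------------------------------------------------------
# calibration

def calibrate_stiffness(trace: TrapTrace) -> float:
    """Trap stiffness from the equipartition theorem.

    kappa = k_BT / var(x) on a motor-free segment of at least 1 s.
    Stationarity is checked by the split-half variance ratio, which must
    lie in [0.5, 2]; a drifting or transport-contaminated segment raises
    :class:`StationarityError`.
    """
    x = np.asarray(trace.x, dtype=float)
    if trace.t[-1] - trace.t[0] < 1.0:
        raise ConfigError("calibration segment must be >= 1 s")
    half = x.size // 2
    v1, v2 = x[:half].var(), x[half:].var()
    ratio = v1 / v2 if v2 > 0 else np.inf
    if not 0.5 <= ratio <= 2.0:
        raise StationarityError(
            f"split-half variance ratio {ratio:.2f} outside [0.5, 2]")
    pooled_sd = math.sqrt(0.5 * (v1 + v2))
    if abs(x[:half].mean() - x[half:].mean()) > pooled_sd:
        raise StationarityError(
            "split-half mean shift exceeds the thermal s.d. (drift or "
            "active transport in the calibration segment)")
    return float(trace.k_bt / x.var())


# ---------------------------------------------------------------------------
# event classification

def _baseline(x: np.ndarray, sigma_th: float) -> float:
    """Trap-centre estimate: mode of the trace within +-2 thermal s.d."""
    med = np.median(x)
    sel = x[np.abs(x - med) <= 2 * sigma_th]
    if sel.size < 10:
        return float(med)
    hist, edges = np.histogram(sel, bins=40)
    k = int(np.argmax(hist))
    return float(0.5 * (edges[k] + edges[k + 1]))


def _plateau_duration(t: np.ndarray, dev: np.ndarray, smooth: np.ndarray,
                      start: int, end: int, peak_idx: int) -> float:
    """Dwell at the excursion peak, measured robustly under thermal noise.

    The plateau end is the last sample of the contiguous run around the
    peak where the smoothed deviation stays above 75% of the peak level
    (the recoil crosses this quickly).  The plateau start is found by a
    two-segment change-point fit (rising ramp, then constant level) over
    the approach, which averages the noise over whole segments instead
    of relying on a single-window velocity estimate.
    """
    peak = abs(smooth[peak_idx])
    hi_band = np.abs(smooth[start:end + 1]) >= 0.75 * peak
    k = peak_idx - start
    lo = k
    while lo > 0 and hi_band[lo - 1]:
        lo -= 1
    hi = k
    while hi < hi_band.size - 1 and hi_band[hi + 1]:
        hi += 1
    i75, j75 = start + lo, start + hi
    if j75 <= i75 + 1:
        return 0.0
    # change-point: dev is ~linear on [start, knot], ~constant on [knot, j75]
    tt = t[start:j75 + 1] - t[start]
    yy = dev[start:j75 + 1]
    n_seg = tt.size
    if n_seg < 6:
        return 0.0
    stride = max(n_seg // 200, 1)
    best_sse, best_knot = np.inf, n_seg - 1
    for knot in range(2, n_seg - 1, stride):
        t1, y1 = tt[:knot + 1], yy[:knot + 1]
        a = np.polyfit(t1, y1, 1)
        sse1 = float(((y1 - np.polyval(a, t1)) ** 2).sum())
        y2 = yy[knot:]
        sse2 = float(((y2 - y2.mean()) ** 2).sum())
        if sse1 + sse2 < best_sse:
            best_sse, best_knot = sse1 + sse2, knot
    return float(t[j75] - (t[start] + tt[best_knot]))


def classify_events(trace: TrapTrace, stall_min: float = STALL_MIN_S,
                    v_window: float = 0.02, range_nm: float | None = None,
                    force_cap: float = 80.0, excursion_sd: float = 5.0
                    ) -> list[ForceEvent]:
    """Segment a fixed-trap trace into stall / release / escape events.

    Excursions are intervals where |x - baseline| exceeds
    ``excursion_sd`` thermal standard deviations, extended to the
    surrounding baseline crossings.  Within each excursion the dwell at
    the peak is measured (see :func:`_plateau_duration`; ``v_window`` is
    the smoothing window used for level crossings); a dwell of at least
    ``stall_min`` scores a stall, a shorter one a release, and crossing
    the detector linear range (``range_nm``, default from the trace
    header; equivalently kappa|x| > force_cap) scores an escape.  Peak
    force is kappa * max|x - baseline| within the event.

    Direction uses the trace's flagellar ``orientation`` metadata
    ("positive" meaning positive x is retrograde); without it events are
    scored with direction "unknown".
    """
    if trace.stiffness <= 0:
        raise ConfigError("trace must carry a calibrated stiffness")
    if v_window >= stall_min:
        raise ConfigError("v_window must be < stall_min")
    kappa = trace.stiffness
    x = np.asarray(trace.x, dtype=float)
    t = np.asarray(trace.t, dtype=float)
    dt = trace.dt
    rng_nm = range_nm if range_nm is not None else trace.detector_range
    sigma_th = math.sqrt(trace.k_bt / kappa)
    base = _baseline(x, sigma_th)
    dev = x - base

    above = np.abs(dev) > excursion_sd * sigma_th
    if not above.any():
        return []
    near = np.abs(dev) < 2.0 * sigma_th
    n_w = max(int(round(v_window / dt)), 2)
    kern = np.ones(n_w) / n_w
    smooth = np.convolve(dev, kern, mode="same")

    from scipy.signal import find_peaks

    def _sub_segments(start: int, end: int) -> list[tuple[int, int]]:
        """Split a merged excursion at valleys between prominent peaks."""
        seg = np.abs(smooth[start:end + 1])
        pk, _ = find_peaks(seg, prominence=8.0 * sigma_th,
                           height=excursion_sd * sigma_th,
                           distance=max(n_w, 2))
        if pk.size <= 1:
            return [(start, end)]
        bounds = [start]
        for a, b in zip(pk[:-1], pk[1:]):
            bounds.append(start + a + int(np.argmin(seg[a:b + 1])))
        bounds.append(end)
        return [(bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1)]

    events: list[ForceEvent] = []
    i = 0
    n = x.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        start = i
        while start > 0 and not near[start - 1]:
            start -= 1
        end = i
        while end < n - 1 and not near[end + 1]:
            end += 1
        for s0, s1 in _sub_segments(start, end):
            peak_idx = s0 + int(np.argmax(np.abs(dev[s0:s1 + 1])))
            peak_dev = dev[peak_idx]
            peak_force = kappa * abs(peak_dev)

            if abs(peak_dev) > rng_nm or peak_force > force_cap:
                ev_type, plateau_dur = "escape", 0.0
            else:
                plateau_dur = _plateau_duration(t, dev, smooth, s0, s1,
                                                peak_idx)
                ev_type = "stall" if plateau_dur >= stall_min else "release"

            if trace.orientation == "positive":
                direction = "retrograde" if peak_dev > 0 else "anterograde"
            elif trace.orientation == "negative":
                direction = "anterograde" if peak_dev > 0 else "retrograde"
            else:
                direction = "unknown"
            events.append(ForceEvent(ev_type, direction, float(peak_force),
                                     float(plateau_dur), float(t[s0]),
                                     float(t[s1])))
        i = end + 1
    return events


def peak_force_stats(events: list[ForceEvent], bin_width: float = 2.5
                     ) -> dict[str, dict[str, object]]:
    """Peak-force histograms and summary stats per (direction, type).

    Returns a dict keyed ``direction/type`` with mean, SEM, n, histogram
    (counts, bin edges of ``bin_width`` pN) plus per-direction event-type
    fractions under keys ``direction/fractions``.
    """
    if not events:
        raise ConfigError("empty event list")
    out: dict[str, dict[str, object]] = {}
    directions = sorted({e.direction for e in events})
    for d in directions:
        d_events = [e for e in events if e.direction == d]
        for ty in ("stall", "release", "escape"):
            sel = [e.peak_force for e in d_events if e.type == ty]
            if not sel:
                continue
            arr = np.asarray(sel)
            hi = max(arr.max(), bin_width)
            edges = np.arange(0.0, hi + bin_width, bin_width)
            counts, _ = np.histogram(arr, bins=edges)
            out[f"{d}/{ty}"] = {
                "n": int(arr.size),
                "mean": float(arr.mean()),
                "sem": float(arr.std(ddof=1) / math.sqrt(arr.size))
                if arr.size > 1 else math.nan,
                "hist_counts": counts,
                "hist_edges": edges,
            }
        n_d = len(d_events)
        out[f"{d}/fractions"] = {
            ty: sum(e.type == ty for e in d_events) / n_d
            for ty in ("stall", "release", "escape")}
    return out


# ---------------------------------------------------------------------------
# drag fits

def _exp_decay(t, x0, tau, baseline):
    return x0 * np.exp(-t / tau) + baseline


def fit_recoil(t: np.ndarray, x: np.ndarray, kappa: float,
               min_r2: float = 0.8) -> DragFit:
    """Fit an exponential recoil segment and derive the drag constant.

    ``t``/``x`` is the trace segment starting at motor detachment (time
    origin arbitrary); fits x(t) = x0 exp(-t/tau) + baseline by least
    squares and returns gamma = kappa * tau * 1000 (pN.s/um).  Rejects
    non-decaying segments, segments with fewer than 10 samples, and fits
    with R^2 below ``min_r2``.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.size < 10:
        raise ConfigError("recoil segment needs >= 10 samples")
    tt = t - t[0]
    x0_guess = x[0]
    if abs(x[0]) <= abs(x[-1]):
        raise FitRejected("segment does not decay toward the baseline")
    tau_guess = max(tt[-1] / 3.0, tt[1])
    try:
        popt, _ = optimize.curve_fit(
            _exp_decay, tt, x, p0=[x0_guess, tau_guess, 0.0],
            bounds=([-np.inf, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=5000)
    except RuntimeError as exc:
        raise FitRejected(f"recoil fit did not converge: {exc}") from exc
    x0, tau, baseline = popt
    resid = x - _exp_decay(tt, *popt)
    ss_tot = float(((x - x.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0
    if r2 < min_r2:
        raise FitRejected(f"recoil fit R^2 = {r2:.3f} < {min_r2}")
    gamma = kappa * tau * PN_PER_NM_S_TO_PN_S_PER_UM
    return DragFit(float(gamma), float(tau), float(r2),
                   (float(t[0]), float(t[-1])))


class FitRejected(RuntimeError):
    """A drag fit was rejected (non-decaying, non-converged or poor R^2)."""


def oscillation_drag(trace: TrapTrace, step_times: np.ndarray,
                     amplitude: float, kappa: float,
                     min_r2: float = 0.5) -> DragFit:
    """Drag constant from square-wave trap oscillation.

    After each trap step at ``step_times`` the bead relaxes toward the
    new trap center with time constant tau = gamma/kappa; each step's
    relaxation is fitted with an exponential and the per-step gamma
    values are pooled (mean +- SD / SEM).  ``amplitude`` is the
    peak-to-peak trap step in nm.  Steps must be at least ~3 tau apart.
    """
    step_times = np.asarray(step_times, dtype=float)
    if step_times.size < 1:
        raise ConfigError("no trap steps given")
    t = trace.t
    x = trace.x
    gammas, taus = [], []
    intervals = np.diff(np.concatenate([step_times, [t[-1]]]))
    for t_step, span in zip(step_times, intervals):
        sel = (t >= t_step) & (t < t_step + span)
        ts, xs = t[sel], x[sel]
        if ts.size < 10:
            continue
        # relax toward the new trap centre: fit deviation from the tail
        target = float(np.mean(xs[-max(ts.size // 5, 2):]))
        dev = xs - target
        if abs(dev[0]) < amplitude * 0.2:
            continue
        try:
            fit = fit_recoil(ts, dev, kappa, min_r2=min_r2)
        except (FitRejected, ConfigError):
            continue
        if fit.tau * 3.0 > span:
            raise ConfigError("trap steps shorter than ~3 relaxation times")
        gammas.append(fit.gamma)
        taus.append(fit.tau)
    if not gammas:
        raise ConfigError("no usable relaxation segments found")
    g = np.asarray(gammas)
    return DragFit(float(g.mean()), float(np.mean(taus)), math.nan,
                   (float(step_times[0]), float(t[-1])),
                   gamma_sd=float(g.std(ddof=1)) if g.size > 1 else math.nan,
                   gamma_sem=float(g.std(ddof=1) / math.sqrt(g.size))
                   if g.size > 1 else math.nan)


def recoil_fits(trace: TrapTrace, events: list[ForceEvent],
                window: float = 0.1, min_r2: float = 0.8) -> list[DragFit]:
    """Fit the post-detachment recoil of every stall/release event.

    The recoil segment starts at the last sample (within the event)
    where the displacement still exceeds 70% of the event peak and runs
    for ``window`` seconds; escapes are skipped, and events whose fit is
    rejected are silently dropped.
    """
    out: list[DragFit] = []
    x = np.asarray(trace.x, dtype=float)
    t = np.asarray(trace.t, dtype=float)
    for e in events:
        if e.type == "escape":
            continue
        sel = np.flatnonzero((t >= e.t_start) & (t <= e.t_end))
        if sel.size < 5:
            continue
        peak = np.abs(x[sel]).max()
        high = sel[np.abs(x[sel]) >= 0.7 * peak]
        start = t[high[-1]] if high.size else e.t_end
        seg = (t >= start) & (t <= start + window)
        if seg.sum() < 10:
            continue
        try:
            out.append(fit_recoil(t[seg], x[seg], trace.stiffness,
                                  min_r2=min_r2))
        except (FitRejected, ConfigError):
            continue
    return out


# ---------------------------------------------------------------------------
# derived quantities

def motor_count(peak_force: float, f_single: float) -> int:
    """Minimum number of engaged motors: ceil(F_peak / f_single)."""
    if f_single <= 0:
        raise ConfigError("single-motor force must be > 0")
    if peak_force < 0:
        raise ConfigError("peak force must be >= 0")
    return int(math.ceil(peak_force / f_single))


def drag_force(gamma: float, v: float) -> float:
    """Viscous resistive force gamma * v (pN for gamma in pN.s/um, v in um/s)."""
    if gamma < 0:
        raise ConfigError("gamma must be >= 0")
    return gamma * v
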