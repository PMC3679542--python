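"""Overdamped Langevin simulation of a bead in a fixed optical trap.

The bead obeys

    x(t + dt) = x + dt * (F_motor - kappa * x) / gamma + sqrt(2 kBT dt / gamma) * N(0, 1)

(Euler-Maruyama; x in nm, kappa in pN/nm, gamma converted to pN.s/nm).
Motor runs are generated as a renewal process: after an exponential idle
period a motor engages and its force ramps linearly until the trap load
kappa*|x| reaches a stall force drawn from N(mean, sd); the motor then
holds (stall plateau) for an exponential dwell before detaching, upon
which the bead recoils exponentially to the trap center with time
constant gamma/kappa.  A configurable fraction of events instead keeps
ramping past the detector's linear range and is labelled an escape.
Every event is labelled with its true type, direction and peak force.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .config import ConfigError, TrapSimConfig

__all__ = ["TrapTrace", "TrapEventLabel", "simulate_trap_trace",
           "simulate_recoil"]


@dataclass
class TrapTrace:
    """Uniformly sampled trap displacement record.

    x is the bead displacement from the trap center in nm; stiffness in
    pN/nm, so force = stiffness * x in pN.
    """

    t: np.ndarray                  # s
    x: np.ndarray                  # nm
    stiffness: float               # pN/nm
    sampling_rate: float           # Hz
    k_bt: float = 4.11             # pN.nm
    detector_range: float = 200.0  # nm
    orientation: str | None = None # which displacement sign is anterograde
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate


@dataclass
class TrapEventLabel:
    """Ground-truth label for one motor run in a simulated trace."""

    type: str                      # "stall" | "release" | "escape"
    direction: str                 # "anterograde" | "retrograde"
    t_start: float
    t_end: float
    peak_force: float              # pN, true kappa*|x| maximum
    stall_duration: float          # s spent at the plateau


def simulate_trap_trace(config: TrapSimConfig, duration: float = 20.0
                        ) -> tuple[TrapTrace, list[TrapEventLabel]]:
    """Simulate a fixed-trap displacement record with labelled motor runs.

    Returns the trace and the list of ground-truth event labels.  With
    ``event_rate == 0`` the trace is pure thermal motion in the trap
    (the motor-free record used for equipartition calibration), computed
    by a vectorized linear recursion.
    """
    cfg = config
    dt = cfg.dt
    n = int(round(duration * cfg.sampling_rate))
    if n < 2:
        raise ConfigError("duration too short for the sampling rate")
    kappa = cfg.stiffness
    gamma = cfg.drag_pn_s_per_nm          # pN.s/nm
    a = 1.0 - dt * kappa / gamma
    noise_sd = np.sqrt(2.0 * cfg.k_bt * dt / gamma)
    rng = np.random.default_rng(cfg.seed)

    if cfg.event_rate == 0:
        # x_{i+1} = a x_i + noise: vectorized via cumulative recursion
        w = rng.normal(0.0, noise_sd, size=n)
        x = np.empty(n)
        x[0] = 0.0
        from scipy.signal import lfilter
        x[1:] = lfilter([1.0], [1.0, -a], w[:-1])
        t = np.arange(n) * dt
        return TrapTrace(t, x, kappa, cfg.sampling_rate, cfg.k_bt,
                         cfg.detector_range, orientation="positive"), []

    w = rng.normal(0.0, noise_sd, size=n)
    x = np.zeros(n)
    labels: list[TrapEventLabel] = []

    IDLE, RAMP, STALL = 0, 1, 2
    state = IDLE
    f_motor = 0.0
    next_event = rng.exponential(1.0 / cfg.event_rate)
    sign = 0
    stall_target = 0.0
    dwell_end = 0.0
    is_escape = False
    ev_start = 0.0
    ev_peak = 0.0
    plateau_start = 0.0
    if cfg.detach_prob_per_step is not None:
        p_detach = cfg.detach_prob_per_step
    else:
        p_detach = 1.0 - np.exp(-dt / max(cfg.stall_dwell_mean, 1e-9))

    def close_event(i: int, ev_type: str, stall_dur: float) -> None:
        direction = "retrograde" if sign > 0 else "anterograde"
        labels.append(TrapEventLabel(ev_type, direction, ev_start, i * dt,
                                     ev_peak, stall_dur))

    for i in range(1, n):
        t = i * dt
        xi = x[i - 1]
        if state == IDLE and t >= next_event:
            state = RAMP
            sign = 1 if rng.random() < cfg.retro_fraction else -1
            stall_target = max(1.0, rng.normal(cfg.stall_force_mean,
                                               cfg.stall_force_sd))
            is_escape = rng.random() < cfg.escape_fraction
            f_motor = 0.0
            ev_start = t
            ev_peak = 0.0
        if state == RAMP:
            f_motor += sign * cfg.ramp_rate * dt
            # an escaping bead is carried visibly past the linear range
            # before it is lost and a re-centred bead is trapped again
            if abs(xi) > cfg.detector_range * 1.15:
                close_event(i, "escape", 0.0)
                state = IDLE
                f_motor = 0.0
                next_event = t + rng.exponential(1.0 / cfg.event_rate)
                xi = 0.0
            elif not is_escape and kappa * abs(xi) >= stall_target:
                state = STALL
                # the labelled dwell follows the operational definition
                # (cargo velocity ~ 0): it starts once the bead has
                # settled at the plateau, one trap relaxation time after
                # the stall force is first reached
                plateau_start = t + gamma / kappa
        elif state == STALL:
            # motor holds its last force; the bead sits at the plateau
            if rng.random() < p_detach:
                dwell = max(t - plateau_start, 0.0)
                close_event(i, "stall" if dwell >= 0.1 else "release", dwell)
                state = IDLE
                f_motor = 0.0
                next_event = t + rng.exponential(1.0 / cfg.event_rate)
        if state != IDLE:
            ev_peak = max(ev_peak, kappa * abs(xi))
        x[i] = xi + dt * (f_motor - kappa * xi) / gamma + w[i]

    t = np.arange(n) * dt
    trace = TrapTrace(t, x, kappa, cfg.sampling_rate, cfg.k_bt,
                      cfg.detector_range, orientation="positive",
                      meta={"seed": cfg.seed})
    return trace, labels


def simulate_recoil(config: TrapSimConfig, x0: float = 60.0,
                    duration: float = 0.2, thermal: bool = True,
                    seed: int | None = None) -> TrapTrace:
    """Simulate a bare relaxation from displacement ``x0`` (nm) to center.

    With ``thermal=False`` the trace is the noiseless closed-form
    x(t) = x0 exp(-kappa t / gamma), useful as an exact oracle.
    """
    cfg = config
    dt = cfg.dt
    n = max(int(round(duration * cfg.sampling_rate)), 2)
    t = np.arange(n) * dt
    gamma = cfg.drag_pn_s_per_nm
    if not thermal:
        x = x0 * np.exp(-cfg.stiffness * t / gamma)
    else:
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        noise_sd = np.sqrt(2.0 * cfg.k_bt * dt / gamma)
        a = 1.0 - dt * cfg.stiffness / gamma
        x = np.empty(n)
        x[0] = x0
        w = rng.normal(0.0, noise_sd, size=n)
        for i in range(1, n):
            x[i] = a * x[i - 1] + w[i]
    return TrapTrace(t, x, cfg.stiffness, cfg.sampling_rate, cfg.k_bt,
                     cfg.detector_range)
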