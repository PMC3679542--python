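"""Ground-truth simulation of IFT train traffic, bead motility and gliding.

The simulator produces the dynamics the analysis chain is meant to
recover: anterograde trains injected at the flagellar base as a Poisson
process and carried tip-ward by kinesin-2, retrograde trains injected at
the tip and carried base-ward by dynein-1b, rare Ca2+-dependent pauses in
which a train anchors to the glass surface through its membrane cargo, a
membrane-attached bead that alternates free 1D diffusion with
train-coupled processive runs, and whole-cell gliding initiated by paused
retrograde trains.

Positions are arc-length coordinates s in um measured from the flagellar
base; positive velocity is anterograde (base -> tip).

Pause events are generated as a *cell-level* Poisson process whose events
are assigned to a uniformly random currently-moving train.  Under this
convention the configured rate is the per-cell pausing frequency
(events/s summed over the whole cell), matching how pausing frequency is
measured from kymographs (total events / acquisition time); the expected
pause count is simply ``rate * duration`` regardless of train occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ConfigError, SimConfig, hill_response

__all__ = [
    "TrainTrack",
    "PauseEvent",
    "BeadTrack",
    "BodyTrack",
    "GroundTruth",
    "simulate_ift",
    "simulate_bead",
    "simulate_gliding",
]

ANTEROGRADE = "anterograde"
RETROGRADE = "retrograde"


@dataclass
class TrainTrack:
    """One IFT train: frame-sampled arc-length trajectory plus kinetics."""

    id: int
    direction: str                 # "anterograde" | "retrograde"
    speed: float                   # um/s, unsigned
    t: np.ndarray                  # s, frame-aligned sample times
    s: np.ndarray                  # um from base, same length as t
    flagellum: int = 0

    @property
    def sign(self) -> int:
        return 1 if self.direction == ANTEROGRADE else -1


@dataclass
class PauseEvent:
    """Surface anchoring of a train through its membrane glycoprotein cargo."""

    train_id: int
    position: float                # um from base at the moment of anchoring
    t_start: float
    t_end: float
    prior_direction: str
    flagellum: int = 0

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class BeadTrack:
    """Frame-sampled bead trajectory; coupled_to is -1 while diffusing."""

    t: np.ndarray
    s: np.ndarray
    coupled_to: np.ndarray         # int train id per frame, -1 = free


@dataclass
class BodyTrack:
    """Cell-body displacement (um, signed, lab frame) per frame."""

    t: np.ndarray
    displacement: np.ndarray
    onsets: list[float] = field(default_factory=list)   # true glide onset times
    onset_directions: list[int] = field(default_factory=list)


@dataclass
class GroundTruth:
    """Everything the downstream analyses are asked to recover."""

    config: SimConfig
    trains: list[TrainTrack]
    pauses: list[PauseEvent]
    bead: BeadTrack | None = None
    body: BodyTrack | None = None

    def frame_times(self) -> np.ndarray:
        n = self.config.n_frames
        return np.arange(n) * self.config.frame_interval


# ---------------------------------------------------------------------------
# train kinetics

class _TrainState:
    """Piecewise-linear train trajectory built incrementally from pauses."""

    __slots__ = ("id", "direction", "speed", "t_inject", "s0", "sign",
                 "break_t", "break_s", "exit_time", "paused_until")

    def __init__(self, tid: int, direction: str, speed: float,
                 t_inject: float, length: float):
        self.id = tid
        self.direction = direction
        self.speed = speed
        self.t_inject = t_inject
        self.sign = 1 if direction == ANTEROGRADE else -1
        self.s0 = 0.0 if direction == ANTEROGRADE else length
        self.break_t = [t_inject]
        self.break_s = [self.s0]
        transit = length / speed
        self.exit_time = t_inject + transit
        self.paused_until = -np.inf

    def position(self, t: float) -> float:
        return float(np.interp(t, self.break_t + [self.exit_time],
                               self.break_s + [self._s_exit()]))

    def _s_exit(self) -> float:
        return self.s0 + self.sign * self.speed * self._moving_time(self.exit_time)

    def _moving_time(self, t: float) -> float:
        # total non-paused time between injection and t, using breakpoints
        moving = 0.0
        ts = self.break_t + [t]
        ss = self.break_s
        for i in range(len(ts) - 1):
            if i < len(ss) - 1 and ss[i] == ss[i + 1]:
                continue  # paused segment
            moving += ts[i + 1] - ts[i]
        return moving

    def is_moving(self, t: float) -> bool:
        return self.t_inject <= t < self.exit_time and t >= self.paused_until

    def add_pause(self, t_start: float, duration: float) -> float:
        """Insert a pause; returns the anchoring position."""
        pos = self.position(t_start)
        self.break_t += [t_start, t_start + duration]
        self.break_s += [pos, pos]
        self.exit_time += duration
        self.paused_until = t_start + duration
        return pos

    def sample(self, frame_times: np.ndarray, length: float) -> TrainTrack:
        lo, hi = self.t_inject, self.exit_time
        mask = (frame_times >= lo) & (frame_times <= hi)
        t = frame_times[mask]
        knots_t = np.asarray(self.break_t + [self.exit_time])
        knots_s = np.asarray(self.break_s + [self._s_exit()])
        s = np.interp(t, knots_t, knots_s)
        s = np.clip(s, 0.0, length)
        return TrainTrack(self.id, self.direction, self.speed, t, s)


def _poisson_times(rng: np.random.Generator, rate: float,
                   duration: float) -> np.ndarray:
    if rate <= 0:
        return np.empty(0)
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def simulate_ift(config: SimConfig) -> GroundTruth:
    """Simulate bidirectional IFT traffic with Ca2+-dependent pausing.

    Trains are injected as independent Poisson processes at the base
    (anterograde) and tip (retrograde), transit at a per-train speed drawn
    from N(v, v_jitter^2), pause at the cell-level rate
    ``residual + (max - residual) * H([Ca2+])`` with exponential pause
    durations, resume their prior direction, and vanish on arrival.

    Returns a :class:`GroundTruth` with frame-sampled train tracks and
    the exact (continuous-time) pause events.
    """
    cfg = config
    seq = np.random.SeedSequence(cfg.seed)
    rng_inject, rng_pause, rng_speed = (
        np.random.default_rng(s) for s in seq.spawn(3))

    frame_times = np.arange(cfg.n_frames) * cfg.frame_interval
    states: list[_TrainState] = []
    tid = 0
    for direction, rate, v in (
            (ANTEROGRADE, cfg.injection_rate_antero, cfg.v_antero),
            (RETROGRADE, cfg.injection_rate_retro, cfg.v_retro)):
        if v <= 0 and rate > 0:
            raise ConfigError(f"{direction} speed must be > 0 when its "
                              "injection rate is > 0")
        # burn-in: start injections before t = 0 so that traffic is at
        # steady state when the acquisition starts
        burn_in = 1.5 * cfg.flagellum_length / v if rate > 0 else 0.0
        times = _poisson_times(rng_inject, rate, cfg.duration + burn_in)
        for t_inj in times - burn_in:
            speed = max(0.05, rng_speed.normal(v, cfg.v_jitter))
            states.append(_TrainState(tid, direction, speed, float(t_inj),
                                      cfg.flagellum_length))
            tid += 1
    states.sort(key=lambda st: st.t_inject)

    pause_rate = cfg.pause_rate
    pauses: list[PauseEvent] = []
    for tp in _poisson_times(rng_pause, pause_rate, cfg.duration):
        movers = [st for st in states if st.is_moving(tp)]
        if not movers:
            continue
        st = movers[rng_pause.integers(len(movers))]
        dur = rng_pause.exponential(cfg.pause_duration_mean)
        pos = st.add_pause(float(tp), float(dur))
        pauses.append(PauseEvent(st.id, pos, float(tp), float(tp + dur),
                                 st.direction))

    trains = [st.sample(frame_times, cfg.flagellum_length) for st in states]
    trains = [tr for tr in trains if tr.t.size >= 2]
    trains.sort(key=lambda tr: tr.id)
    return GroundTruth(cfg, trains, pauses)


# ---------------------------------------------------------------------------
# bead

def simulate_bead(config: SimConfig, truth: GroundTruth) -> GroundTruth:
    """Add a membrane-bead trajectory to ``truth``.

    The bead performs 1D diffusion (coefficient ``bead_diffusion_coeff``,
    reflecting boundaries at both flagellar ends) interrupted by
    train-coupled runs: attachment is Poisson with rate
    ``bead_attach_rate * H([Ca2+])`` (so Ca2+-deprived beads only
    diffuse), coupling is to the nearest active train, and a coupled bead
    moves at ``bead_speed_factor`` times the train's velocity until a
    Poisson detachment event or the train's exit.
    """
    if truth.trains is None:
        raise ConfigError("simulate_bead requires a train list (run "
                          "simulate_ift first)")
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(4)[3])
    dt = cfg.frame_interval
    frame_times = truth.frame_times()
    n = frame_times.size
    length = cfg.flagellum_length

    # per-frame lookup of active train positions
    by_frame_pos = np.full((len(truth.trains), n), np.nan)
    for k, tr in enumerate(truth.trains):
        idx = np.round(tr.t / dt).astype(int)
        ok = (idx >= 0) & (idx < n)
        by_frame_pos[k, idx[ok]] = tr.s[ok]
    train_ids = np.array([tr.id for tr in truth.trains])

    attach_rate = cfg.bead_attach_rate * min(
        hill_response(cfg.ca_free, cfg.ca_half), 1.0)
    p_attach = 1.0 - np.exp(-attach_rate * dt)
    p_detach = 1.0 - np.exp(-cfg.bead_detach_rate * dt)
    step_sd = np.sqrt(2.0 * cfg.bead_diffusion_coeff * dt)

    s = np.empty(n)
    coupled = np.full(n, -1, dtype=int)
    pos = rng.uniform(0.0, length)
    k_train = -1  # row index into by_frame_pos, -1 = free
    for i in range(n):
        if k_train >= 0:
            tr_pos = by_frame_pos[k_train, i]
            if np.isnan(tr_pos) or rng.random() < p_detach:
                k_train = -1
            else:
                if i > 0 and not np.isnan(by_frame_pos[k_train, i - 1]):
                    dpos = tr_pos - by_frame_pos[k_train, i - 1]
                    pos += cfg.bead_speed_factor * dpos
        if k_train < 0:
            pos += rng.normal(0.0, step_sd) if step_sd > 0 else 0.0
            # reflect at both ends
            pos = abs(pos)
            if pos > length:
                pos = 2 * length - pos
            pos = float(np.clip(pos, 0.0, length))
            if p_attach > 0 and rng.random() < p_attach:
                col = by_frame_pos[:, i]
                cand = np.flatnonzero(~np.isnan(col))
                if cand.size:
                    k_train = int(cand[np.argmin(np.abs(col[cand] - pos))])
        pos = float(np.clip(pos, 0.0, length))
        s[i] = pos
        coupled[i] = train_ids[k_train] if k_train >= 0 else -1

    truth.bead = BeadTrack(frame_times.copy(), s, coupled)
    return truth


# ---------------------------------------------------------------------------
# gliding

def simulate_gliding(config: SimConfig, truth: GroundTruth,
                     flagellum_signs: dict[int, int] | None = None
                     ) -> GroundTruth:
    """Add cell-body gliding driven by surface-anchored retrograde pauses.

    While at least one retrograde-origin pause is anchored and the anchor
    count between the two flagella is unbalanced, dynein-1b pulls the
    cell body toward the majority-side anchors at ``glide_speed``.  Motion
    stops when the driving pauses end or when the body has closed the
    distance to the nearest driving anchor (the body never overshoots a
    paused train).  Anterograde-origin pauses never initiate motion, and
    equal anchor counts on the two flagella cancel exactly.

    ``flagellum_signs`` maps flagellum id to the lab-frame direction
    (+1/-1) in which its anchored trains pull the body; default
    ``{0: +1, 1: -1}``.

    The arc-length trajectories of driving anchored trains are corrected
    in place: while the body advances a distance d, a surface-fixed train
    approaches the base by d in the flagellar frame.
    """
    cfg = config
    signs = flagellum_signs or {0: 1, 1: -1}
    frame_times = truth.frame_times()
    dt = cfg.frame_interval
    n = frame_times.size

    retro_pauses = [p for p in truth.pauses if p.prior_direction == RETROGRADE]
    trains_by_id = {tr.id: tr for tr in truth.trains}

    disp = np.zeros(n)
    onsets: list[float] = []
    onset_dirs: list[int] = []
    b = 0.0
    traveled: dict[int, float] = {id(p): 0.0 for p in retro_pauses}
    moving_prev = False
    for i in range(1, n):
        t = frame_times[i]
        active = [p for p in retro_pauses
                  if p.t_start <= t < p.t_end
                  and traveled[id(p)] < p.position - 1e-12]
        pull = sum(signs.get(p.flagellum, 1) for p in active)
        if pull == 0 or not active:
            moving_prev = False
            disp[i] = b
            continue
        direction = 1 if pull > 0 else -1
        drivers = [p for p in active
                   if signs.get(p.flagellum, 1) == direction]
        step = cfg.glide_speed * dt
        cap = min(p.position - traveled[id(p)] for p in drivers)
        step = min(step, cap)
        if step <= 0:
            moving_prev = False
            disp[i] = b
            continue
        if not moving_prev:
            onsets.append(float(frame_times[i - 1]))
            onset_dirs.append(direction)
            moving_prev = True
        b += direction * step
        for p in drivers:
            traveled[id(p)] += step
            tr = trains_by_id.get(p.train_id)
            if tr is not None:
                later = tr.t >= t
                tr.s[later] = np.clip(tr.s[later] - step, 0.0,
                                      cfg.flagellum_length)
        disp[i] = b

    truth.body = BodyTrack(frame_times.copy(), disp, onsets, onset_dirs)
    return truth
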