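"""Configuration objects for the synthetic-data simulators.

Two configs drive everything upstream of the analysis code:

``SimConfig``
    One flagellum of a surface-adhered cell: bidirectional IFT train
    traffic, Ca2+-dependent surface-anchoring pauses, a membrane bead that
    alternates free diffusion and train-coupled runs, cell-body gliding,
    and the camera model used to render TIRF-like movies.

``TrapSimConfig``
    A bead held in a fixed optical trap over the flagellar membrane:
    overdamped Langevin dynamics with a harmonic restoring force, motor
    force ramps terminated by stalls, releases or trap escapes.

Defaults are the wild-type, normal-calcium (0.34 mM free Ca2+) regime of
paralyzed-flagella *Chlamydomonas* cells imaged at 5 frames/s with a
106 nm pixel: anterograde trains at ~2 um/s, retrograde at ~3 um/s, one
pause per ~8 s per cell, trap stiffness 0.4 pN/nm sampled at 2 kHz.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

__all__ = [
    "SimConfig",
    "TrapSimConfig",
    "hill_response",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised when a configuration value violates its invariants."""


#: Reference free-Ca2+ concentration (mol/L) of standard TAP medium; the
#: pause-rate dose response is normalized to 1 at this concentration.
CA_REFERENCE_M = 0.34e-3


def hill_response(ca_free: float, k_half: float = 1e-6,
                  ca_ref: float = CA_REFERENCE_M) -> float:
    """Saturating Ca2+ dose response H with H(0) = 0 and H(ca_ref) = 1.

    A first-order Hill (Michaelis) curve with half-saturation ``k_half``
    (mol/L, default 1 uM), rescaled so that the reference concentration
    (0.34 mM, standard medium) maps exactly to 1.  Drives both the train
    pausing rate and the bead-train attachment rate.
    """
    if ca_free < 0:
        raise ConfigError(f"ca_free must be >= 0, got {ca_free}")
    if k_half <= 0 or ca_ref <= 0:
        raise ConfigError("k_half and ca_ref must be > 0")
    norm = ca_ref / (ca_ref + k_half)
    return (ca_free / (ca_free + k_half)) / norm


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


def _finite_nonneg(value: float, name: str) -> None:
    _require(math.isfinite(value) and value >= 0,
             f"{name} must be finite and >= 0, got {value}")


@dataclass
class SimConfig:
    """Parameters of the single-flagellum IFT / bead / gliding simulation.

    Lengths in um, times in s, rates in 1/s, concentrations in mol/L.
    """

    flagellum_length: float = 10.0      # fully grown flagella are 8-12 um
    duration: float = 120.0
    frame_interval: float = 0.2         # 5 frames/s
    pixel_size: float = 0.106           # um, EM-CCD effective pixel

    v_antero: float = 2.0               # um/s, kinesin-2 anterograde
    v_retro: float = 2.96               # um/s, dynein-1b retrograde
    v_jitter: float = 0.2               # um/s, train-to-train speed s.d.

    injection_rate_antero: float = 1.0  # trains/s entering at the base
    injection_rate_retro: float = 1.0   # trains/s entering at the tip

    ca_free: float = CA_REFERENCE_M     # mol/L free Ca2+
    ca_half: float = 1e-6               # mol/L, half-saturation of H
    pause_rate_max: float = 0.125       # 1/s per cell at reference Ca2+
    pause_rate_residual: float = 0.0125 # 1/s, Ca2+-independent residue
    pause_duration_mean: float = 2.0    # s, exponential pause durations

    bead_diffusion_coeff: float = 0.05  # um^2/s on the membrane
    bead_attach_rate: float = 0.5       # 1/s while free, at reference Ca2+
    bead_detach_rate: float = 0.5       # 1/s while coupled
    bead_speed_factor: float = 0.7      # coupled beads run ~30% slower

    glide_speed: float = 1.49           # um/s, uniflagellate cells

    psf_sigma: float = 0.11             # um, emitter PSF width
    train_extent: float = 0.0           # um, additional train length (0 = point)
    photon_rate: float = 150.0          # peak signal counts per emitter
    background_rate: float = 20.0       # counts/pixel/frame
    read_noise: float = 2.0             # counts r.m.s.

    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.flagellum_length > 0, "flagellum_length must be > 0")
        _require(self.duration > 0, "duration must be > 0")
        _require(self.frame_interval > 0, "frame_interval must be > 0")
        _require(self.pixel_size > 0, "pixel_size must be > 0")
        for name in ("v_antero", "v_retro", "v_jitter",
                     "injection_rate_antero", "injection_rate_retro",
                     "ca_free", "pause_rate_max", "pause_rate_residual",
                     "pause_duration_mean", "bead_diffusion_coeff",
                     "bead_attach_rate", "bead_detach_rate", "glide_speed",
                     "psf_sigma", "train_extent", "photon_rate",
                     "background_rate", "read_noise"):
            _finite_nonneg(float(getattr(self, name)), name)
        _require(0 < self.bead_speed_factor <= 1,
                 "bead_speed_factor must be in (0, 1]")
        _require(self.pause_rate_max >= self.pause_rate_residual,
                 "pause_rate_max must be >= pause_rate_residual")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval))

    @property
    def pause_rate(self) -> float:
        """Effective per-cell pause rate at the configured free Ca2+."""
        h = hill_response(self.ca_free, self.ca_half)
        return (self.pause_rate_residual
                + (self.pause_rate_max - self.pause_rate_residual) * min(h, 1.0))

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class TrapSimConfig:
    """Parameters of the bead-in-fixed-trap Langevin simulation.

    Displacement x is in nm, stiffness kappa in pN/nm, drag gamma in
    pN.s/um, forces in pN; the Euler-Maruyama step is 1/sampling_rate.
    """

    stiffness: float = 0.4              # pN/nm trap spring constant
    drag: float = 8.0                   # pN.s/um bead-membrane-train drag
    sampling_rate: float = 2000.0       # Hz (QPD acquisition rate)
    k_bt: float = 4.11                  # pN.nm thermal energy at ~25 C

    stall_force_mean: float = 25.2      # pN, drawn per event
    stall_force_sd: float = 5.0         # pN
    stall_dwell_mean: float = 0.15      # s; P(dwell>=0.1 s) ~ 0.51
    detach_prob_per_step: float | None = None  # overrides dwell mean if set
    escape_fraction: float = 0.1        # events that pull past the detector
    ramp_rate: float = 100.0            # pN/s motor force build-up
    event_rate: float = 0.5             # 1/s, new runs while bead is free
    retro_fraction: float = 0.5         # probability a run is retrograde
    detector_range: float = 200.0       # nm linear QPD range

    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.stiffness > 0, "stiffness must be > 0")
        _require(self.drag > 0, "drag must be > 0")
        _require(self.sampling_rate > 0, "sampling_rate must be > 0")
        _require(self.k_bt > 0, "k_bt must be > 0")
        for name in ("stall_force_mean", "stall_force_sd", "stall_dwell_mean",
                     "escape_fraction", "ramp_rate", "event_rate",
                     "detector_range"):
            _finite_nonneg(float(getattr(self, name)), name)
        _require(0 <= self.escape_fraction <= 1,
                 "escape_fraction must be in [0, 1]")
        _require(0 <= self.retro_fraction <= 1,
                 "retro_fraction must be in [0, 1]")
        # Euler-Maruyama stability of the harmonic relaxation.
        if self.dt * self.stiffness / self.drag_pn_s_per_nm >= 1.0:
            raise ConfigError(
                "unstable integration: dt * kappa / gamma >= 1; increase "
                "sampling_rate or drag")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def drag_pn_s_per_nm(self) -> float:
        return self.drag * 1e-3

    @property
    def relaxation_time(self) -> float:
        """Trap relaxation time constant gamma/kappa in seconds."""
        return self.drag_pn_s_per_nm / self.stiffness

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TrapSimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown TrapSimConfig keys: {sorted(unknown)}")
        return cls(**d)
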