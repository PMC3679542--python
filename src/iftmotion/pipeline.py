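"""Pipeline orchestration: simulate -> render -> kymo -> fsda -> events / trap.

A single :class:`RunConfig` (YAML-friendly dict of sub-configs plus a
global seed) drives all stages in dependency order; every artifact is
written with a JSON sidecar carrying the seed, a config echo, the
package version and the SHA-256 checksums of its inputs, and a final
JSON report aggregates the summary statistics of the run (pause
frequency, gliding speed, lag-time mean, colocalization KS p, peak-force
means, drag constant).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .config import ConfigError, SimConfig, TrapSimConfig
from .events import (RETROGRADE, Track, colocalization_test,
                     detect_gliding_onset, detect_pauses, independence_test,
                     lag_time_analysis)
from .fsda import VelocityBins, decompose, extract_tracks
from .io import (sha256_file, write_glides, write_json, write_kymograph,
                 write_movie, write_pauses, write_tracks, write_trap_trace)
from .kymo import Kymograph, sample_kymograph
from .render import render_kymograph, render_movie, straight_path
from .synthetic import simulate_bead, simulate_gliding, simulate_ift
from .trap_sim import simulate_trap_trace
from .trapforce import (calibrate_stiffness, classify_events, drag_force,
                        motor_count, peak_force_stats, recoil_fits)

__all__ = ["RunConfig", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("simulate", "render", "kymo", "fsda", "events", "trap")


@dataclass
class RunConfig:
    """Configuration of a full synthetic pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    trap: TrapSimConfig = field(default_factory=TrapSimConfig)
    seed: int = 0
    out_dir: str = "run"
    stages: tuple[str, ...] = ALL_STAGES
    linewidth_px: int = 3
    v_min: float = 0.2
    min_track_length: float = 1.0
    min_track_duration: float = 1.0
    trap_duration: float = 30.0
    n_null: int = 50
    render_movie_stage: bool = False   # full 2D movie (slower) vs kymograph

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ConfigError(f"unknown stages: {sorted(bad)}")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown RunConfig keys: {sorted(unknown)}")
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig.from_dict(d["sim"])
        if "trap" in d and isinstance(d["trap"], dict):
            d["trap"] = TrapSimConfig.from_dict(d["trap"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def resolved_sim(self) -> SimConfig:
        d = self.sim.to_dict()
        d["seed"] = self.seed
        return SimConfig.from_dict(d)

    def resolved_trap(self) -> TrapSimConfig:
        d = self.trap.to_dict()
        d["seed"] = self.seed + 1
        return TrapSimConfig.from_dict(d)


def _sidecar_meta(config: RunConfig, inputs: dict[str, str]) -> dict[str, Any]:
    return {"seed": config.seed, "version": __version__,
            "input_checksums": inputs}


def _truth_tracks(truth) -> list[Track]:
    tracks = []
    for tr in truth.trains:
        tracks.append(Track(tr.id, "train", tr.t, tr.s,
                            direction=tr.direction, flagellum=tr.flagellum))
    return tracks


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the requested stages and return (and write) the summary report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.stages
    report: dict[str, Any] = {"seed": config.seed, "version": __version__,
                              "stages": list(stages)}
    checksums: dict[str, str] = {}

    sim_cfg = config.resolved_sim()
    truth = None
    if "simulate" in stages:
        truth = simulate_ift(sim_cfg)
        truth = simulate_bead(sim_cfg, truth)
        truth = simulate_gliding(sim_cfg, truth)
        tracks = _truth_tracks(truth)
        write_tracks(out / "train_tracks.csv", tracks)
        write_pauses(out / "pauses_truth.csv", truth.pauses)
        np.savetxt(out / "bead_track.csv",
                   np.column_stack([truth.bead.t, truth.bead.s,
                                    truth.bead.coupled_to]),
                   delimiter=",", header="t_s,position_um,coupled_to",
                   comments="")
        np.savetxt(out / "body_track.csv",
                   np.column_stack([truth.body.t, truth.body.displacement]),
                   delimiter=",", header="t_s,displacement_um", comments="")
        for f in ("train_tracks.csv", "pauses_truth.csv", "bead_track.csv",
                  "body_track.csv"):
            checksums[f] = sha256_file(out / f)
        write_json(out / "simulate.json",
                   {**_sidecar_meta(config, {}), "config": sim_cfg.to_dict(),
                    "n_trains": len(truth.trains),
                    "n_pauses": len(truth.pauses)})
        report["n_trains"] = len(truth.trains)
        report["n_pauses_truth"] = len(truth.pauses)

    kymograph = None
    if "render" in stages or "kymo" in stages:
        if truth is None:
            raise ConfigError("render/kymo stages require the simulate stage")
        if config.render_movie_stage:
            movie = render_movie(truth, sim_cfg)
            write_movie(out / "movie.tif", movie, sim_cfg.to_dict())
            checksums["movie.tif"] = sha256_file(out / "movie.tif")
            if "kymo" in stages:
                kymograph = sample_kymograph(movie, straight_path(sim_cfg),
                                             config.linewidth_px)
        else:
            data = render_kymograph(truth, sim_cfg)
            kymograph = Kymograph(data, sim_cfg.pixel_size,
                                  sim_cfg.frame_interval,
                                  meta={"seed": sim_cfg.seed})
        if kymograph is not None:
            write_kymograph(out / "kymograph.tif", kymograph,
                            sim_cfg.to_dict())
            checksums["kymograph.tif"] = sha256_file(out / "kymograph.tif")

    fsda_result = None
    if "fsda" in stages:
        if kymograph is None:
            raise ConfigError("fsda stage requires the kymo stage")
        bins = VelocityBins.standard(config.v_min)
        fsda_result = decompose(kymograph, bins)
        for label in ("anterograde", "retrograde", "paused"):
            comp = fsda_result.component_kymograph(label)
            write_kymograph(out / f"component_{label}.tif", comp)
            checksums[f"component_{label}.tif"] = \
                sha256_file(out / f"component_{label}.tif")
        report["fsda_energy"] = fsda_result.energy
        speeds = {}
        for label in ("anterograde", "retrograde"):
            comp = fsda_result.component_kymograph(label)
            trks = extract_tracks(comp, config.min_track_length,
                                  config.min_track_duration)
            speeds[label] = float(np.mean([abs(tr.velocity)
                                           for tr in trks])) if trks \
                else float("nan")
            report[f"n_tracks_{label}"] = len(trks)
        report["train_speed_um_s"] = speeds

    if "events" in stages:
        if truth is None:
            raise ConfigError("events stage requires the simulate stage")
        tracks = _truth_tracks(truth)
        pauses, pstats = detect_pauses(tracks,
                                       acquisition_time=sim_cfg.duration,
                                       n_flagella=1)
        write_pauses(out / "pauses_detected.csv", pauses)
        checksums["pauses_detected.csv"] = \
            sha256_file(out / "pauses_detected.csv")
        report["pause_stats"] = pstats

        body = Track(0, "cell_body", truth.body.t, truth.body.displacement)
        glides = detect_gliding_onset(body)
        write_glides(out / "glides.csv", glides)
        checksums["glides.csv"] = sha256_file(out / "glides.csv")
        report["n_glides"] = len(glides)
        if glides:
            report["gliding_speed_um_s"] = float(
                np.mean([g.speed for g in glides]))
            lag = lag_time_analysis(pauses, glides, leading_flagellum=0)
            report["lag_mean_s"] = lag["mean"]
            report["lag_sem_s"] = lag["sem"]
            report["lag_n"] = lag["n"]
            retro_pauses = [p for p in pauses
                            if p.prior_direction == RETROGRADE]
            if lag["n"] >= 2 and len(retro_pauses) >= 2 and lag["mean"] > 0:
                interpause = sim_cfg.duration / max(len(pauses), 1)
                report["independence_p"] = independence_test(
                    lag["mean"], lag["n"], interpause, n_mc=10 ** 5,
                    seed=config.seed + 2)
        bead = Track(1, "bead", truth.bead.t, truth.bead.s)
        train_tracks = [tr for tr in tracks if tr.t.size >= 2]
        try:
            _, _, ks, p = colocalization_test(
                bead, train_tracks, n_null=config.n_null,
                seed=config.seed + 3, stride=3)
            report["colocalization_ks"] = ks
            report["colocalization_p"] = p
        except ConfigError:
            report["colocalization_p"] = float("nan")

    if "trap" in stages:
        trap_cfg = config.resolved_trap()
        trace, labels = simulate_trap_trace(trap_cfg, config.trap_duration)
        write_trap_trace(out / "trap_trace.csv", trace, trap_cfg.to_dict())
        checksums["trap_trace.csv"] = sha256_file(out / "trap_trace.csv")
        calib_cfg = TrapSimConfig.from_dict(
            {**trap_cfg.to_dict(), "event_rate": 0.0, "seed": config.seed + 4})
        calib_trace, _ = simulate_trap_trace(calib_cfg, 10.0)
        kappa_hat = calibrate_stiffness(calib_trace)
        report["kappa_pN_per_nm"] = kappa_hat
        events_list = classify_events(trace)
        report["n_force_events"] = len(events_list)
        if events_list:
            stats = peak_force_stats(events_list)
            report["peak_force"] = {
                k: {"mean": v["mean"], "sem": v["sem"], "n": v["n"]}
                for k, v in stats.items() if not k.endswith("fractions")}
            stalls = [e for e in events_list if e.type == "stall"]
            if stalls:
                mean_stall = float(np.mean([e.peak_force for e in stalls]))
                report["motor_count_min"] = motor_count(mean_stall, 7.0)
        # drag from recoils after detected stalls/releases
        gammas = [f.gamma for f in recoil_fits(trace, events_list)]
        if gammas:
            g = float(np.mean(gammas))
            report["gamma_pN_s_per_um"] = g
            report["drag_force_pN_at_2_3"] = [drag_force(g, 2.0),
                                              drag_force(g, 3.0)]
        write_json(out / "trap_events.json",
                   {"events": [dataclasses.asdict(e) for e in events_list],
                    "labels": [dataclasses.asdict(l) for l in labels]})
        checksums["trap_events.json"] = sha256_file(out / "trap_events.json")

    report["checksums"] = checksums
    write_json(out / "report.json", report)
    return report
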