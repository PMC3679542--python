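"""Reading and writing of movies, kymographs, paths, tracks and traces.

Conventions:

* movies: multi-page 16-bit TIFF + JSON sidecar (``<name>.json``) with
  pixel_size_um, frame_interval_s, seed and a config echo;
* kymographs: 32-bit float TIFF + JSON sidecar;
* flagellar paths: CSV (frame, vertex_index, row_px, col_px) + JSON
  header (anchor_um, base_end);
* tracks and trap traces: CSV with documented headers;
* events / fits / reports: JSON.

All JSON is written with sorted keys and no timestamps so that repeated
runs with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from .config import ConfigError
from .events import GlideEvent, PauseEvent, Track
from .kymo import FlagellarPath, Kymograph
from .render import Movie
from .trap_sim import TrapTrace

__all__ = [
    "write_movie", "read_movie", "write_kymograph", "read_kymograph",
    "write_path", "read_path", "write_tracks", "read_tracks",
    "write_trap_trace", "read_trap_trace", "write_json", "read_json",
    "write_pauses", "read_pauses", "write_glides", "sha256_file",
]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(path: str | Path, payload: dict[str, Any]) -> None:
    Path(path).write_text(
        json.dumps(_jsonable(payload), sort_keys=True, indent=1) + "\n")


def read_json(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())


def sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_movie(path: str | Path, movie: Movie,
                config_echo: dict[str, Any] | None = None) -> None:
    path = Path(path)
    tifffile.imwrite(path, movie.data.astype(np.uint16),
                     photometric="minisblack")
    meta = {"pixel_size_um": movie.pixel_size,
            "frame_interval_s": movie.frame_interval}
    meta.update(movie.meta)
    if config_echo is not None:
        meta["config"] = config_echo
    write_json(_sidecar(path), meta)


def read_movie(path: str | Path) -> Movie:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    meta = read_json(_sidecar(path)) if _sidecar(path).exists() else {}
    px = float(meta.get("pixel_size_um", 1.0))
    dt = float(meta.get("frame_interval_s", 1.0))
    return Movie(data, px, dt, meta)


def write_kymograph(path: str | Path, kymo: Kymograph,
                    config_echo: dict[str, Any] | None = None) -> None:
    path = Path(path)
    tifffile.imwrite(path, kymo.data.astype(np.float32),
                     photometric="minisblack")
    meta = {"pixel_size_um": kymo.pixel_size,
            "frame_interval_s": kymo.frame_interval}
    meta.update({k: v for k, v in kymo.meta.items() if k not in meta})
    if config_echo is not None:
        meta["config"] = config_echo
    write_json(_sidecar(path), meta)


def read_kymograph(path: str | Path) -> Kymograph:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    meta = read_json(_sidecar(path)) if _sidecar(path).exists() else {}
    return Kymograph(data, float(meta.get("pixel_size_um", 1.0)),
                     float(meta.get("frame_interval_s", 1.0)), meta)


def write_path(path: str | Path, fpath: FlagellarPath) -> None:
    rows = []
    for frame, poly in fpath.keyframes:
        poly = np.asarray(poly, dtype=float)
        for j, (r, c) in enumerate(poly):
            rows.append({"frame": frame, "vertex_index": j,
                         "row_px": r, "col_px": c})
    pd.DataFrame(rows).to_csv(path, index=False)
    write_json(_sidecar(Path(path)),
               {"anchor_um": fpath.anchor, "base_end": fpath.base_end})


def read_path(path: str | Path) -> FlagellarPath:
    df = pd.read_csv(path)
    needed = {"frame", "vertex_index", "row_px", "col_px"}
    if not needed.issubset(df.columns):
        raise ConfigError(f"path CSV must have columns {sorted(needed)}")
    keyframes = []
    for frame, grp in df.groupby("frame"):
        grp = grp.sort_values("vertex_index")
        keyframes.append((int(frame),
                          grp[["row_px", "col_px"]].to_numpy(float)))
    keyframes.sort(key=lambda kv: kv[0])
    meta = read_json(_sidecar(Path(path))) if _sidecar(Path(path)).exists() \
        else {}
    return FlagellarPath(keyframes, float(meta.get("anchor_um", 0.0)),
                         str(meta.get("base_end", "first")))


def write_tracks(path: str | Path, tracks: list[Track]) -> None:
    rows = []
    for tr in tracks:
        for i in range(tr.t.size):
            rows.append({
                "track_id": tr.id, "entity": tr.entity,
                "flagellum": tr.flagellum, "direction": tr.direction,
                "t_s": tr.t[i], "position_um": tr.position[i],
                "intensity": tr.intensity[i]
                if tr.intensity is not None else np.nan,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tracks(path: str | Path) -> list[Track]:
    df = pd.read_csv(path)
    out = []
    for tid, grp in df.groupby("track_id"):
        grp = grp.sort_values("t_s")
        out.append(Track(
            int(tid), str(grp["entity"].iloc[0]),
            grp["t_s"].to_numpy(float), grp["position_um"].to_numpy(float),
            direction=str(grp["direction"].iloc[0]),
            flagellum=int(grp["flagellum"].iloc[0])))
    out.sort(key=lambda tr: tr.id)
    return out


def write_pauses(path: str | Path, pauses: list[PauseEvent]) -> None:
    pd.DataFrame([{
        "flagellum": p.flagellum, "position_um": p.position,
        "t_start_s": p.t_start, "t_end_s": p.t_end,
        "prior_direction": p.prior_direction,
        "track_id": getattr(p, "track_id", getattr(p, "train_id", -1)),
    } for p in pauses]).to_csv(path, index=False)


def read_pauses(path: str | Path) -> list[PauseEvent]:
    df = pd.read_csv(path)
    return [PauseEvent(int(r.flagellum), float(r.position_um),
                       float(r.t_start_s), float(r.t_end_s),
                       str(r.prior_direction), int(r.track_id))
            for r in df.itertuples()]


def write_glides(path: str | Path, glides: list[GlideEvent]) -> None:
    pd.DataFrame([{
        "onset_s": g.onset, "direction": g.direction, "speed_um_s": g.speed,
        "t_end_s": g.t_end,
    } for g in glides]).to_csv(path, index=False)


def write_trap_trace(path: str | Path, trace: TrapTrace,
                     config_echo: dict[str, Any] | None = None) -> None:
    pd.DataFrame({"t_s": trace.t, "x_nm": trace.x}).to_csv(path, index=False)
    meta = {"kappa_pN_per_nm": trace.stiffness, "rate_hz": trace.sampling_rate,
            "k_bt_pN_nm": trace.k_bt, "range_nm": trace.detector_range,
            "orientation": trace.orientation}
    if config_echo is not None:
        meta["config"] = config_echo
    write_json(_sidecar(Path(path)), meta)


def read_trap_trace(path: str | Path) -> TrapTrace:
    df = pd.read_csv(path)
    if not {"t_s", "x_nm"}.issubset(df.columns):
        raise ConfigError("trap trace CSV must have columns t_s, x_nm")
    meta = read_json(_sidecar(Path(path))) if _sidecar(Path(path)).exists() \
        else {}
    t = df["t_s"].to_numpy(float)
    rate = float(meta.get("rate_hz", 1.0 / np.median(np.diff(t))))
    return TrapTrace(t, df["x_nm"].to_numpy(float),
                     float(meta.get("kappa_pN_per_nm", 1.0)), rate,
                     float(meta.get("k_bt_pN_nm", 4.11)),
                     float(meta.get("range_nm", 200.0)),
                     meta.get("orientation"), meta)
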