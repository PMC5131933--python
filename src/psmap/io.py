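"""File formats: voltage movies (HDF5 / NPZ), PS tables (CSV), run configs (YAML).

Layouts are documented in docs/formats.md.  Reading a movie without its
physical metadata (``dx_mm``, ``frame_interval_ms``) is a hard error — no
silent defaults, since every downstream distance and delay depends on them.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .datatypes import PSPointSet, VoltageMovie

__all__ = ["write_movie", "read_movie", "write_ps", "read_ps",
           "load_config", "save_config"]

_REQUIRED_ATTRS = ("dx_mm", "frame_interval_ms")


def _meta_to_attrs(meta: dict) -> dict:
    out = {}
    for k, v in meta.items():
        if isinstance(v, (str, int, float, np.integer, np.floating, bool)):
            out[f"meta_{k}"] = v
        else:
            out[f"meta_{k}"] = json.dumps(v)
    return out


def _attrs_to_meta(attrs) -> dict:
    meta = {}
    for k, v in attrs.items():
        if not k.startswith("meta_"):
            continue
        if isinstance(v, bytes):
            v = v.decode()
        if isinstance(v, str) and v[:1] in "[{":
            try:
                v = json.loads(v)
            except json.JSONDecodeError:
                pass
        meta[k[5:]] = v
    return meta


def write_movie(movie: VoltageMovie, path) -> Path:
    """Write a movie as HDF5 (.h5/.hdf5) or NPZ (.npz fallback)."""
    path = Path(path)
    frames = np.asarray(movie.frames, dtype=np.float32)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("frames", data=frames)
            ds.attrs["units"] = "mV"
            f.attrs["dx_mm"] = movie.dx_mm
            f.attrs["frame_interval_ms"] = movie.frame_interval_ms
            f.attrs["t0_ms"] = movie.t0_ms
            for k, v in _meta_to_attrs(movie.meta).items():
                f.attrs[k] = v
    elif path.suffix == ".npz":
        np.savez(path, frames=frames, dx_mm=movie.dx_mm,
                 frame_interval_ms=movie.frame_interval_ms, t0_ms=movie.t0_ms,
                 meta=json.dumps(movie.meta))
    else:
        raise ValueError(f"unsupported movie format {path.suffix!r} "
                         "(use .h5, .hdf5 or .npz)")
    return path


def read_movie(path) -> VoltageMovie:
    """Read a movie written by :func:`write_movie`.

    Raises ``ValueError`` naming the missing attribute if physical metadata
    is absent.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "frames" not in f:
                raise ValueError(f"{path}: no /frames dataset")
            for a in _REQUIRED_ATTRS:
                if a not in f.attrs:
                    raise ValueError(f"{path}: required attribute {a!r} missing")
            return VoltageMovie(f["frames"][...],
                                float(f.attrs["dx_mm"]),
                                float(f.attrs["frame_interval_ms"]),
                                float(f.attrs.get("t0_ms", 0.0)),
                                _attrs_to_meta(f.attrs))
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            for a in _REQUIRED_ATTRS:
                if a not in z:
                    raise ValueError(f"{path}: required attribute {a!r} missing")
            return VoltageMovie(z["frames"], float(z["dx_mm"]),
                                float(z["frame_interval_ms"]),
                                float(z["t0_ms"]) if "t0_ms" in z else 0.0,
                                json.loads(str(z["meta"])) if "meta" in z else {})
    raise ValueError(f"unsupported movie format {path.suffix!r}")


def write_ps(ps: PSPointSet, path) -> Path:
    """PS table as CSV: method,frame,t_ms,row,col,x_mm,y_mm,chirality.

    Grid metadata rides in ``# key=value`` header comments so the set reads
    back losslessly.
    """
    path = Path(path)
    with open(path, "w") as f:
        f.write(f"# dx_mm={ps.dx_mm!r}\n")
        f.write(f"# frame_interval_ms={ps.frame_interval_ms!r}\n")
        f.write(f"# config={json.dumps(ps.config, default=str)}\n")
        ps.points.to_csv(f, index=False)
    return path


def read_ps(path) -> PSPointSet:
    path = Path(path)
    header = {}
    with open(path) as f:
        pos = f.tell()
        line = f.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            header[key.strip()] = val
            pos = f.tell()
            line = f.readline()
        f.seek(pos)
        df = pd.read_csv(f)
    for a in _REQUIRED_ATTRS:
        if a not in header:
            raise ValueError(f"{path}: required attribute {a!r} missing")
    return PSPointSet(df, float(header["dx_mm"]),
                      float(header["frame_interval_ms"]),
                      json.loads(header.get("config", "{}")))


def save_config(config: dict, path) -> Path:
    """Write a run configuration mapping as YAML (round-trips losslessly)."""
    path = Path(path)
    with open(path, "w") as f:
        yaml.safe_dump(config, f, sort_keys=False)
    return path


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
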