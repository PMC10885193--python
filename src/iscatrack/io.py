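"""File-format plumbing: TIFF movies, CSV tables, YAML configs, manifests.

Movies travel as multi-page grayscale TIFF (16-bit unsigned, frame
major); contrast stacks optionally as 32-bit float TIFF.  Tabular
outputs are comma-separated UTF-8 with a header row and no index
column.  Every pipeline output directory carries a ``manifest.json``
recording input hashes, the configuration hash and the seed, so runs
are auditable and reproducible.
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
import yaml

from .background import ContrastStack, MovieStack
from .errors import InputFormatError
from .simulate import BlobParams, ParticleTruth, SimulationConfig

__all__ = [
    "write_movie_tiff",
    "read_movie_tiff",
    "write_contrast_tiff",
    "write_truth_csv",
    "read_truth_csv",
    "load_simulation_config",
    "dump_simulation_config",
    "config_hash",
    "file_sha256",
    "write_manifest",
]

TRUTH_COLUMNS = ["particle_id", "frame", "x_nm", "y_nm", "z_nm", "exited"]


def write_movie_tiff(path: str | Path, stack: MovieStack) -> None:
    """Write a movie as frame-major 16-bit unsigned multi-page TIFF."""
    data = np.clip(np.rint(stack.frames), 0, np.iinfo(np.uint16).max).astype(
        np.uint16
    )
    tifffile.imwrite(
        path,
        data,
        metadata={
            "pixel_nm": stack.pixel_nm,
            "frame_rate_hz": stack.frame_rate_hz,
        },
    )


def read_movie_tiff(
    path: str | Path,
    pixel_nm: float | None = None,
    frame_rate_hz: float | None = None,
) -> MovieStack:
    """Read a multi-page TIFF movie; metadata overridable by arguments."""
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    except (tifffile.TiffFileError, FileNotFoundError, ValueError) as exc:
        raise InputFormatError(f"cannot read TIFF movie {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim != 3:
        raise InputFormatError(
            f"expected a (T, H, W) grayscale stack in {path}, got shape {data.shape}"
        )
    px = pixel_nm if pixel_nm is not None else float(meta.get("pixel_nm", 0) or 0)
    hz = (
        frame_rate_hz
        if frame_rate_hz is not None
        else float(meta.get("frame_rate_hz", 0) or 0)
    )
    if px <= 0 or hz <= 0:
        raise InputFormatError(
            f"{path} lacks pixel_nm/frame_rate_hz metadata; pass them explicitly"
        )
    return MovieStack(frames=data.astype(np.float64), pixel_nm=px, frame_rate_hz=hz)


def write_contrast_tiff(path: str | Path, cstack: ContrastStack) -> None:
    """Write a contrast stack as 32-bit float multi-page TIFF."""
    tifffile.imwrite(
        path,
        cstack.frames.astype(np.float32),
        metadata={
            "pixel_nm": cstack.pixel_nm,
            "frame_rate_hz": cstack.frame_rate_hz,
            "valid_frame_offset": cstack.valid_frame_offset,
        },
    )


def write_truth_csv(path: str | Path, truth: list[ParticleTruth]) -> None:
    """Ground truth as long-format CSV: one row per particle per frame."""
    records = []
    for p in truth:
        for i, t in enumerate(p.frames):
            records.append(
                (p.particle_id, int(t), p.x_nm[i], p.y_nm[i], p.z_nm[i],
                 p.exited_fov)
            )
    df = pd.DataFrame(records, columns=TRUTH_COLUMNS)
    df.to_csv(path, index=False)


def read_truth_csv(path: str | Path) -> list[ParticleTruth]:
    """Rebuild :class:`ParticleTruth` records from a truth CSV."""
    try:
        df = pd.read_csv(path)
    except (OSError, ValueError) as exc:
        raise InputFormatError(f"cannot read truth CSV {path}: {exc}") from exc
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise InputFormatError(f"truth CSV {path} lacks columns {sorted(missing)}")
    out = []
    for pid, g in df.groupby("particle_id", sort=True):
        g = g.sort_values("frame")
        out.append(
            ParticleTruth(
                particle_id=int(pid),
                arrival_frame=int(g["frame"].iloc[0]),
                x_nm=g["x_nm"].to_numpy(),
                y_nm=g["y_nm"].to_numpy(),
                z_nm=g["z_nm"].to_numpy(),
                exited_fov=bool(g["exited"].iloc[0]),
            )
        )
    return out


def dump_simulation_config(cfg: SimulationConfig) -> dict[str, Any]:
    d = dataclasses.asdict(cfg)
    return d


def load_simulation_config(path: str | Path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from YAML (or JSON) mapping."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    except (OSError, yaml.YAMLError) as exc:
        raise InputFormatError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise InputFormatError(f"config {path} must be a mapping")
    blob = raw.pop("blob", None)
    kwargs = dict(raw)
    if blob is not None:
        kwargs["blob"] = BlobParams(**blob)
    return SimulationConfig(**kwargs)


def config_hash(obj: Any) -> str:
    """Stable sha256 of a JSON-serialisable configuration object."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    *,
    config: Any,
    seed: int | None,
    inputs: dict[str, str | Path] | None = None,
    extra: dict[str, Any] | None = None,
) -> None:
    """Write a run manifest (config hash, seed, input hashes, versions)."""
    from . import __version__

    manifest: dict[str, Any] = {
        "iscatrack_version": __version__,
        "config_hash": config_hash(config),
        "seed": seed,
        "inputs": {
            name: file_sha256(p) for name, p in (inputs or {}).items()
        },
    }
    if extra:
        manifest.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
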