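"""File I/O and run configuration.

Image fields round-trip through multi-page TIFF with the axis order
``CZTYX`` and channel roles / pixel size stored as JSON in the TIFF
description.  Result tables are plain CSV with documented headers; every
run writes a JSON manifest with the configuration hash and seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .imaging import ImageField

AXES = "CZTYX"


class FormatError(ValueError):
    """Raised when an image file does not match the documented layout."""


def write_field(path, fld: ImageField) -> None:
    """Write an ImageField as multi-page TIFF (one page per C/Z/T plane)."""
    # "dims" rather than "shape": tifffile reserves a top-level "shape" key
    # in the description for its own shaped-series convention
    meta = {
        "axes": AXES,
        "dims": list(fld.pixels.shape),
        "channel_roles": {str(k): v for k, v in fld.channel_roles.items()},
        "pixel_size_um": fld.pixel_size_um,
    }
    pages = np.ascontiguousarray(fld.pixels.reshape((-1,) + fld.pixels.shape[-2:]))
    tifffile.imwrite(path, pages, description=json.dumps(meta))


def read_field(path, channel_map: Optional[Dict[int, str]] = None) -> ImageField:
    """Read a multi-page TIFF written by :func:`write_field`.

    Missing metadata falls back to a single-channel single-plane stack at
    1 um/px with a warning; an explicit ``channel_map`` overrides stored
    roles.
    """
    with tifffile.TiffFile(path) as tf:
        pages = tf.asarray()
        desc = tf.pages[0].description
    meta = None
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = None
    if meta is not None and "dims" not in meta:
        meta = None  # foreign description (e.g. tifffile shaped metadata)
    if pages.ndim == 2:
        pages = pages[None]
    if meta is None:
        warnings.warn(f"{path}: no layout metadata; assuming (t, y, x) at 1 um/px")
        arr = pages[None, None, :, :, :]
        roles = channel_map or {}
        return ImageField(arr.astype(float), roles, 1.0)
    shape = tuple(meta["dims"])
    if int(np.prod(shape[:3])) != pages.shape[0]:
        raise FormatError(
            f"{path}: expected {int(np.prod(shape[:3]))} pages, found {pages.shape[0]}"
        )
    arr = pages.reshape(shape)
    roles = {int(k): v for k, v in meta.get("channel_roles", {}).items()}
    if channel_map:
        roles = dict(channel_map)
    px = float(meta.get("pixel_size_um", 0) or 0)
    if px <= 0:
        warnings.warn(f"{path}: missing pixel size; defaulting to 1 um")
        px = 1.0
    return ImageField(arr.astype(float), roles, px)


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Pipeline thresholds and paths; round-trips losslessly via YAML."""

    paths: Dict[str, str] = field(default_factory=dict)
    channel_roles: Dict[int, str] = field(default_factory=lambda: {0: "nucleus", 1: "cytoplasm"})
    pixel_size_um: float = 1.0
    z_threshold: float = 1.5
    min_replicates: int = 2
    min_fa_size_px: int = 10
    min_track_frames: int = 5
    r2_gate: float = 0.9
    ring_outer_um: float = 2.0
    min_nucleus_area_px: int = 60
    norm_include_controls: bool = True
    seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "pixel_size_um",
            "z_threshold",
            "min_replicates",
            "min_fa_size_px",
            "min_track_frames",
            "r2_gate",
            "ring_outer_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "channel_roles" in data:
            data["channel_roles"] = {int(k): v for k, v in data["channel_roles"].items()}
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


TABLE_COLUMNS = {
    "cells.csv": ["plate", "well", "field", "cell_id", "edge", "assigned_class"],
    "pqms.csv": ["population_id", "class", "percentage", "n_cells"],
    "zscores.csv": ["plate", "well", "reagent", "library", "replicate", "shape", "z"],
    "hits.csv": ["reagent", "library", "shape", "direction", "replicate_zscores"],
    "tracks.csv": [
        "track_id",
        "mean_area",
        "mean_axial_ratio",
        "mean_intensity",
        "longevity_min",
        "mean_dist_centroid",
        "mean_dist_hull",
    ],
    "kinetics.csv": ["track_id", "phase", "rate_per_min", "phase_length_min", "r_squared", "n_points"],
    "tension.csv": ["track_id", "n_frames", "n_masked", "mean_yfp_ratio", "mean_tension", "min_tension"],
    "invasion.csv": ["depth_um", "count", "fraction_pct"],
}


def write_tables(
    tables: Dict[str, pd.DataFrame],
    out_dir,
    config: Optional[RunConfig] = None,
) -> List[Path]:
    """Write result tables (CSV) and a JSON run manifest.

    Keys of ``tables`` must be known table names; empty frames produce
    header-only files with the documented columns.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        if name not in TABLE_COLUMNS:
            raise KeyError(f"unknown table {name!r}")
        cols = TABLE_COLUMNS[name]
        if df is None or df.empty:
            df = pd.DataFrame(columns=cols)
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)
    manifest = {
        "tables": sorted(t for t in tables),
        "config_digest": config.digest() if config else None,
        "seed": config.seed if config else None,
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written.append(mpath)
    return written
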