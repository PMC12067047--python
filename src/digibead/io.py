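"""File I/O: multi-page TIFF stacks, CSV tables, and run configuration.

FrameSets are exchanged as one multi-page grayscale TIFF per channel
(``<stem>_localization.tif`` / ``<stem>_fluorescence.tif``, uint8 or uint16
per the configured bit depth) plus a ``<stem>_truth.csv`` ground-truth
table. A dilution series adds ``manifest.csv`` mapping stems to conditions
and a fully resolved ``config.yaml`` so any run can be reproduced from its
output directory alone.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import InvalidParameterError, NoFramesError
from .synthetic import TRUTH_COLUMNS, DilutionCondition, FrameSet, OpticsParams

__all__ = [
    "condition_stem",
    "write_frameset",
    "read_frames",
    "write_series",
    "read_series_manifest",
    "load_config",
    "dump_config",
]


def condition_stem(concentration: float, replicate: int) -> str:
    return f"conc{concentration:g}_rep{replicate}"


def _to_uint(frames: list[np.ndarray], bit_depth: int) -> np.ndarray:
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    stack = np.rint(np.stack(frames)).astype(dtype)
    return stack


def write_frameset(frameset: FrameSet, directory: Path | str, stem: str) -> dict[str, Path]:
    """Write one FrameSet as two TIFF stacks + a truth CSV; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bd = frameset.optics.bit_depth
    paths = {
        "localization": directory / f"{stem}_localization.tif",
        "fluorescence": directory / f"{stem}_fluorescence.tif",
        "truth": directory / f"{stem}_truth.csv",
    }
    tifffile.imwrite(
        paths["localization"], _to_uint(frameset.localization_frames, bd), photometric="minisblack"
    )
    tifffile.imwrite(
        paths["fluorescence"], _to_uint(frameset.fluorescence_frames, bd), photometric="minisblack"
    )
    frameset.truth_table.to_csv(paths["truth"], index=False, columns=TRUTH_COLUMNS)
    return paths


def read_frames(path: Path | str) -> list[np.ndarray]:
    """Read a multi-page TIFF stack as a list of float 2-D frames."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise InvalidParameterError(f"{path}: expected a 2-D or 3-D grayscale TIFF")
    return [a.astype(float) for a in arr]


def write_series(
    conditions: list[DilutionCondition],
    manifest: pd.DataFrame,
    directory: Path | str,
    config: dict | None = None,
) -> pd.DataFrame:
    """Write a simulated dilution series to a directory.

    Adds a ``stem`` column to the manifest and writes ``manifest.csv``; the
    resolved run configuration, when given, is serialized next to the data.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    stems = []
    for cond in conditions:
        stem = condition_stem(cond.concentration, cond.replicate)
        write_frameset(cond.frameset, directory, stem)
        stems.append(stem)
    manifest["stem"] = stems
    manifest.to_csv(directory / "manifest.csv", index=False)
    if config is not None:
        dump_config(config, directory / "config.yaml")
    return manifest


def read_series_manifest(directory: Path | str) -> pd.DataFrame:
    directory = Path(directory)
    path = directory / "manifest.csv"
    if not path.exists():
        raise NoFramesError(f"no manifest.csv in {directory}")
    return pd.read_csv(path)


def load_config(path: Path | str) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InvalidParameterError(f"{path}: configuration must be a key-value mapping")
    return cfg


def dump_config(config: dict, path: Path | str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
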