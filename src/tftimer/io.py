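"""File I/O: OME-TIFF images, CSV tables, YAML configs, seed derivation."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthetic import (
    CHANNELS,
    SECTIONS,
    DiscImage,
    ScenarioConfig,
    scenario_from_dict,
    scenario_to_dict,
)

__all__ = [
    "IOError_",
    "write_image",
    "read_image",
    "write_table",
    "read_table",
    "write_config",
    "read_config",
    "child_seed",
    "config_hash",
]


class IOError_(ValueError):
    """Malformed file or unknown channel/section."""


def write_image(image: DiscImage, directory) -> list:
    """Write one multichannel OME-TIFF per section (axes CYX).

    Channel order is the documented fixed order (fast, slow, hh, rab7,
    membrane); files are named ``<section>.ome.tif``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for section in SECTIONS:
        if section not in image.sections:
            continue
        path = directory / f"{section}.ome.tif"
        data = np.asarray(image.sections[section], dtype=np.float32)
        tifffile.imwrite(
            path,
            data,
            ome=True,
            metadata={
                "axes": "CYX",
                "Channel": {"Name": list(image.channels)},
                "PhysicalSizeX": image.pixel_size,
                "PhysicalSizeY": image.pixel_size,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeYUnit": "µm",
            },
        )
        paths.append(path)
    return paths


def read_image(directory, pixel_size: float | None = None) -> DiscImage:
    """Read the per-section OME-TIFFs written by :func:`write_image`."""
    directory = Path(directory)
    sections = {}
    for section in SECTIONS:
        path = directory / f"{section}.ome.tif"
        if not path.exists():
            continue
        try:
            with tifffile.TiffFile(path) as tf:
                data = tf.asarray()
                if pixel_size is None:
                    try:
                        px = tf.ome_metadata and tifffile.xml2dict(tf.ome_metadata)
                        pixel_size = float(
                            px["OME"]["Image"]["Pixels"]["PhysicalSizeX"]
                        )
                    except (KeyError, TypeError, ValueError):
                        pixel_size = None
        except (tifffile.TiffFileError, OSError) as err:
            raise IOError_(f"cannot read image {path}: {err}") from err
        if data.ndim != 3 or data.shape[0] != len(CHANNELS):
            raise IOError_(
                f"{path}: expected {len(CHANNELS)}-channel CYX stack, "
                f"got shape {data.shape}"
            )
        sections[section] = data.astype(np.float32)
    if not sections:
        raise IOError_(f"no section images found under {directory}")
    return DiscImage(
        sections=sections, channels=CHANNELS,
        pixel_size=0.2 if pixel_size is None else float(pixel_size),
    )


def write_table(frame: pd.DataFrame, path) -> Path:
    """UTF-8 CSV with a header row and '.' decimal."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, encoding="utf-8")
    return path


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path, encoding="utf-8")
    except (pd.errors.ParserError, OSError, UnicodeDecodeError) as err:
        raise IOError_(f"cannot parse table {path}: {err}") from err


def write_config(scenario: ScenarioConfig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(scenario_to_dict(scenario), fh, sort_keys=True)
    return path


def read_config(path) -> ScenarioConfig:
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as err:
        mark = getattr(err, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark else ""
        raise IOError_(f"cannot parse config {path}{where}: {err}") from err
    if not isinstance(data, dict):
        raise IOError_(f"config {path}: expected a mapping at top level")
    try:
        return scenario_from_dict(data)
    except TypeError as err:
        raise IOError_(f"config {path}: unknown or missing field ({err})") from err


def config_hash(scenario: ScenarioConfig) -> str:
    text = yaml.safe_dump(scenario_to_dict(scenario), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global run seed.

    Stages can be rerun independently and reproducibly; the value is kept
    below 2**31.
    """
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)
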