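"""Image-stack and table I/O.

Stacks are 3D (Z, Y, X) TIFF volumes — one file per channel per timepoint —
read and written with :mod:`tifffile`.  Label maps are 16-bit integer TIFFs.
Object tables and density time courses are plain CSV (UTF-8, '.' decimal)
read and written with :mod:`pandas`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "ImageStack",
    "read_stack",
    "write_stack",
    "read_labels",
    "write_labels",
    "read_table",
    "write_table",
    "load_config",
    "save_config",
]

#: Default voxel size in microns (z, y, x); the 0.2 um Z step matches
#: confocal acquisition and is carried as metadata only — all geometry is
#: computed on the raw voxel grid.
DEFAULT_VOXEL_SIZE_UM = (0.2, 0.1, 0.1)


@dataclass
class ImageStack:
    """A single-channel 3D fluorescence volume in (Z, Y, X) axis order."""

    data: np.ndarray
    channel: str = ""
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"stack must be 3D (Z, Y, X); got {self.data.ndim}D shape {self.data.shape}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def read_stack(path, channel: str | None = None) -> ImageStack:
    """Read a 3D TIFF Z-stack.

    Accepts 8/16-bit integer and 32-bit float TIFFs.  2D images are
    rejected: this pipeline operates on Z-stacks.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        raise ValueError(f"{path} is a 2D image; a 3D Z-stack (Z, Y, X) is required")
    if data.ndim != 3:
        raise ValueError(
            f"{path} has {data.ndim} dimensions; cannot resolve (Z, Y, X) axis order"
        )
    return ImageStack(data=data, channel=channel or path.stem)


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as a (Z, Y, X) TIFF, preserving dtype."""
    tifffile.imwrite(Path(path), np.asarray(stack.data))


def read_labels(path) -> np.ndarray:
    """Read an integer label map from TIFF."""
    data = tifffile.imread(Path(path))
    if data.ndim != 3:
        raise ValueError(f"{path}: label map must be a 3D volume")
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError(f"{path}: label map must be integer-typed, got {data.dtype}")
    return data.astype(np.int32)


def write_labels(labels: np.ndarray, path) -> None:
    """Write a label map as 16-bit TIFF."""
    labels = np.asarray(labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; cannot store as 16-bit TIFF")
    tifffile.imwrite(Path(path), labels.astype(np.uint16), photometric="minisblack")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def write_table(records: pd.DataFrame, path) -> None:
    """Write a table as CSV with header, UTF-8, '.' decimal."""
    if len(records.columns) == 0:
        raise ValueError("refusing to write a table with no columns")
    records.to_csv(Path(path), index=False, encoding="utf-8")


def load_config(path) -> dict:
    """Load a nested key-value (YAML) configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping of sections")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
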