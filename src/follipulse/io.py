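"""Containers and file I/O.

Image data travels as :class:`ImageStack` (frames x channels x rows x
cols, calibrated).  On disk a stack is a multi-page TIFF in channel-major
page order (all frames of channel 0, then all frames of channel 1, ...)
with a JSON sidecar holding calibration, channel names and the generating
parameters.  Tables are CSV with a leading ``#``-commented metadata block
(units, provenance); :func:`write_table` / :func:`read_table` round-trip
them losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

from .errors import InputError

__all__ = [
    "ImageStack",
    "save_stack",
    "load_stack",
    "write_table",
    "read_table",
    "write_json",
]


@dataclass
class ImageStack:
    """Calibrated multi-channel time-lapse image data.

    Attributes
    ----------
    data : ndarray, shape (T, C, H, W)
        Pixel intensities, non-negative.
    channel_names : list of str
        One name per channel, e.g. ``["membrane", "myosin"]``.
    pixel_size_um : float
        Lateral calibration, micrometres per pixel.
    frame_interval_s : float
        Time between consecutive frames, seconds.
    """

    data: np.ndarray
    channel_names: list[str]
    pixel_size_um: float
    frame_interval_s: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise InputError(
                f"stack must be 4-D (T, C, H, W), got shape {self.data.shape}"
            )
        if len(self.channel_names) != self.data.shape[1]:
            raise InputError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} channels"
            )
        if self.pixel_size_um <= 0:
            raise InputError("pixel_size_um must be > 0")
        if self.frame_interval_s <= 0:
            raise InputError("frame_interval_s must be > 0")
        if np.any(self.data < 0):
            raise InputError("intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def channel(self, name: str) -> np.ndarray:
        """Return the (T, H, W) sub-stack for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise InputError(
                f"no channel {name!r}; have {self.channel_names}"
            ) from None
        return self.data[:, idx]


def save_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF (channel-major) plus JSON sidecar."""
    path = Path(path)
    t, c, h, w = stack.data.shape
    # channel-major page order: page index = channel * T + frame
    pages = stack.data.transpose(1, 0, 2, 3).reshape(c * t, h, w)
    tifffile.imwrite(path, pages.astype(np.float32), photometric="minisblack")
    sidecar = {
        "n_frames": t,
        "channel_names": stack.channel_names,
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_s": stack.frame_interval_s,
        "page_order": "channel-major",
        "meta": _jsonable(stack.meta),
    }
    write_json(sidecar, path.with_suffix(path.suffix + ".json"))
    return path


def load_stack(path: str | Path) -> ImageStack:
    """Read a stack written by :func:`save_stack`."""
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    t = sidecar["n_frames"]
    c = len(sidecar["channel_names"])
    if pages.shape[0] != t * c:
        raise InputError(
            f"TIFF has {pages.shape[0]} pages, sidecar promises {t * c}"
        )
    data = pages.reshape(c, t, *pages.shape[1:]).transpose(1, 0, 2, 3)
    return ImageStack(
        data=data,
        channel_names=list(sidecar["channel_names"]),
        pixel_size_um=sidecar["pixel_size_um"],
        frame_interval_s=sidecar["frame_interval_s"],
        meta=sidecar.get("meta", {}),
    )


def save_labels(labels: np.ndarray, path: str | Path) -> Path:
    """Write a (T, H, W) or (H, W) label stack as 16-bit TIFF."""
    labels = np.asarray(labels)
    if labels.max() >= 2**16:
        raise InputError("more than 65535 labels; cannot write 16-bit TIFF")
    tifffile.imwrite(
        Path(path), labels.astype(np.uint16), photometric="minisblack"
    )
    return Path(path)


def load_labels(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)), dtype=np.int32)


def write_table(
    df: pd.DataFrame, path: str | Path, metadata: Mapping[str, str] | None = None
) -> Path:
    """Write a CSV with a ``#``-commented metadata header block."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, skipping metadata lines."""
    return pd.read_csv(Path(path), comment="#")


def read_table_metadata(path: str | Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(Path(path)) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition(":")
            meta[key.strip()] = val.strip()
    return meta


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays and dataclass-like objects."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
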