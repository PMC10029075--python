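"""Multichannel image stack / movie containers and TIFF round-trip.

Conventions used throughout the package:

- canonical axis order ``(channel, z, y, x)``; singleton axes are kept;
- indices are 0-based; z-windows are half-open ``[start, stop)``;
- intensities are floating point in memory regardless of file dtype, with the
  original dtype recorded so writes can restore it;
- physical pixel sizes are micrometres per pixel (xy) or per plane (z); when a
  file carries no metadata they default to 1.0 with a logged warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = ["ImageStack", "Movie", "read_stack", "write_stack", "max_project"]


@dataclass
class ImageStack:
    """Multichannel intensity volume with physical pixel metadata.

    ``data`` is indexed ``(channel, z, y, x)``; 2D images keep a singleton z.
    ``expansion_factor`` is the linear post/pre expansion ratio the stack has
    been normalized with, or ``None`` when the stack is on its raw scale.
    """

    data: np.ndarray
    pixel_size_xy: float = 1.0
    pixel_size_z: float = 1.0
    channel_names: list[str] = field(default_factory=list)
    expansion_factor: float | None = None
    dtype_on_disk: np.dtype | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[None, None]
        elif self.data.ndim == 3:
            self.data = self.data[:, None]
        if self.data.ndim != 4:
            raise ValueError(f"expected <=4 axes (c, z, y, x), got shape {self.data.shape}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        self.validate()

    def validate(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image stack contains non-finite intensities")
        if np.any(self.data < 0):
            raise ValueError("image stack contains negative intensities")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )
        if self.pixel_size_xy <= 0:
            raise ValueError("pixel_size_xy must be positive")
        if self.data.shape[1] > 1 and self.pixel_size_z <= 0:
            raise ValueError("pixel_size_z must be positive for multi-plane stacks")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_planes(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """(z, y, x) volume for one channel, by name or positional index."""
        if isinstance(name_or_index, str):
            name_or_index = self.channel_names.index(name_or_index)
        return self.data[name_or_index]


@dataclass
class Movie:
    """Time series of 2D frames, indexed ``(t, y, x)``."""

    frames: np.ndarray
    frame_interval: float = 0.1
    pixel_size_xy: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"expected (t, y, x) frames, got shape {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise ValueError("a movie needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("movie contains non-finite intensities")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# Axis codes tifffile uses for the dimensions we care about.
_AXIS_TO_ROLE = {"C": "c", "S": "c", "Z": "z", "Q": "z", "I": "z", "T": "z", "Y": "y", "X": "x"}


def _canonicalize(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder a tifffile array with axis string ``axes`` into (c, z, y, x)."""
    roles = []
    for ax in axes:
        role = _AXIS_TO_ROLE.get(ax)
        if role is None:
            raise ValueError(f"cannot interpret axis {ax!r} in axes {axes!r} for shape {data.shape}")
        roles.append(role)
    for needed in ("c", "z", "y", "x"):
        if needed not in roles:
            data = data[None]
            roles.insert(0, needed)
    if sorted(roles) != ["c", "x", "y", "z"]:
        raise ValueError(f"ambiguous axes {axes!r} for shape {data.shape}; pass axis_order_hint")
    order = [roles.index(r) for r in ("c", "z", "y", "x")]
    return np.transpose(data, order)


def read_stack(path: str | Path, axis_order_hint: str | None = None) -> ImageStack:
    """Read a TIFF / OME-TIFF into an :class:`ImageStack`.

    ``axis_order_hint`` (e.g. ``"ZCYX"``) overrides the axis string recorded in
    the file; it is required when the file tags leave the layout ambiguous.
    Missing pixel-size metadata defaults to 1.0 µm with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = axis_order_hint or series.axes
        meta = _read_metadata(tf)
    data = _canonicalize(data, axes)
    if meta.get("pixel_size_xy") is None:
        logger.warning("%s: no pixel-size metadata; defaulting to 1.0 um/px", path.name)
    names = meta.get("channel_names") or [f"ch{i}" for i in range(data.shape[0])]
    return ImageStack(
        data=data.astype(float),
        pixel_size_xy=meta.get("pixel_size_xy") or 1.0,
        pixel_size_z=meta.get("pixel_size_z") or 1.0,
        channel_names=list(names)[: data.shape[0]],
        expansion_factor=meta.get("expansion_factor"),
        dtype_on_disk=data.dtype,
    )


def _read_metadata(tf: tifffile.TiffFile) -> dict:
    meta: dict = {}
    if tf.ome_metadata:
        try:
            ome = tifffile.xml2dict(tf.ome_metadata)["OME"]
            image = ome["Image"]
            if isinstance(image, list):
                image = image[0]
            pixels = image["Pixels"]
            meta["pixel_size_xy"] = pixels.get("PhysicalSizeX")
            meta["pixel_size_z"] = pixels.get("PhysicalSizeZ")
            chans = pixels.get("Channel", [])
            if isinstance(chans, dict):
                chans = [chans]
            names = [c.get("Name") for c in chans]
            if names and all(n is not None for n in names):
                meta["channel_names"] = names
            desc = image.get("Description")
            if desc:
                try:
                    sidecar = json.loads(desc)
                    if sidecar.get("expansion_factor") is not None:
                        meta["expansion_factor"] = sidecar["expansion_factor"]
                except (TypeError, ValueError):
                    pass
        except (KeyError, TypeError):  # malformed OME block: fall back to defaults
            pass
    ij = tf.imagej_metadata or {}
    if "exmquant" in ij:
        try:
            meta.update(json.loads(ij["exmquant"]))
        except (TypeError, ValueError):
            pass
    return meta


def write_stack(path: str | Path, stack: ImageStack, dtype: np.dtype | str | None = None) -> Path:
    """Write an :class:`ImageStack` as OME-TIFF, preserving metadata.

    Data are written in the dtype they were loaded with (or ``dtype``);
    floating-point stacks never created from a file stay float32.
    """
    path = Path(path)
    out_dtype = np.dtype(dtype or stack.dtype_on_disk or np.float32)
    data = stack.data
    if np.issubdtype(out_dtype, np.integer):
        data = np.clip(np.rint(data), np.iinfo(out_dtype).min, np.iinfo(out_dtype).max)
    data = data.astype(out_dtype)
    sidecar = {
        "pixel_size_xy": stack.pixel_size_xy,
        "pixel_size_z": stack.pixel_size_z,
        "channel_names": stack.channel_names,
        "expansion_factor": stack.expansion_factor,
    }
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": stack.pixel_size_xy,
            "PhysicalSizeY": stack.pixel_size_xy,
            "PhysicalSizeZ": stack.pixel_size_z,
            "Channel": {"Name": stack.channel_names},
            "Description": json.dumps(sidecar),
        },
    )
    # OME description round-trips expansion_factor; also store as sidecar JSON
    # so plain-TIFF readers can recover it.
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))
    return path


def max_project(stack: ImageStack, channel: int | str, z_window: tuple[int, int]) -> np.ndarray:
    """Maximum-intensity projection of one channel over planes [start, stop).

    This is the projection used to pair a single pre-expansion plane with the
    post-expansion volume, where one projection over 5-30 planes corresponds to
    the pre-expansion focal plane.
    """
    start, stop = z_window
    vol = stack.channel(channel)
    if not (0 <= start < stop <= vol.shape[0]):
        raise IndexError(
            f"z window [{start}, {stop}) out of range for {vol.shape[0]} planes"
        )
    return vol[start:stop].max(axis=0)
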