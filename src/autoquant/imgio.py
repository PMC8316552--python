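"""Image stack I/O and projection.

Stacks are held as ``(channel, z, row, col)`` arrays.  TIFF is the only
image format; pixel size travels in the ImageJ-style resolution metadata
and falls back to 1.0 px units with a warning when absent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError, ParameterError

logger = logging.getLogger(__name__)

__all__ = ["ImageStack", "read_stack", "write_stack", "max_intensity_projection"]


@dataclass
class ImageStack:
    """A multi-channel, optionally multi-plane image.

    Parameters
    ----------
    data:
        Array indexed ``(channel, z, row, col)``.
    channel_names:
        One unique name per channel.
    pixel_size:
        Lateral pixel size in µm/px (1.0 when unknown).
    z_step:
        Axial step in µm, or ``None`` for single-plane data.
    provenance:
        Free-text origin of the data (file path or generator id).
    """

    data: np.ndarray
    channel_names: tuple[str, ...] = ()
    pixel_size: float = 1.0
    z_step: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ParameterError(
                f"stack data must be (channel, z, row, col); got ndim={self.data.ndim}"
            )
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.data.shape[0]))
        if len(self.channel_names) != self.data.shape[0]:
            raise ParameterError("one channel name required per channel")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ParameterError(f"channel names not unique: {self.channel_names}")
        if self.pixel_size <= 0:
            raise ParameterError(f"pixel size must be positive, got {self.pixel_size}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_z(self) -> int:
        return self.data.shape[1]

    @property
    def shape_2d(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, name: str) -> np.ndarray:
        """Return the 2-D image for a named channel (errors if z > 1)."""
        if name not in self.channel_names:
            raise ParameterError(f"no channel named {name!r}; have {self.channel_names}")
        if self.n_z != 1:
            raise ParameterError("project the stack before extracting 2-D channels")
        return self.data[self.channel_names.index(name), 0]


def _normalize_axes(arr: np.ndarray, axes: str | None) -> np.ndarray:
    """Coerce a tifffile array into (channel, z, row, col)."""
    if axes is not None and set(axes) <= set("CZYXS") and len(axes) == arr.ndim:
        order = [axes.index(a) for a in "CZYX" if a in axes]
        rest = [i for i in range(arr.ndim) if i not in order]
        if rest:  # samples axis etc. not supported
            raise FormatError(f"unsupported TIFF axes {axes!r}")
        arr = arr.transpose(order)
        for i, a in enumerate("CZYX"):
            if a not in axes:
                arr = np.expand_dims(arr, i)
        return arr
    if arr.ndim == 2:
        return arr[None, None]
    if arr.ndim == 3:  # assume leading channel axis
        return arr[:, None]
    if arr.ndim == 4:
        return arr
    raise FormatError(f"cannot interpret array of ndim {arr.ndim} as an image stack")


def read_stack(path: str | Path) -> ImageStack:
    """Read a TIFF into an :class:`ImageStack`.

    Axes are normalized to ``(channel, z, row, col)``: 2-D files become
    one channel / one plane, 3-D files are read as ``(channel, row, col)``
    unless the TIFF declares its axes.  Pixel size is taken from the
    ImageJ/description metadata when present, otherwise defaults to 1.0
    with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            arr = series.asarray()
            axes = series.axes
            desc = tif.pages[0].description or ""
            shaped = tif.shaped_metadata
    except (tifffile.TiffFileError, ValueError) as exc:
        raise FormatError(f"unreadable TIFF {path}: {exc}") from exc

    data = _normalize_axes(arr, axes)

    pixel_size = 1.0
    z_step = None
    channel_names: tuple[str, ...] = ()
    sidecar = {}
    if shaped:
        sidecar = dict(shaped[0])
    elif desc.startswith("{"):
        try:
            sidecar = json.loads(desc)
        except json.JSONDecodeError:
            sidecar = {}
    if "pixel_size_um" in sidecar:
        pixel_size = float(sidecar["pixel_size_um"])
    else:
        logger.warning("%s: no pixel-size metadata, assuming 1.0 px units", path)
    if sidecar.get("z_step_um") is not None:
        z_step = float(sidecar["z_step_um"])
    if "channel_names" in sidecar:
        channel_names = tuple(sidecar["channel_names"])

    if np.issubdtype(data.dtype, np.floating) and (data < 0).any():
        data = np.clip(data, 0, None)
    return ImageStack(
        data=data,
        channel_names=channel_names,
        pixel_size=pixel_size,
        z_step=z_step,
        provenance=str(path),
    )


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as TIFF with a JSON description carrying the metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        stack.data,
        photometric="minisblack",
        metadata={
            "pixel_size_um": stack.pixel_size,
            "z_step_um": stack.z_step,
            "channel_names": list(stack.channel_names),
        },
    )


def max_intensity_projection(stack: ImageStack) -> ImageStack:
    """Collapse z by a per-channel, per-pixel maximum.

    A single-plane stack is returned unchanged (new object, same values).
    """
    if stack.data.size == 0:
        raise ParameterError("cannot project an empty stack")
    projected = stack.data.max(axis=1, keepdims=True)
    return replace(stack, data=projected, z_step=None)
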