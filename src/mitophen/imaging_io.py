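"""Calibrated multi-channel TIFF I/O and axis utilities.

Every image in this package is carried as an :class:`ImageStack` whose pixel
array always has the canonical axis order ``(frame, channel, z, y, x)``;
missing axes are kept as explicit singletons.  Physical calibration
(``pixel_size_um``, ``frame_interval_min``) and channel identities travel with
the pixels so that downstream stages can report distances in micrometres
without per-call bookkeeping.

Points are ``(x, y)`` pairs of 0-based pixel indices (continuous, sub-pixel
positions allowed).  Distances are converted to micrometres through
``pixel_size_um``, which is isotropic in x and y.

On disk, stacks are plain TIFF files.  Calibration, channel names and the
5-D shape are stored as a JSON object in the ImageDescription tag, so a stack
round-trips bit-for-bit through :func:`write_stack` / :func:`read_stack`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError, GeometryError

#: Channel labels understood by the quantification stages.
CHANNEL_VOCAB = ("dna", "gfp", "tubulin", "centrin", "kif22")

#: Default physical calibration (60x/100x sCMOS imaging).
DEFAULT_PIXEL_SIZE_UM = 0.11
DEFAULT_FRAME_INTERVAL_MIN = 1.0

_DESC_KEY = "mitophen"

_DEFAULT_NAMES = {
    1: ("dna",),
    2: ("dna", "tubulin"),
    3: ("dna", "centrin", "gfp"),
    4: ("dna", "gfp", "tubulin", "centrin"),
    5: CHANNEL_VOCAB,
}


@dataclass(frozen=True)
class ImageStack:
    """Multi-channel, optionally multi-frame pixel data with calibration.

    Parameters
    ----------
    pixels
        Real-valued array indexed ``(frame, channel, z, y, x)``.  Values must
        be finite and non-negative (fluorescence counts).
    pixel_size_um
        Micrometres per pixel, isotropic in x and y.  Must be positive.
    frame_interval_min
        Minutes per frame; 0 for fixed (single timepoint) images.
    channel_names
        Ordered labels, one per channel, drawn from :data:`CHANNEL_VOCAB`.
    """

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_min: float = 0.0
    channel_names: tuple[str, ...] = ("dna",)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 5:
            raise FormatError(
                f"pixels must be 5-D (frame, channel, z, y, x); got {px.ndim}-D"
            )
        if not np.issubdtype(px.dtype, np.floating):
            px = px.astype(np.float32)
        if not np.all(np.isfinite(px)):
            raise FormatError("pixel values must be finite")
        if px.size and px.min() < 0:
            raise FormatError("pixel values must be non-negative")
        if not self.pixel_size_um > 0:
            raise FormatError("pixel_size_um must be positive")
        if self.frame_interval_min < 0:
            raise FormatError("frame_interval_min must be non-negative")
        names = tuple(self.channel_names)
        if len(names) != px.shape[1]:
            raise FormatError(
                f"{len(names)} channel names for {px.shape[1]} channels"
            )
        unknown = [n for n in names if n not in CHANNEL_VOCAB]
        if unknown:
            raise FormatError(f"unknown channel names {unknown}; "
                              f"expected labels from {CHANNEL_VOCAB}")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "channel_names", names)

    # -- convenience accessors -------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_z(self) -> int:
        return self.pixels.shape[2]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[3], self.pixels.shape[4]

    @property
    def field_size_um(self) -> tuple[float, float]:
        """Physical extent (height, width) in micrometres."""
        h, w = self.shape_yx
        return h * self.pixel_size_um, w * self.pixel_size_um

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise FormatError(
                f"no channel named '{name}' in {self.channel_names}"
            ) from None

    def has_channel(self, name: str) -> bool:
        return name in self.channel_names

    def plane(self, name: str, frame: int = 0) -> np.ndarray:
        """A single ``(y, x)`` plane: named channel, given frame, z projected."""
        z = self.pixels[frame, self.channel_index(name)]
        return z.max(axis=0) if z.shape[0] > 1 else z[0]

    def replace(self, **kwargs) -> "ImageStack":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class CircularRoi:
    """Circular region of interest: continuous pixel center, radius in um."""

    center_xy: tuple[float, float]
    radius_um: float

    def __post_init__(self) -> None:
        if not self.radius_um > 0:
            raise GeometryError("ROI radius must be positive")

    def validate_inside(self, stack: ImageStack) -> None:
        h, w = stack.shape_yx
        x, y = self.center_xy
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise GeometryError(
                f"ROI center {self.center_xy} outside image of shape {(h, w)}"
            )


# -- axis normalization ----------------------------------------------------

def _promote_to_5d(arr: np.ndarray) -> np.ndarray:
    """Normalize a 2-5 dimensional array to (frame, channel, z, y, x).

    The trailing two axes are always (y, x).  A single leading axis is taken
    as frames; two leading axes as (frame, channel).  This matches the shapes
    written by this package and common exported time-lapse TIFFs.
    """
    if arr.ndim == 2:
        return arr[None, None, None]
    if arr.ndim == 3:
        return arr[:, None, None]
    if arr.ndim == 4:
        return arr[:, :, None]
    if arr.ndim == 5:
        return arr
    raise FormatError(f"cannot interpret a {arr.ndim}-D array as an image stack")


def read_stack(
    path: str | Path,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    frame_interval_min: float = 0.0,
    channel_names: tuple[str, ...] | None = None,
) -> ImageStack:
    """Read a TIFF file into the canonical (frame, channel, z, y, x) layout.

    Calibration and channel names are taken from the file's JSON description
    (as written by :func:`write_stack`) when present; otherwise the arguments
    are used, with positional channel-name defaults by channel count.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            desc = tif.pages[0].description or ""
    except (OSError, tifffile.TiffFileError) as exc:
        raise OSError(f"cannot read TIFF file {path}: {exc}") from exc

    meta = None
    if desc:
        try:
            meta = json.loads(desc).get(_DESC_KEY)
        except (json.JSONDecodeError, AttributeError):
            meta = None

    if meta is not None:
        shape = tuple(int(s) for s in meta["stack_shape"])
        if int(np.prod(shape)) != arr.size:
            raise FormatError(
                f"metadata shape {shape} does not match pixel count {arr.size}"
            )
        pixels = arr.reshape(shape)
        return ImageStack(
            pixels=pixels,
            pixel_size_um=float(meta.get("pixel_size_um", pixel_size_um)),
            frame_interval_min=float(
                meta.get("frame_interval_min", frame_interval_min)
            ),
            channel_names=tuple(meta["channel_names"]),
        )

    pixels = _promote_to_5d(arr)
    if channel_names is None:
        n_chan = pixels.shape[1]
        if n_chan not in _DEFAULT_NAMES:
            raise FormatError(
                f"{n_chan} channels: channel_names must be given explicitly"
            )
        channel_names = _DEFAULT_NAMES[n_chan]
    return ImageStack(
        pixels=pixels,
        pixel_size_um=pixel_size_um,
        frame_interval_min=frame_interval_min,
        channel_names=tuple(channel_names),
    )


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as TIFF; :func:`read_stack` recovers it exactly."""
    path = Path(path)
    if not path.parent.exists():
        raise OSError(f"parent directory {path.parent} does not exist")
    desc = json.dumps(
        {
            _DESC_KEY: {
                "stack_shape": list(stack.pixels.shape),
                "pixel_size_um": stack.pixel_size_um,
                "frame_interval_min": stack.frame_interval_min,
                "channel_names": list(stack.channel_names),
            }
        }
    )
    tifffile.imwrite(
        path,
        stack.pixels,
        photometric="minisblack",
        description=desc,
        metadata=None,
        shaped=False,
    )
    return path


def max_project_z(stack: ImageStack) -> ImageStack:
    """Maximum-intensity projection over z; idempotent."""
    if stack.n_z == 1:
        return stack
    return stack.replace(pixels=stack.pixels.max(axis=2, keepdims=True))
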