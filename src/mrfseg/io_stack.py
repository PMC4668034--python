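"""Reading and writing of anisotropic multichannel image stacks and label maps.

Stacks are multi-page greyscale TIFFs, one file per fluorescence channel
(false colour: red = tumour cells, green = CAFs).  Physical voxel spacing is
supplied by the caller — confocal protocols in this regime use ~0.5 um
in-plane pixels and 10-40 um between slices, and the spacing drives the
distance weighting of the between-slice MRF edges downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile

BACKGROUND, TUMOUR, CAF = 0, 1, 2

#: palette used when writing indexed label maps (channels x 256 entries):
#: background black, tumour red, CAF green.
LABEL_PALETTE = np.zeros((3, 256), dtype=np.uint16)
LABEL_PALETTE[0, TUMOUR] = 65535
LABEL_PALETTE[1, CAF] = 65535


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical voxel spacing in micrometres.

    Attributes
    ----------
    dz : float
        Distance between adjacent slices (um).
    dy, dx : float
        In-plane pixel size along rows / columns (um).
    """

    dz: float
    dy: float
    dx: float

    def __post_init__(self) -> None:
        if not (self.dz > 0 and self.dy > 0 and self.dx > 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def anisotropy(self) -> float:
        """Between-slice distance in units of the in-plane pixel size (dz/dx)."""
        return self.dz / self.dx


@dataclass
class ImageStack:
    """A 3D multichannel stack of 8-bit intensities, axes (z, y, x, channel)."""

    data: np.ndarray
    spacing: VoxelSpacing
    channel_names: list[str] = field(default_factory=lambda: ["red", "green"])

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("ImageStack data must have axes (z, y, x, channel)")
        nc = self.data.shape[3]
        if not 1 <= nc <= 2:
            raise ValueError(f"expected 1 or 2 channels, got {nc}")
        if len(self.channel_names) != nc:
            raise ValueError("channel_names length must equal channel count")
        if self.data.dtype != np.uint8:
            if self.data.min() < 0 or self.data.max() > 255:
                raise ValueError("intensities must lie in [0, 255]; quantize first")
            self.data = self.data.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape


@dataclass
class LabelMap:
    """Per-voxel labels in {0 background, 1 tumour, 2 CAF}, axes (z, y, x)."""

    labels: np.ndarray
    spacing: VoxelSpacing

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabelMap must have axes (z, y, x)")
        if not np.isin(self.labels, (BACKGROUND, TUMOUR, CAF)).all():
            raise ValueError("labels must be in {0, 1, 2}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


def quantize_8bit(raw: np.ndarray, bit_depth: int) -> np.ndarray:
    """Down-sample a raw integer image to 8-bit.

    Full-dynamic-range scaling v -> round(v * 255 / (2**b - 1)) with round
    half up, so mixture fits remain comparable across stacks (per-image
    min--max stretching would not be).  8-bit input is returned unchanged.
    """
    if bit_depth not in (8, 16):
        raise ValueError(f"unsupported bit depth {bit_depth}")
    raw = np.asarray(raw)
    if raw.min() < 0 or raw.max() > 2**bit_depth - 1:
        raise ValueError(f"values outside [0, {2**bit_depth - 1}]")
    if bit_depth == 8:
        return raw.astype(np.uint8)
    scaled = raw.astype(np.float64) * (255.0 / (2**bit_depth - 1))
    return np.floor(scaled + 0.5).astype(np.uint8)


def _read_pages(path) -> np.ndarray:
    """Read a multi-page TIFF as a (z, y, x) greyscale array."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 4 and arr.shape[-1] in (3, 4):
        raise ValueError(f"{path}: colour (multi-sample) pages are not supported "
                         "for per-channel stacks")
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected multi-page greyscale TIFF, got shape {arr.shape}")
    return arr


def read_stack(paths_per_channel: list, spacing: VoxelSpacing,
               channel_names: list[str] | None = None) -> ImageStack:
    """Read one greyscale multi-page TIFF per channel into an ImageStack.

    Raw bit depths above 8 are passed through :func:`quantize_8bit`.
    All channels must share page count and page dimensions.
    """
    channels = []
    for path in paths_per_channel:
        arr = _read_pages(path)
        if arr.dtype == np.uint8:
            arr = quantize_8bit(arr, 8)
        elif arr.dtype == np.uint16:
            arr = quantize_8bit(arr, 16)
        else:
            raise ValueError(f"{path}: unsupported dtype {arr.dtype}")
        channels.append(arr)
    shapes = {c.shape for c in channels}
    if len(shapes) != 1:
        raise ValueError(f"channel shapes differ: {sorted(shapes)}")
    if channel_names is None:
        channel_names = ["red", "green"][: len(channels)] if len(channels) <= 2 \
            else [f"ch{i}" for i in range(len(channels))]
    return ImageStack(np.stack(channels, axis=-1), spacing, list(channel_names))


def read_rgb_stack(path, spacing: VoxelSpacing) -> ImageStack:
    """Read an RGB TIFF, splitting R and G planes; the blue plane is ignored."""
    arr = tifffile.imread(path)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4 or arr.shape[-1] not in (3, 4):
        raise ValueError(f"{path}: not an RGB(A) multi-page TIFF")
    if arr[..., 2].any():
        warnings.warn(f"{path}: blue plane is non-empty and will be ignored")
    data = arr[..., :2]
    if data.dtype == np.uint16:
        data = quantize_8bit(data, 16)
    return ImageStack(data.astype(np.uint8), spacing, ["red", "green"])


def write_stack(stack: ImageStack, paths_per_channel: list) -> None:
    """Write each channel of a stack as a multi-page greyscale TIFF."""
    if len(paths_per_channel) != stack.data.shape[3]:
        raise ValueError("need one output path per channel")
    for c, path in enumerate(paths_per_channel):
        tifffile.imwrite(path, stack.data[..., c], photometric="minisblack")


def write_labelmap(labelmap: LabelMap, path) -> None:
    """Write a label map as an indexed multi-page TIFF.

    Values stay {0, 1, 2}; the embedded palette renders background black,
    tumour red and CAF green.
    """
    tifffile.imwrite(path, labelmap.labels, colormap=LABEL_PALETTE,
                     photometric="palette")


def read_labelmap(path, spacing: VoxelSpacing) -> LabelMap:
    """Read a label map written by :func:`write_labelmap` (palette ignored)."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return LabelMap(arr, spacing)
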