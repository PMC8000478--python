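"""Image loading, region-of-interest cropping, and per-channel summaries.

The measurement geometry is a cuvette photographed against a fixed support,
so the informative pixels always fall inside one fixed rectangular region of
interest (ROI) covering the cuvette viewing window — 1244 x 231 pixels by
default.  This module reads 8-bit RGB images, crops that window, and reduces
it to per-channel arithmetic means plus exact 256-bin intensity histograms.
The channel means are the intensities entering the Beer-Lambert style
absorbance computation (:mod:`eeye.absorbance`).

Coordinate convention (used everywhere in the package): 0-based, row-major
pixel indices; an ROI is specified by its top-left corner ``(x0, y0)`` and a
half-open extent ``[y0, y0 + height) x [x0, x0 + width)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import ConfigurationError, ImageIOError

__all__ = [
    "RGBImage",
    "ROISpec",
    "ChannelSummary",
    "load_image",
    "save_image",
    "crop_roi",
    "channel_summary",
    "DEFAULT_ROI_WIDTH",
    "DEFAULT_ROI_HEIGHT",
]

DEFAULT_ROI_WIDTH = 1244
DEFAULT_ROI_HEIGHT = 231


@dataclass
class RGBImage:
    """An 8-bit RGB pixel grid with optional measurement metadata.

    Attributes
    ----------
    pixels:
        ``(H, W, 3)`` array of dtype ``uint8``, channel order R, G, B.
    tag, cuvette, image_index:
        Optional provenance: sample tag (e.g. ``"A7"``), cuvette replicate
        number, and image repetition number within the cuvette.
    """

    pixels: np.ndarray
    tag: str | None = None
    cuvette: int | None = None
    image_index: int | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must contain at least one pixel")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class ROISpec:
    """Rectangular region of interest: top-left corner plus size, in pixels."""

    x0: int = 0
    y0: int = 0
    width: int = DEFAULT_ROI_WIDTH
    height: int = DEFAULT_ROI_HEIGHT

    def __post_init__(self) -> None:
        if self.x0 < 0 or self.y0 < 0:
            raise ConfigurationError(f"ROI corner must be non-negative, got ({self.x0}, {self.y0})")
        if self.width < 1 or self.height < 1:
            raise ConfigurationError(f"ROI size must be positive, got {self.width} x {self.height}")

    def validate_within(self, height: int, width: int) -> None:
        """Raise if the ROI does not fit inside an ``height x width`` frame."""
        if self.x0 + self.width > width:
            raise ConfigurationError(
                f"ROI right edge x0 + width = {self.x0 + self.width} exceeds image width {width}"
            )
        if self.y0 + self.height > height:
            raise ConfigurationError(
                f"ROI bottom edge y0 + height = {self.y0 + self.height} exceeds image height {height}"
            )

    @classmethod
    def centered(cls, frame_height: int, frame_width: int,
                 width: int = DEFAULT_ROI_WIDTH, height: int = DEFAULT_ROI_HEIGHT) -> "ROISpec":
        """ROI of the given size centered in a frame (default cuvette window placement)."""
        return cls(x0=(frame_width - width) // 2, y0=(frame_height - height) // 2,
                   width=width, height=height)


@dataclass
class ChannelSummary:
    """Per-channel mean intensities and exact 256-bin histograms of a region.

    The means are unrounded floating-point arithmetic means over all pixels;
    each histogram counts pixels per intensity value 0..255 and therefore
    sums to the pixel count of the summarised region.
    """

    mean_r: float
    mean_g: float
    mean_b: float
    hist_r: np.ndarray = field(repr=False)
    hist_g: np.ndarray = field(repr=False)
    hist_b: np.ndarray = field(repr=False)
    tag: str | None = None
    cuvette: int | None = None
    image_index: int | None = None

    @property
    def n_pixels(self) -> int:
        return int(self.hist_r.sum())

    @property
    def means(self) -> tuple[float, float, float]:
        return (self.mean_r, self.mean_g, self.mean_b)


def load_image(path: str | Path, *, convert: bool = False) -> RGBImage:
    """Read a PNG or JPEG file as an :class:`RGBImage`.

    Parameters
    ----------
    path:
        Image file to read.
    convert:
        If True, grayscale images are replicated across channels and an
        alpha channel is dropped; if False (default) such inputs are
        rejected with :class:`~eeye.errors.ImageIOError`.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises a mix of OSError/ValueError subclasses
        raise ImageIOError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        if not convert:
            raise ImageIOError(f"{path}: grayscale image, expected 3 RGB channels")
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        if not convert:
            raise ImageIOError(f"{path}: image has an alpha channel, expected 3 RGB channels")
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageIOError(f"{path}: unsupported channel layout, shape {arr.shape}")
    return RGBImage(pixels=arr.astype(np.uint8))


def save_image(img: RGBImage, path: str | Path) -> Path:
    """Write an image to disk; PNG is lossless and the format used in tests."""
    path = Path(path)
    iio.imwrite(path, img.pixels)
    return path


def crop_roi(img: RGBImage, roi: ROISpec) -> RGBImage:
    """Crop the region of interest out of a frame, preserving metadata.

    Output pixel ``(i, j)`` equals input pixel ``(y0 + i, x0 + j)``.
    """
    roi.validate_within(img.height, img.width)
    window = img.pixels[roi.y0:roi.y0 + roi.height, roi.x0:roi.x0 + roi.width, :]
    return replace(img, pixels=window.copy())


def channel_summary(img: RGBImage) -> ChannelSummary:
    """Summarise an image region as per-channel means and histograms."""
    px = img.pixels
    hists = [np.bincount(px[:, :, c].ravel(), minlength=256) for c in range(3)]
    means = px.reshape(-1, 3).mean(axis=0, dtype=np.float64)
    return ChannelSummary(
        mean_r=float(means[0]), mean_g=float(means[1]), mean_b=float(means[2]),
        hist_r=hists[0], hist_g=hists[1], hist_b=hists[2],
        tag=img.tag, cuvette=img.cuvette, image_index=img.image_index,
    )
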