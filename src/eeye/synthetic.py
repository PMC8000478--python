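"""Synthetic electronic-eye measurements with the study's replicate structure.

No raw cuvette images are publicly deposited for the tequila study, so
every downstream stage is exercised against a generator that reproduces the
*statistical* structure of the measurements: 25 samples (8 Silver, 12 Aged,
5 Extra-aged), each measured in 3 cuvettes with 10 images per cuvette — 750
replicates — plus a deionised-water blank with channel intensities
(255, 251, 253).

Two modes are provided:

* **feature mode** draws per-replicate absorbance triplets directly from
  per-channel Gaussians with the reference means and replicate SDs
  (truncated at zero; the published summaries report only mean +/- SD, so
  normality and cross-channel independence are modelling assumptions);
* **image mode** renders full camera frames: a per-replicate mean intensity
  is drawn once per image from the intensity-level Gaussian (replicate
  scatter), then per-pixel texture noise of scale ``texture_sd`` is added
  inside the cuvette window (ROI) and the surround is a dark constant.

Randomness is reproducible: every (sample, replicate) pair gets its own
stream derived deterministically from ``(seed, tag, replicate_index)``, so
datasets are bit-identical for a given seed regardless of generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .absorbance import DatasetTable
from .categories import CATEGORY_ORDER, category_from_tag
from .errors import ConfigurationError
from .imaging import RGBImage, ROISpec

__all__ = [
    "SampleParams",
    "GeneratorConfig",
    "generate_feature_dataset",
    "generate_image",
    "generate_blank_image",
    "generate_image_set",
]

#: Pixel value used outside the region of interest (dark chamber surround).
DARK_SURROUND = 10


def _triplet(values, name: str, low: float | None = None, high: float | None = None):
    vals = tuple(float(v) for v in values)
    if len(vals) != 3:
        raise ConfigurationError(f"{name} must have three components, got {values!r}")
    if low is not None and any(v < low for v in vals):
        raise ConfigurationError(f"{name} components must be >= {low}, got {vals}")
    if high is not None and any(v > high for v in vals):
        raise ConfigurationError(f"{name} components must be <= {high}, got {vals}")
    return vals


@dataclass(frozen=True)
class SampleParams:
    """Measurement distribution of one sample, at intensity and absorbance level.

    Means/SDs describe replicate-to-replicate scatter of per-image channel
    summaries (not pixel texture).
    """

    tag: str
    category: str
    intensity_mean: tuple[float, float, float]
    intensity_sd: tuple[float, float, float]
    absorbance_mean: tuple[float, float, float]
    absorbance_sd: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_ORDER:
            raise ConfigurationError(f"unknown category {self.category!r} for tag {self.tag}")
        if category_from_tag(self.tag) != self.category:
            raise ConfigurationError(
                f"tag {self.tag!r} prefix does not match category {self.category!r}"
            )
        object.__setattr__(self, "intensity_mean",
                           _triplet(self.intensity_mean, "intensity_mean", 0.0, 255.0))
        object.__setattr__(self, "intensity_sd",
                           _triplet(self.intensity_sd, "intensity_sd", 0.0))
        object.__setattr__(self, "absorbance_mean",
                           _triplet(self.absorbance_mean, "absorbance_mean"))
        object.__setattr__(self, "absorbance_sd",
                           _triplet(self.absorbance_sd, "absorbance_sd", 0.0))


def _default_samples() -> list[SampleParams]:
    from .reference import reference_samples

    return reference_samples()


@dataclass
class GeneratorConfig:
    """Configuration of one synthetic measurement session.

    Defaults reproduce the study layout: 25 reference samples x 3 cuvettes
    x 10 images = 750 replicates, 1944 x 2592 frames with a centered
    1244 x 231 cuvette window, blank intensities (255, 251, 253).
    """

    samples: list[SampleParams] = field(default_factory=_default_samples)
    blank_intensity: tuple[float, float, float] = (255.0, 251.0, 253.0)
    n_cuvettes: int = 3
    n_images: int = 10
    mode: str = "feature"
    image_height: int = 1944
    image_width: int = 2592
    roi: ROISpec | None = None
    texture_sd: float = 2.0
    blank_sd: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.samples:
            raise ConfigurationError("sample list is empty")
        tags = [s.tag for s in self.samples]
        if len(set(tags)) != len(tags):
            raise ConfigurationError("sample tags must be unique")
        self.blank_intensity = _triplet(self.blank_intensity, "blank_intensity")
        if any(v <= 0 for v in self.blank_intensity):
            raise ConfigurationError("blank intensities must be strictly positive")
        self.blank_sd = _triplet(self.blank_sd, "blank_sd", 0.0)
        if self.n_cuvettes < 1 or self.n_images < 1:
            raise ConfigurationError("n_cuvettes and n_images must be >= 1")
        if self.mode not in ("feature", "image"):
            raise ConfigurationError(f"mode must be 'feature' or 'image', got {self.mode!r}")
        if self.texture_sd < 0:
            raise ConfigurationError("texture_sd must be >= 0")
        if self.roi is None:
            self.roi = ROISpec.centered(self.image_height, self.image_width)
        self.roi.validate_within(self.image_height, self.image_width)

    @property
    def replicates_per_sample(self) -> int:
        return self.n_cuvettes * self.n_images

    @property
    def n_records(self) -> int:
        return len(self.samples) * self.replicates_per_sample


def _stream(seed: int, tag: str, replicate_index: int) -> np.random.Generator:
    """Independent RNG stream for one (sample, replicate) pair."""
    tag_key = zlib.crc32(tag.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag_key, int(replicate_index)]))


def generate_feature_dataset(config: GeneratorConfig) -> DatasetTable:
    """Draw replicate absorbance triplets for every sample (feature mode).

    Each replicate's channels are independent Gaussians
    ``N(absorbance_mean_c, absorbance_sd_c)`` truncated at 0 (the clamp is
    inert at the study's signal-to-noise levels); ``a_total`` is recomputed
    as the channel mean.  Output row order is samples in config order,
    cuvettes then images within each sample.
    """
    if config.mode != "feature":
        raise ConfigurationError("generate_feature_dataset requires mode='feature'")
    rows = []
    for sample in config.samples:
        mean = np.array(sample.absorbance_mean)
        sd = np.array(sample.absorbance_sd)
        for rep in range(config.replicates_per_sample):
            rng = _stream(config.seed, sample.tag, rep)
            a = np.maximum(rng.normal(mean, sd), 0.0)
            cuvette, image = divmod(rep, config.n_images)
            rows.append((sample.tag, sample.category, cuvette, image,
                         a[0], a[1], a[2], a.mean()))
    frame = pd.DataFrame(
        rows, columns=["tag", "category", "cuvette", "image", "a_r", "a_g", "a_b", "a_total"]
    )
    return DatasetTable(frame, provenance=f"synthetic feature mode, seed={config.seed}")


def _render_frame(config: GeneratorConfig, replicate_mean: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    roi = config.roi
    frame = np.full((config.image_height, config.image_width, 3), DARK_SURROUND, dtype=np.uint8)
    window_shape = (roi.height, roi.width, 3)
    if config.texture_sd > 0:
        window = rng.normal(replicate_mean, config.texture_sd, size=window_shape)
    else:
        window = np.broadcast_to(replicate_mean, window_shape).copy()
    window = np.clip(np.rint(window), 0, 255).astype(np.uint8)
    frame[roi.y0:roi.y0 + roi.height, roi.x0:roi.x0 + roi.width, :] = window
    return frame


def generate_image(sample: SampleParams, config: GeneratorConfig,
                   replicate_index: int) -> RGBImage:
    """Render one synthetic camera frame for a sample replicate (image mode).

    A per-replicate mean is drawn once from ``N(intensity_mean, intensity_sd)``
    (replicate scatter), then per-pixel texture noise of scale
    ``texture_sd`` is added inside the ROI; the surround is a dark constant.
    """
    if config.mode != "image":
        raise ConfigurationError("generate_image requires mode='image'")
    rng = _stream(config.seed, sample.tag, replicate_index)
    m_rep = np.clip(rng.normal(sample.intensity_mean, sample.intensity_sd), 0.0, 255.0)
    pixels = _render_frame(config, m_rep, rng)
    cuvette, image = divmod(replicate_index, config.n_images)
    return RGBImage(pixels=pixels, tag=sample.tag, cuvette=cuvette, image_index=image)


def generate_blank_image(config: GeneratorConfig, replicate_index: int = 0) -> RGBImage:
    """Render the blank (deionised water) frame; noiseless unless blank_sd is set."""
    rng = _stream(config.seed, "BLANK", replicate_index)
    m_rep = np.clip(rng.normal(config.blank_intensity, config.blank_sd), 0.0, 255.0)
    pixels = _render_frame(config, m_rep, rng)
    return RGBImage(pixels=pixels, tag="BLANK", cuvette=0, image_index=replicate_index)


def generate_image_set(config: GeneratorConfig, out_dir: str | Path) -> list[Path]:
    """Write the full synthetic image session as PNG files.

    File names follow ``{tag}_{cuvette}_{image}.png``; the blank frame is
    ``BLANK_0_0.png``.  Returns the written paths.
    """
    from .imaging import save_image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = [save_image(generate_blank_image(config), out_dir / "BLANK_0_0.png")]
    for sample in config.samples:
        for rep in range(config.replicates_per_sample):
            img = generate_image(sample, config, rep)
            paths.append(save_image(img, out_dir / f"{img.tag}_{img.cuvette}_{img.image_index}.png"))
    return paths
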