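"""Shared fixtures: small synthetic study configurations for fast tests."""

from __future__ import annotations

import numpy as np
import pytest

from eeye.reference import REFERENCE_BLANK
from eeye.synthetic import GeneratorConfig, SampleParams

# Three well-separated toy classes, three samples each.  Within-class sample
# means vary along different axes so the pooled within-class scatter is full
# rank even with zero replicate noise.
_TOY_MEANS = {
    "Silver": [(0.060, 0.060, 0.060), (0.065, 0.060, 0.060), (0.060, 0.065, 0.060)],
    "Aged": [(0.100, 0.080, 0.100), (0.100, 0.080, 0.105), (0.105, 0.080, 0.100)],
    "Extra-aged": [(0.090, 0.130, 0.180), (0.095, 0.130, 0.180), (0.090, 0.135, 0.185)],
}
_PREFIX = {"Silver": "S", "Aged": "A", "Extra-aged": "EA"}


def make_toy_samples(abs_sd: float = 0.0) -> list[SampleParams]:
    """Nine separable samples (3 per category) with optional replicate noise."""
    samples = []
    for category, means in _TOY_MEANS.items():
        for i, mean in enumerate(means, start=1):
            intensity = tuple(b * 10 ** (-a) for b, a in zip(REFERENCE_BLANK, mean))
            samples.append(SampleParams(
                tag=f"{_PREFIX[category]}{i}",
                category=category,
                intensity_mean=intensity,
                intensity_sd=(0.5, 0.5, 0.5),
                absorbance_mean=mean,
                absorbance_sd=(abs_sd, abs_sd, abs_sd),
            ))
    return samples


@pytest.fixture
def toy_samples() -> list[SampleParams]:
    return make_toy_samples()


@pytest.fixture
def separable_config() -> GeneratorConfig:
    """Zero replicate noise: every replicate equals its sample mean."""
    return GeneratorConfig(samples=make_toy_samples(abs_sd=0.0),
                           n_cuvettes=2, n_images=3, seed=7)


@pytest.fixture
def noisy_toy_config() -> GeneratorConfig:
    return GeneratorConfig(samples=make_toy_samples(abs_sd=0.002),
                           n_cuvettes=2, n_images=3, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
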