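"""Blank-referenced RGB absorbance and per-sample / per-class aggregation.

A transparent liquid in a cuvette attenuates the white backlight; comparing
the transmitted channel intensity of the analyte against that of a blank
(deionised water) cuvette gives an experimental, Beer-Lambert style
absorbance per colour channel:

    a_c = log10(I_blank,c / I_sample,c),   c in {R, G, B}

The triplet ``(a_r, a_g, a_b)`` is the colour fingerprint of one replicate
image; its arithmetic mean is reported as the total absorbance ``a_total``.
Absorbance rises with pigment load, so unaged (Silver) tequilas sit lowest
and oak-aged ones higher, with the blue channel the most discriminating for
amber tones.

All logarithms are base 10.  Intensities below an explicit floor (1.0 by
default) are clamped before the log so dark or dead pixels degrade
gracefully instead of producing infinities; a warning is emitted because a
clamp signals an exposure problem.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .categories import CATEGORY_ORDER, tag_sort_key
from .errors import DataError
from .imaging import ChannelSummary

__all__ = [
    "BlankReference",
    "AbsorbanceVector",
    "SampleRecord",
    "DatasetTable",
    "compute_absorbance",
    "aggregate_sample",
    "class_average",
    "fingerprint_export",
    "INTENSITY_FLOOR",
    "FEATURE_COLUMNS",
]

INTENSITY_FLOOR = 1.0
FEATURE_COLUMNS = ("a_r", "a_g", "a_b")
_TABLE_COLUMNS = ("tag", "category", "cuvette", "image", "a_r", "a_g", "a_b", "a_total")


@dataclass(frozen=True)
class BlankReference:
    """Channel intensities of the blank (solvent) cuvette, one per RGB channel."""

    intensity: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.intensity) != 3:
            raise DataError("blank reference needs exactly three channel intensities")
        if any(v <= 0 for v in self.intensity):
            raise DataError(f"blank intensities must be strictly positive, got {self.intensity}")


@dataclass(frozen=True)
class AbsorbanceVector:
    """Per-channel absorbances plus their mean (the total absorbance).

    ``a_total`` is always the arithmetic mean of the three channels; passing
    an inconsistent value raises.
    """

    a_r: float
    a_g: float
    a_b: float
    a_total: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        mean3 = (self.a_r + self.a_g + self.a_b) / 3.0
        if self.a_total is None:
            object.__setattr__(self, "a_total", mean3)
        elif abs(self.a_total - mean3) > 1e-12:
            raise DataError(
                f"a_total {self.a_total} is not the mean of the channel absorbances ({mean3})"
            )
        for v in (self.a_r, self.a_g, self.a_b, self.a_total):
            if not math.isfinite(v):
                raise DataError("absorbance components must be finite")

    @property
    def channels(self) -> tuple[float, float, float]:
        return (self.a_r, self.a_g, self.a_b)


@dataclass
class SampleRecord:
    """All replicate absorbance vectors measured for one sample."""

    tag: str
    category: str
    replicates: list[AbsorbanceVector]

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_ORDER:
            raise DataError(f"unknown category {self.category!r}")
        if not self.replicates:
            raise DataError(f"sample {self.tag} has no replicates")


@dataclass
class DatasetTable:
    """Labeled replicate absorbance table — the unit of chemometric modelling.

    ``frame`` has one row per replicate with columns
    ``tag, category, cuvette, image, a_r, a_g, a_b, a_total``.
    """

    frame: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in _TABLE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise DataError(f"dataset table missing columns {missing}")
        self.frame = self.frame.reset_index(drop=True)
        cats = self.frame.groupby("tag")["category"].nunique()
        if (cats > 1).any():
            bad = cats[cats > 1].index.tolist()
            raise DataError(f"tags with inconsistent category labels: {bad}")

    @property
    def tags(self) -> list[str]:
        """Sample tags in first-appearance order."""
        return list(dict.fromkeys(self.frame["tag"]))

    @property
    def categories_present(self) -> list[str]:
        present = set(self.frame["category"])
        return [c for c in CATEGORY_ORDER if c in present]

    def require_classifiable(self) -> None:
        """Every category must appear at least once for classification use."""
        missing = [c for c in CATEGORY_ORDER if c not in set(self.frame["category"])]
        if missing:
            raise DataError(f"dataset lacks categories {missing}; cannot classify")

    def sample_records(self) -> list[SampleRecord]:
        records = []
        for tag in self.tags:
            sub = self.frame[self.frame["tag"] == tag]
            reps = [AbsorbanceVector(r.a_r, r.a_g, r.a_b) for r in sub.itertuples()]
            records.append(SampleRecord(tag=tag, category=sub["category"].iloc[0], replicates=reps))
        return records

    @classmethod
    def from_records(cls, records: Iterable[SampleRecord], provenance: str = "") -> "DatasetTable":
        rows = []
        for rec in records:
            for i, vec in enumerate(rec.replicates):
                rows.append((rec.tag, rec.category, 0, i, vec.a_r, vec.a_g, vec.a_b, vec.a_total))
        return cls(pd.DataFrame(rows, columns=_TABLE_COLUMNS), provenance=provenance)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, index=False, lineterminator="\n")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "DatasetTable":
        path = Path(path)
        if not path.exists():
            raise DataError(f"feature table not found: {path}")
        frame = pd.read_csv(path)
        if "a_total" not in frame.columns and all(c in frame.columns for c in FEATURE_COLUMNS):
            frame["a_total"] = frame[list(FEATURE_COLUMNS)].mean(axis=1)
        return cls(frame, provenance=str(path))

    def content_hash(self) -> str:
        return hashlib.sha256(
            self.frame.to_csv(index=False, lineterminator="\n").encode()
        ).hexdigest()[:16]


def _channel_means(sample: ChannelSummary | Sequence[float]) -> tuple[float, float, float]:
    if isinstance(sample, ChannelSummary):
        return sample.means
    vals = tuple(float(v) for v in sample)
    if len(vals) != 3:
        raise DataError("expected three channel means")
    return vals


def compute_absorbance(
    sample_summary: ChannelSummary | Sequence[float],
    blank: BlankReference | Sequence[float],
    *,
    floor: float = INTENSITY_FLOOR,
) -> AbsorbanceVector:
    """Blank-referenced absorbance per channel: ``log10(blank_c / sample_c)``.

    Sample means below ``floor`` (default 1.0 intensity unit) are clamped to
    keep the result finite; a warning flags the saturated/dark condition.
    """
    if not isinstance(blank, BlankReference):
        blank = BlankReference(tuple(float(v) for v in blank))
    means = _channel_means(sample_summary)
    out = []
    for name, sample_c, blank_c in zip("RGB", means, blank.intensity):
        if sample_c < 0:
            raise DataError(f"negative channel mean on {name}: {sample_c}")
        if sample_c < floor:
            warnings.warn(
                f"channel {name} mean {sample_c:.3g} below floor {floor}; clamped "
                "(dark or saturated region)",
                stacklevel=2,
            )
            sample_c = floor
        out.append(math.log10(blank_c / sample_c))
    return AbsorbanceVector(*out)


@dataclass(frozen=True)
class AggregateStats:
    """Mean and sample standard deviation (ddof=1) of replicate absorbances."""

    mean: AbsorbanceVector
    sd_r: float
    sd_g: float
    sd_b: float
    sd_total: float
    n: int


def aggregate_sample(replicates: Sequence[AbsorbanceVector]) -> AggregateStats:
    """Per-channel and total mean +/- SD over the replicates of one sample."""
    if len(replicates) == 0:
        raise DataError("cannot aggregate an empty replicate list")
    arr = np.array([[v.a_r, v.a_g, v.a_b, v.a_total] for v in replicates], dtype=float)
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=1) if len(replicates) > 1 else np.zeros(4)
    return AggregateStats(
        mean=AbsorbanceVector(means[0], means[1], means[2]),
        sd_r=float(sds[0]), sd_g=float(sds[1]), sd_b=float(sds[2]), sd_total=float(sds[3]),
        n=len(replicates),
    )


def class_average(dataset: DatasetTable, category: str) -> tuple[float, float, int]:
    """Unweighted mean +/- SD of per-sample total absorbance within a category.

    Each sample contributes one value: the mean ``a_total`` over its
    replicates.  Returns ``(mean, sd_between_samples, n_samples)``; the SD is
    0 by convention for a single-sample category.
    """
    if category not in CATEGORY_ORDER:
        raise DataError(f"unknown category {category!r}")
    sub = dataset.frame[dataset.frame["category"] == category]
    if sub.empty:
        raise DataError(f"category {category!r} not present in dataset")
    per_sample = sub.groupby("tag", sort=False)["a_total"].mean()
    mean = float(per_sample.mean())
    sd = float(per_sample.std(ddof=1)) if len(per_sample) > 1 else 0.0
    return mean, sd, len(per_sample)


def fingerprint_export(dataset: DatasetTable) -> pd.DataFrame:
    """Per-sample mean channel absorbances grouped by category.

    This is the numeric content of the per-class radar fingerprints: one row
    per sample with its mean ``a_r, a_g, a_b, a_total``, ordered by category
    (Silver, Aged, Extra-aged) and tag number — stable across runs.
    """
    rows = []
    for rec in dataset.sample_records():
        agg = aggregate_sample(rec.replicates)
        rows.append((rec.category, rec.tag, agg.mean.a_r, agg.mean.a_g, agg.mean.a_b,
                     agg.mean.a_total, agg.n))
    out = pd.DataFrame(rows, columns=["category", "tag", "a_r", "a_g", "a_b", "a_total", "n_replicates"])
    out = out.sort_values("tag", key=lambda s: s.map(tag_sort_key), kind="stable")
    return out.reset_index(drop=True)


def summary_report(dataset: DatasetTable) -> pd.DataFrame:
    """Per-sample mean +/- SD table of channel and total absorbances."""
    rows = []
    for rec in dataset.sample_records():
        agg = aggregate_sample(rec.replicates)
        rows.append({
            "tag": rec.tag, "category": rec.category, "n": agg.n,
            "absmean_R": agg.mean.a_r, "abssd_R": agg.sd_r,
            "absmean_G": agg.mean.a_g, "abssd_G": agg.sd_g,
            "absmean_B": agg.mean.a_b, "abssd_B": agg.sd_b,
            "abs_total": agg.mean.a_total, "abssd_total": agg.sd_total,
        })
    out = pd.DataFrame(rows)
    out = out.sort_values("tag", key=lambda s: s.map(tag_sort_key), kind="stable")
    return out.reset_index(drop=True)
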