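"""End-to-end orchestration: simulate -> extract -> classify -> report.

The stages mirror the physical workflow: acquire cuvette images (here:
synthesise them), crop the cuvette window and reduce it to channel means,
convert to blank-referenced absorbances, then run the two-stage classifier
under sample-level leave-one-out validation and tabulate the metrics.
Every run is reproducible from ``(config, seed)``; outputs are plain CSV/
JSON files listed in a manifest with checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import absorbance as ab
from . import metrics as mx
from .categories import category_from_tag
from .chemometrics import CVResult, PipelineConfig, loocv_by_sample
from .errors import ConfigurationError, DataError
from .imaging import ROISpec, channel_summary, crop_roi, load_image
from .reference import REFERENCE_BLANK
from .synthetic import GeneratorConfig, generate_feature_dataset, generate_image_set

logger = logging.getLogger("eeye")

__all__ = [
    "RunConfig",
    "ClassificationReport",
    "simulate_features",
    "extract_directory",
    "classify_dataset",
    "write_manifest",
]


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    chemometrics: PipelineConfig = field(default_factory=PipelineConfig)
    out_dir: str = "eeye_out"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        gen = dataclasses.asdict(self.generator)
        gen["roi"] = dataclasses.asdict(self.generator.roi)
        gen["samples"] = [dataclasses.asdict(s) for s in self.generator.samples]
        return {
            "generator": gen,
            "chemometrics": self.chemometrics.to_dict(),
            "out_dir": self.out_dir,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        from .synthetic import SampleParams

        data = dict(data)
        gen = dict(data.get("generator", {}))
        if "roi" in gen and gen["roi"] is not None:
            gen["roi"] = ROISpec(**gen["roi"])
        if "samples" in gen:
            gen["samples"] = [
                SampleParams(**{k: tuple(v) if isinstance(v, list) else v for k, v in s.items()})
                for s in gen["samples"]
            ]
        for key in ("blank_intensity", "blank_sd"):
            if key in gen and isinstance(gen[key], list):
                gen[key] = tuple(gen[key])
        return cls(
            generator=GeneratorConfig(**gen),
            chemometrics=PipelineConfig.from_dict(data.get("chemometrics", {})),
            out_dir=data.get("out_dir", "eeye_out"),
            log_level=data.get("log_level", "INFO"),
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        try:
            data = yaml.safe_load(path.read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"invalid YAML in {path}: {exc}") from exc
        return cls.from_dict(data)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def simulate_features(config: GeneratorConfig, out_path: str | Path) -> Path:
    """Generate a feature-mode dataset and write it as CSV."""
    dataset = generate_feature_dataset(config)
    logger.info("simulated %d replicate rows for %d samples (seed %d)",
                len(dataset.frame), len(config.samples), config.seed)
    return dataset.to_csv(out_path)


def simulate_images(config: GeneratorConfig, out_dir: str | Path) -> list[Path]:
    """Render the full synthetic image session as PNGs (plus the blank)."""
    paths = generate_image_set(config, out_dir)
    logger.info("rendered %d frames (%d x %d, ROI %d x %d) to %s",
                len(paths), config.image_height, config.image_width,
                config.roi.width, config.roi.height, out_dir)
    return paths


def extract_directory(
    image_dir: str | Path,
    blank: ab.BlankReference | tuple[float, float, float] | str | Path | None,
    roi: ROISpec,
) -> pd.DataFrame:
    """Crop and summarise every PNG/JPEG in a directory, then compute absorbances.

    ``blank`` may be a channel triplet, a blank image path, or None to use a
    file named ``BLANK_*`` inside the directory.  File names of the form
    ``{tag}_{cuvette}_{image}`` provide the metadata columns.  Returns one
    row per image: channel means plus the absorbance vector.
    """
    image_dir = Path(image_dir)
    if not image_dir.is_dir():
        raise DataError(f"image directory not found: {image_dir}")
    files = sorted(
        p for p in image_dir.iterdir()
        if p.suffix.lower() in (".png", ".jpg", ".jpeg")
    )
    blank_files = [p for p in files if p.stem.upper().startswith("BLANK")]
    sample_files = [p for p in files if p not in blank_files]
    if not sample_files:
        raise DataError(f"no sample images found in {image_dir}")

    if blank is None:
        if not blank_files:
            raise DataError("no blank supplied and no BLANK_* image in the directory")
        triplets = []
        for path in blank_files:
            summary = channel_summary(crop_roi(load_image(path), roi))
            triplets.append(summary.means)
        blank_ref = ab.BlankReference(tuple(np.mean(triplets, axis=0)))
    elif isinstance(blank, (str, Path)):
        summary = channel_summary(crop_roi(load_image(blank), roi))
        blank_ref = ab.BlankReference(summary.means)
    elif isinstance(blank, ab.BlankReference):
        blank_ref = blank
    else:
        blank_ref = ab.BlankReference(tuple(float(v) for v in blank))
    logger.info("blank reference intensities: %s", blank_ref.intensity)

    rows = []
    formats = set()
    for path in sample_files:
        formats.add(path.suffix.lower())
        img = load_image(path)
        parts = path.stem.rsplit("_", 2)
        tag = parts[0]
        cuvette = int(parts[1]) if len(parts) == 3 and parts[1].isdigit() else 0
        image_idx = int(parts[2]) if len(parts) == 3 and parts[2].isdigit() else 0
        summary = channel_summary(crop_roi(img, roi))
        vec = ab.compute_absorbance(summary, blank_ref)
        try:
            category = category_from_tag(tag)
        except ValueError:
            category = "unknown"
        rows.append((tag, category, cuvette, image_idx,
                     summary.mean_r, summary.mean_g, summary.mean_b,
                     vec.a_r, vec.a_g, vec.a_b, vec.a_total))
    logger.info("extracted %d images (formats: %s)", len(rows), ", ".join(sorted(formats)))
    return pd.DataFrame(rows, columns=[
        "tag", "category", "cuvette", "image",
        "mean_R", "mean_G", "mean_B", "a_r", "a_g", "a_b", "a_total",
    ])


@dataclass
class ClassificationReport:
    """All evaluation artefacts of one LOOCV classification run."""

    cv: CVResult
    confusion: mx.ConfusionMatrix
    metrics: pd.DataFrame
    kappa: mx.KappaResult
    kappa_band: str
    fold_rates: pd.DataFrame
    mean_fold_kappa: float | None
    sample_summary: pd.DataFrame
    explained_variance_ratio: np.ndarray | None

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["cv"] = out_dir / "cv_predictions.csv"
        self.cv.frame.to_csv(paths["cv"], index=False, lineterminator="\n")
        paths["confusion"] = out_dir / "confusion_matrix.csv"
        self.confusion.to_frame().to_csv(paths["confusion"], lineterminator="\n")
        paths["metrics"] = out_dir / "class_metrics.csv"
        self.metrics.to_csv(paths["metrics"], lineterminator="\n")
        paths["samples"] = out_dir / "sample_summary.csv"
        self.sample_summary.to_csv(paths["samples"], index=False, lineterminator="\n")
        paths["kappa"] = out_dir / "kappa.json"
        payload = {
            "kappa": self.kappa.kappa,
            "observed_agreement": self.kappa.observed_agreement,
            "chance_agreement": self.kappa.chance_agreement,
            "band": self.kappa_band,
            "mean_fold_kappa": self.mean_fold_kappa,
        }
        if self.explained_variance_ratio is not None:
            payload["explained_variance_ratio"] = [float(v) for v in self.explained_variance_ratio]
        paths["kappa"].write_text(json.dumps(payload, indent=2))
        return paths


def classify_dataset(dataset: ab.DatasetTable,
                     config: PipelineConfig | None = None) -> ClassificationReport:
    """Run LOOCV classification and assemble every evaluation table."""
    config = config or PipelineConfig()
    cv = loocv_by_sample(dataset, config)
    cm = mx.confusion(cv)
    metrics = mx.class_metrics(cm)
    kappa = mx.cohens_kappa(cm)
    folds = mx.fold_kappas(cv)
    logger.info("LOOCV finished: %d folds, pooled kappa %.4f (%s)",
                cv.n_folds, kappa.kappa, mx.interpret_kappa(kappa.kappa))
    return ClassificationReport(
        cv=cv,
        confusion=cm,
        metrics=metrics,
        kappa=kappa,
        kappa_band=mx.interpret_kappa(kappa.kappa),
        fold_rates=mx.per_fold_rates(cv),
        mean_fold_kappa=float(np.mean(folds)) if folds else None,
        sample_summary=ab.summary_report(dataset),
        explained_variance_ratio=cv.explained_variance_ratio,
    )


def study_reproduction(seeds, chemo: PipelineConfig | None = None) -> dict[str, float]:
    """Simulate the full study once per seed and average the evaluation metrics.

    For each seed, a feature-mode dataset with the reference replicate
    structure (25 samples x 3 cuvettes x 10 images) is generated, classified
    under sample-level LOOCV, and scored.  Returns the across-seed means of
    the per-class classification rates (replicate-level recall, %), the
    macro rate, pooled-confusion Cohen's kappa, and macro sensitivity /
    specificity, plus the total number of predictions scored.
    """
    chemo = chemo or PipelineConfig()
    acc: dict[str, list[float]] = {k: [] for k in (
        "rate_silver", "rate_aged", "rate_extra_aged", "rate_overall",
        "kappa_pooled", "macro_sensitivity", "macro_specificity")}
    n_predictions = 0
    for seed in seeds:
        dataset = generate_feature_dataset(GeneratorConfig(seed=int(seed)))
        report = classify_dataset(dataset, chemo)
        m = report.metrics
        acc["rate_silver"].append(m.loc["Silver", "rate_pct"])
        acc["rate_aged"].append(m.loc["Aged", "rate_pct"])
        acc["rate_extra_aged"].append(m.loc["Extra-aged", "rate_pct"])
        acc["rate_overall"].append(m.loc["Average", "rate_pct"])
        acc["kappa_pooled"].append(report.kappa.kappa)
        acc["macro_sensitivity"].append(m.loc["Average", "sensitivity"])
        acc["macro_specificity"].append(m.loc["Average", "specificity"])
        n_predictions += len(report.cv.frame)
    out = {k: float(np.mean(v)) for k, v in acc.items()}
    out["n_predictions"] = n_predictions
    return out


def write_manifest(out_dir: str | Path, paths: dict[str, Path], config_hash: str) -> Path:
    """List every output file with a sha256 checksum (reproducibility record)."""
    out_dir = Path(out_dir)
    entries = {
        name: {
            "path": str(path),
            "sha256": hashlib.sha256(Path(path).read_bytes()).hexdigest(),
        }
        for name, path in paths.items()
    }
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps({"config_hash": config_hash, "outputs": entries}, indent=2))
    return manifest
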