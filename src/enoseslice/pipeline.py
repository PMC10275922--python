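"""End-to-end run orchestration.

A single validated configuration drives the whole study analogue: dataset
simulation, baseline correction, feature extraction over the configured
window/statistic grid, PCA score plots and variance table, the centroid
distance-vs-windows table, and the supervised model-comparison report.
All randomness flows from the one run seed; rerunning with the same
configuration reproduces every CSV bit-identically.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__, chemometrics, classification, preprocessing, windowing
from .synthetic import (
    CLASS_LABELS,
    NoiseSpec,
    default_profiles,
    generate_dataset,
    write_dataset,
    write_manifest,
)

logger = logging.getLogger(__name__)

_CLASS_COLORS = {"beef": "tab:red", "chicken": "tab:orange", "pork": "tab:blue"}


class NoiseConfig(BaseModel):
    baseline_offset_sd: float = Field(default=0.02, ge=0)
    additive_noise_sd: float = Field(default=0.02, ge=0)
    amplitude_cv: float = Field(default=0.06, ge=0)
    drift_slope_sd: float = Field(default=1e-4, ge=0)

    def to_spec(self) -> NoiseSpec:
        return NoiseSpec(**self.model_dump())


class ModelConfig(BaseModel):
    family: str
    k: int = Field(default=5, ge=1)
    mtry: int = Field(default=6, ge=1)
    n_trees: int = Field(default=500, ge=1)

    @field_validator("family")
    @classmethod
    def _family_known(cls, v):
        if v not in classification.MODEL_FAMILIES:
            raise ValueError(
                f"must be one of {classification.MODEL_FAMILIES}, got {v!r}"
            )
        return v

    def to_spec(self) -> classification.ModelSpec:
        return classification.ModelSpec(**self.model_dump())


class RunConfig(BaseModel):
    """Validated configuration of one full pipeline run."""

    seed: int = 0
    n_per_class: int = Field(default=100, ge=1)
    separation_margin: float = Field(default=0.5, gt=0)
    overlap_margin: float = Field(default=0.1, gt=0)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    window_counts: list[int] = Field(default_factory=lambda: list(range(7)))
    statistics: list[str] = Field(default_factory=lambda: list(windowing.STATISTICS))
    models: list[ModelConfig] = Field(
        default_factory=lambda: [
            ModelConfig(family=f) for f in classification.MODEL_FAMILIES
        ]
    )
    feature_mode: str = "slice_stats"
    train_fraction: float = Field(default=0.75, gt=0, lt=1)
    cv_folds: int = Field(default=10, ge=2)
    cv_repeats: int = Field(default=10, ge=1)
    output_dir: str = "run_output"

    @field_validator("window_counts")
    @classmethod
    def _windows_in_range(cls, v):
        if not v:
            raise ValueError("must be non-empty")
        for w in v:
            if not 0 <= w <= windowing.DEFAULT_MAX_WINDOWS:
                raise ValueError(
                    f"window count {w} outside 0..{windowing.DEFAULT_MAX_WINDOWS}"
                )
        return v

    @field_validator("statistics")
    @classmethod
    def _stats_known(cls, v):
        if not v:
            raise ValueError("must be non-empty")
        for s in v:
            if s not in windowing.STATISTICS:
                raise ValueError(
                    f"must be drawn from {windowing.STATISTICS}, got {s!r}"
                )
        return v

    @field_validator("feature_mode")
    @classmethod
    def _mode_known(cls, v):
        if v not in windowing.FEATURE_MODES:
            raise ValueError(f"must be one of {windowing.FEATURE_MODES}, got {v!r}")
        return v

    @field_validator("separation_margin")
    @classmethod
    def _sep_positive(cls, v):
        return v

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


def _setup_run_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("enoseslice")
    root.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) for h in root.handlers):
        root.addHandler(logging.StreamHandler(sys.stderr))
    root.setLevel(logging.INFO)
    return handler


def _score_plot(result: chemometrics.PCAResult, labels, path: Path, title: str):
    fig, ax = plt.subplots(figsize=(5, 4))
    ratios = result.explained_variance_ratio
    for label in CLASS_LABELS:
        mask = labels == label
        ax.scatter(
            result.scores[mask, 0], result.scores[mask, 1],
            s=12, label=label, color=_CLASS_COLORS[label], alpha=0.7,
        )
    ax.set_xlabel(f"PC1 ({ratios[0] * 100:.1f}%)")
    ax.set_ylabel(f"PC2 ({ratios[1] * 100:.1f}%)")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and write all artifacts to disk.

    Emits: dataset CSV + YAML manifest, one feature-matrix CSV per
    (window, statistic), PCA score plots and an explained-variance table,
    the centroid distance-vs-windows table, the classifier report CSV, a
    markdown summary, and a run log.  Returns the output directory.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(out)
    try:
        logger.info("enoseslice %s | seed=%d | numpy %s", __version__,
                    config.seed, np.__version__)

        noise = config.noise.to_spec()
        profiles = default_profiles(config.separation_margin, config.overlap_margin)
        dataset = generate_dataset(
            config.n_per_class, seed=config.seed, profiles=profiles, noise=noise
        )
        logger.info("simulated %d records (%d per class)", len(dataset),
                    config.n_per_class)
        write_dataset(dataset, out / "dataset.csv")
        write_manifest(
            out / "manifest.yaml",
            seed=config.seed,
            n_per_class=config.n_per_class,
            separation_margin=config.separation_margin,
            overlap_margin=config.overlap_margin,
            noise=noise,
        )

        corrected = preprocessing.baseline_correct_dataset(dataset)
        feat_dir = out / "features"
        plot_dir = out / "plots"
        feat_dir.mkdir(exist_ok=True)
        plot_dir.mkdir(exist_ok=True)

        variance_rows = []
        for w in config.window_counts:
            scheme = windowing.make_window_scheme(w)
            for stat in config.statistics:
                feats = windowing.extract_features(
                    corrected, scheme, stat, mode=config.feature_mode
                )
                feats.to_csv(feat_dir / f"features_W{w}_{stat}.csv")
                standardized, _ = chemometrics.standardize(feats)
                k = min(2, standardized.p, standardized.n_samples - 1)
                result = chemometrics.pca(standardized, k=k)
                if k >= 2:
                    _score_plot(
                        result, standardized.labels,
                        plot_dir / f"pca_W{w}_{stat}.png",
                        f"PCA scores, W{w}, {stat}",
                    )
                variance_rows.append(
                    {
                        "window_count": w,
                        "statistic": stat,
                        "p": feats.p,
                        **{
                            f"PC{i + 1}_ratio": float(r)
                            for i, r in enumerate(result.explained_variance_ratio)
                        },
                    }
                )
        pd.DataFrame(variance_rows).to_csv(out / "pca_variance.csv", index=False)

        windowed = [w for w in config.window_counts if w >= 1]
        distances = None
        if windowed:
            distances = chemometrics.distance_vs_windows(
                dataset, windowed, config.statistics, mode=config.feature_mode
            )
            distances.to_csv(out / "centroid_distances.csv", index=False)

        specs = tuple(m.to_spec() for m in config.models)
        report = classification.model_comparison(
            dataset,
            config.window_counts,
            config.statistics,
            model_specs=specs,
            seed=config.seed,
            train_fraction=config.train_fraction,
            folds=config.cv_folds,
            repeats=config.cv_repeats,
            mode=config.feature_mode,
        )
        report.to_csv(out / "classifier_report.csv", index=False)

        summary = [
            "# Run summary\n",
            f"- seed: {config.seed}",
            f"- records: {len(dataset)} ({config.n_per_class} per class)",
            f"- windows: {config.window_counts}",
            f"- statistics: {config.statistics}",
            f"- models: {[m.family for m in config.models]}\n",
            "## Accuracy (validation mean / testing, %)\n",
            classification.render_report_markdown(report),
        ]
        if distances is not None:
            best = distances[distances["pair"] == "pork-nonpork"]
            summary.append("## Pork vs non-pork centroid distance by window count\n")
            summary.append(
                best.groupby("window_count")["distance"].mean().to_string()
            )
            summary.append("")
        (out / "summary.md").write_text("\n".join(summary))
        logger.info("run complete: %s", out)
    finally:
        logging.getLogger("enoseslice").removeHandler(handler)
        handler.close()
    return out
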