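"""Single-command orchestration of the full study workflow.

``run_study`` executes, on simulated or user-supplied cohorts:

1. cohort acquisition (simulate feature tables, or load delimited files);
2. univariate AUC screen with permutation significance and 5% FDR;
3. correlation-based redundancy elimination on the training cohort, the
   retained feature set imposed on validation;
4. the ranking-method x selection-size x classifier benchmark grid;
5. grid summaries, and cutoff-based confusion metrics of the best cell;
6. a JSON manifest recording every stage output, parameter and seed.

All stage parameters default to the study settings (M = 0.8, sizes 5-45
step 5, 1000 permutations, 100 trees, k = 9).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .benchmark import DEFAULT_SIZES, run_benchmark, summarize_grid
from .classifiers import CLASSIFIER_KINDS, positive_scores, train_classifier
from .evaluation import confusion_metrics, optimal_cutoff, univariate_screen
from .io import read_feature_table, split_xy, write_feature_table
from .ranking import RANKING_METHODS, ReliefFConfig, rank_features, select_top
from .redundancy import eliminate_correlated, redundancy_summary
from .simulate import TableSimConfig, paper_like_table_config, simulate_feature_tables

__all__ = ["StudyConfig", "run_study"]

log = logging.getLogger("radhist")


@dataclass
class StudyConfig:
    """Fully materialized configuration of one study run."""

    train_path: str | None = None
    valid_path: str | None = None
    simulate: bool = True
    table_sim: TableSimConfig = field(default_factory=paper_like_table_config)
    corr_threshold: float = 0.8
    methods: tuple[str, ...] = RANKING_METHODS
    sizes: tuple[int, ...] = DEFAULT_SIZES
    classifiers: tuple[str, ...] = CLASSIFIER_KINDS
    n_permutations: int = 1000
    relieff_k: int = 10
    ranking_bins: int = 4
    seed: int = 0
    heatmaps: bool = False

    def validate(self) -> None:
        if not 0.0 < self.corr_threshold <= 1.0:
            raise ValueError("corr_threshold must lie in (0, 1]")
        unknown = set(self.methods) - set(RANKING_METHODS)
        if unknown:
            raise ValueError(f"unknown ranking methods: {sorted(unknown)}")
        unknown = set(self.classifiers) - set(CLASSIFIER_KINDS)
        if unknown:
            raise ValueError(f"unknown classifiers: {sorted(unknown)}")
        if not self.simulate and (self.train_path is None or self.valid_path is None):
            raise ValueError("either simulate=True or both cohort paths are required")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["methods"] = list(self.methods)
        d["sizes"] = list(self.sizes)
        d["classifiers"] = list(self.classifiers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "table_sim" in d and isinstance(d["table_sim"], dict):
            sim = dict(d["table_sim"])
            if sim.get("block_sizes") is not None:
                sim["block_sizes"] = tuple(sim["block_sizes"])
            d["table_sim"] = TableSimConfig(**sim)
        for key in ("methods", "sizes", "classifiers"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _save_heatmaps(grid, out_dir: Path) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for kind in grid.classifiers:
        mat = grid.matrix(kind)
        fig, ax = plt.subplots(figsize=(10, 7))
        im = ax.imshow(mat.to_numpy().T, aspect="auto", cmap="viridis")
        ax.set_yticks(range(len(mat.columns)), [str(s) for s in mat.columns])
        ax.set_xticks(range(len(mat.index)), list(mat.index), rotation=90)
        ax.set_ylabel("selection size")
        ax.set_title(f"validation AUC — {kind}")
        fig.colorbar(im, ax=ax, label="AUC")
        fig.tight_layout()
        name = f"heatmap_{kind}.png"
        fig.savefig(out_dir / name, dpi=120)
        plt.close(fig)
        written.append(name)
    return written


def run_study(config: StudyConfig, out_dir) -> dict:
    """Run the full workflow; returns the manifest (also written to disk)."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"package_version": __version__,
                      "config": config.to_dict(), "outputs": {}, "stages": []}

    def _stage(name):
        log.info("stage %s starting", name)
        manifest["stages"].append(name)

    try:
        _stage("cohorts")
        if config.simulate:
            sim = TableSimConfig(**{**asdict(config.table_sim), "seed": config.seed})
            train, valid = simulate_feature_tables(sim)
        else:
            train = read_feature_table(config.train_path)
            valid = read_feature_table(config.valid_path)
        write_feature_table(train, out_dir / "train.tsv")
        write_feature_table(valid, out_dir / "valid.tsv")
        manifest["outputs"]["train"] = "train.tsv"
        manifest["outputs"]["valid"] = "valid.tsv"
        train_X, train_y = split_xy(train)
        valid_X, valid_y = split_xy(valid)

        _stage("univariate_screen")
        screen = univariate_screen(train_X, train_y,
                                   n_permutations=config.n_permutations,
                                   seed=config.seed)
        screen.to_csv(out_dir / "univariate_screen.tsv", sep="\t")
        manifest["outputs"]["univariate_screen"] = "univariate_screen.tsv"
        manifest["n_significant_features"] = int(screen["significant"].sum())

        _stage("redundancy_filter")
        report = eliminate_correlated(train_X, config.corr_threshold)
        (out_dir / "correlation_report.json").write_text(
            json.dumps(report.to_dict(), indent=1))
        manifest["outputs"]["correlation_report"] = "correlation_report.json"
        manifest["n_features_before_filter"] = int(train_X.shape[1])
        manifest["n_features_after_filter"] = len(report.retained)
        manifest["redundancy_summary"] = redundancy_summary(
            train_X, train_X[report.retained])
        train_X = train_X[report.retained]
        valid_X = valid_X[report.retained]

        _stage("benchmark")
        grid = run_benchmark(train_X, train_y, valid_X, valid_y,
                             methods=config.methods, sizes=config.sizes,
                             classifiers=config.classifiers, seed=config.seed,
                             n_bins=config.ranking_bins,
                             relieff_k=config.relieff_k)
        grid.cells.to_csv(out_dir / "benchmark_grid.tsv", sep="\t", index=False)
        manifest["outputs"]["benchmark_grid"] = "benchmark_grid.tsv"
        manifest["n_grid_cells"] = grid.n_cells
        for kind in grid.classifiers:
            name = f"grid_matrix_{kind}.tsv"
            grid.matrix(kind).to_csv(out_dir / name, sep="\t")
            manifest["outputs"][f"grid_matrix_{kind}"] = name
        if config.heatmaps:
            for name in _save_heatmaps(grid, out_dir):
                manifest["outputs"][name] = name

        _stage("summary")
        summary = summarize_grid(grid)
        summary.table.to_csv(out_dir / "grid_summary.tsv", sep="\t")
        summary.per_size_medians.to_csv(out_dir / "grid_per_size_medians.tsv", sep="\t")
        manifest["outputs"]["grid_summary"] = "grid_summary.tsv"
        manifest["outputs"]["grid_per_size_medians"] = "grid_per_size_medians.tsv"

        _stage("best_model_cutoff")
        best = grid.cells.loc[grid.cells["auc"].idxmax()]
        ranking = rank_features(
            train_X, train_y, best["method"], n_bins=config.ranking_bins,
            relieff=ReliefFConfig(k=config.relieff_k, seed=config.seed),
            seed=config.seed)
        chosen = select_top(ranking, int(best["size"]))
        model = train_classifier(train_X[chosen], train_y, best["classifier"],
                                 seed=config.seed)
        cutoff = optimal_cutoff(positive_scores(model, train_X[chosen]), train_y)
        metrics = confusion_metrics(positive_scores(model, valid_X[chosen]),
                                    valid_y, cutoff)
        manifest["best_model"] = {
            "method": str(best["method"]), "size": int(best["size"]),
            "classifier": str(best["classifier"]),
            "validation_auc": float(best["auc"]),
            "selected_features": chosen,
            "cutoff_metrics": metrics.to_dict(),
        }
    except Exception:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        log.exception("study failed during stage %s",
                      manifest["stages"][-1] if manifest["stages"] else "init")
        raise

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("study complete: %d grid cells", manifest["n_grid_cells"])
    return manifest
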