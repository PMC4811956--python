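"""The feature-selection x selection-size x classifier benchmark grid.

For every ranking method the features are ranked on the training cohort
only; for every selection size the top features are kept; every classifier
is fit on the training cohort (standardization statistics come from the
training cohort alone) and scored on the validation cohort by AUC.  The
default grid is 24 methods x 9 sizes (5..45 step 5) x 3 classifiers = 648
cells.  Cells whose requested size exceeds the available feature count are
computed at the capped size and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifiers import CLASSIFIER_KINDS, positive_scores, train_classifier
from .evaluation import auc
from .ranking import RANKING_METHODS, ReliefFConfig, rank_features, select_top

__all__ = ["DEFAULT_SIZES", "BenchmarkGrid", "GridSummary", "run_benchmark",
           "summarize_grid"]

DEFAULT_SIZES = tuple(range(5, 50, 5))


@dataclass(frozen=True)
class BenchmarkGrid:
    """Long-format AUC grid plus the identifiers needed to reproduce it."""

    cells: pd.DataFrame  # columns: method, size, classifier, auc, size_used, capped
    methods: tuple[str, ...]
    sizes: tuple[int, ...]
    classifiers: tuple[str, ...]
    seed: int

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def matrix(self, classifier: str) -> pd.DataFrame:
        """methods x sizes AUC matrix for one classifier (heatmap layout)."""
        sub = self.cells[self.cells["classifier"] == classifier]
        return sub.pivot(index="method", columns="size", values="auc") \
                  .reindex(index=list(self.methods), columns=list(self.sizes))

    def validate_complete(self) -> None:
        expect = len(self.methods) * len(self.sizes) * len(self.classifiers)
        if len(self.cells) != expect or self.cells["auc"].isna().any():
            raise ValueError("benchmark grid is incomplete")


@dataclass(frozen=True)
class GridSummary:
    """Per-classifier medians and best/worst methods (by method maximum)."""

    table: pd.DataFrame
    per_size_medians: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.table


def _cell_seed(seed: int, mi: int, si: int, ci: int) -> int:
    return int(np.random.SeedSequence([seed, mi, si, ci]).generate_state(1)[0] % (2 ** 31))


def run_benchmark(train_X: pd.DataFrame, train_y, valid_X: pd.DataFrame, valid_y,
                  methods=RANKING_METHODS, sizes=DEFAULT_SIZES,
                  classifiers=CLASSIFIER_KINDS, seed: int = 0,
                  n_bins: int = 4, relieff_k: int = 10) -> BenchmarkGrid:
    """Fill the (method, size, classifier) AUC grid.

    ``train_X`` and ``valid_X`` must share the same feature columns (the
    redundancy-filtered training feature set, imposed on validation).
    """
    train_X = pd.DataFrame(train_X)
    valid_X = pd.DataFrame(valid_X)
    if list(train_X.columns) != list(valid_X.columns):
        raise ValueError("train and validation feature sets differ")
    methods = tuple(methods)
    sizes = tuple(int(s) for s in sizes)
    classifiers = tuple(classifiers)
    rows = []
    for mi, method in enumerate(methods):
        cfg = ReliefFConfig(k=relieff_k, seed=_cell_seed(seed, mi, 0, 0))
        ranking = rank_features(train_X, train_y, method, n_bins=n_bins,
                                relieff=cfg, seed=_cell_seed(seed, mi, 0, 0))
        for si, size in enumerate(sizes):
            capped = size > train_X.shape[1]
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                chosen = select_top(ranking, size)
            tx = train_X[chosen]
            vx = valid_X[chosen]
            for ci, kind in enumerate(classifiers):
                model = train_classifier(tx, train_y, kind,
                                         seed=_cell_seed(seed, mi, si, ci))
                rows.append({
                    "method": method, "size": size, "classifier": kind,
                    "auc": auc(positive_scores(model, vx), valid_y),
                    "size_used": len(chosen), "capped": capped,
                })
    grid = BenchmarkGrid(pd.DataFrame(rows), methods, sizes, classifiers, seed)
    grid.validate_complete()
    return grid


def summarize_grid(grid: BenchmarkGrid) -> GridSummary:
    """Per-classifier median +/- SD over all method x size cells, best/worst
    methods by their maximal cell, and the optimal selection size."""
    grid.validate_complete()
    rows = []
    for kind in grid.classifiers:
        sub = grid.cells[grid.cells["classifier"] == kind]
        med = float(sub["auc"].median())
        sd = float(sub["auc"].std(ddof=1))
        by_method = sub.groupby("method")["auc"].max()
        best_method = by_method.idxmax()
        worst_method = by_method.idxmin()
        best_cell = sub.loc[sub["auc"].idxmax()]
        if not (by_method.max() >= med and by_method.max() >= by_method.min()):
            raise AssertionError("summary ordering violated")
        rows.append({
            "classifier": kind, "median_auc": med, "sd_auc": sd,
            "optimal_n_features": int(best_cell["size"]),
            "best_method": best_method, "best_auc": float(by_method.max()),
            "worst_method": worst_method, "worst_auc": float(by_method.min()),
        })
    per_size = grid.cells.groupby(["classifier", "size"])["auc"].median() \
                         .unstack("size")
    return GridSummary(pd.DataFrame(rows).set_index("classifier"), per_size)
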