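"""Correlation-based feature elimination (stage-1, unsupervised).

Rule: compute the Pearson correlation matrix once and each feature's mean
absolute off-diagonal correlation ``C`` once; visit every pair with
``|c_ij| > M`` in descending ``|c_ij|`` (ties broken by the lexicographic
name pair) and, if both members are still alive, drop the one with the
larger ``C`` (ties: drop the lexicographically later name).  Because at
least one member of every offending pair is removed, no surviving pair can
exceed M — this is asserted on every run.  Zero-variance features (undefined
correlation) are removed up front.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["CorrelationReport", "CorrelationFilter", "eliminate_correlated",
           "redundancy_summary"]


@dataclass
class CorrelationReport:
    """Outcome of one elimination run at threshold M."""

    threshold: float
    removed: list[str]
    retained: list[str]
    removed_constant: list[str]
    mean_abs_corr_before: float
    mean_abs_corr_after: float
    iqr_abs_corr_before: float
    iqr_abs_corr_after: float

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "removed": list(self.removed),
            "retained": list(self.retained),
            "removed_constant": list(self.removed_constant),
            "mean_abs_corr_before": self.mean_abs_corr_before,
            "mean_abs_corr_after": self.mean_abs_corr_after,
            "iqr_abs_corr_before": self.iqr_abs_corr_before,
            "iqr_abs_corr_after": self.iqr_abs_corr_after,
        }


def _offdiag_abs(corr: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(corr.shape[0], k=1)
    return np.abs(corr[iu])


def _mean_iqr(vals: np.ndarray) -> tuple[float, float]:
    if vals.size == 0:
        return float("nan"), float("nan")
    q75, q25 = np.percentile(vals, [75, 25])
    return float(vals.mean()), float(q75 - q25)


def eliminate_correlated(X: pd.DataFrame, threshold: float = 0.8) -> CorrelationReport:
    """Apply the mean-absolute-correlation elimination rule to a feature frame.

    ``X`` holds feature columns only (no label).  Requires >= 2 features and
    >= 3 samples.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")

    variances = X.var(axis=0, ddof=0)
    constant = sorted(variances.index[variances == 0.0])
    Xv = X.drop(columns=constant)
    if Xv.shape[1] == 0:
        raise ValueError("all features are constant")
    names = list(Xv.columns)
    corr = np.corrcoef(Xv.to_numpy(dtype=float), rowvar=False)
    corr = np.atleast_2d(corr)
    abs_corr = np.abs(corr)
    np.fill_diagonal(abs_corr, 0.0)
    p = len(names)
    col_mean = abs_corr.sum(axis=0) / max(p - 1, 1)  # mean |r| excluding self

    before = _offdiag_abs(corr)
    iu, ju = np.triu_indices(p, k=1)
    offending = np.flatnonzero(abs_corr[iu, ju] > threshold)
    pairs = sorted(
        ((iu[k], ju[k]) for k in offending),
        key=lambda ij: (-abs_corr[ij[0], ij[1]],
                        min(names[ij[0]], names[ij[1]]),
                        max(names[ij[0]], names[ij[1]])),
    )
    alive = np.ones(p, dtype=bool)
    for i, j in pairs:
        if not (alive[i] and alive[j]):
            continue
        ci, cj = col_mean[i], col_mean[j]
        if ci > cj:
            drop = i
        elif cj > ci:
            drop = j
        else:
            drop = i if names[i] > names[j] else j
        alive[drop] = False

    retained = [names[k] for k in range(p) if alive[k]]
    removed = [names[k] for k in range(p) if not alive[k]]
    surv = np.flatnonzero(alive)
    after_mat = corr[np.ix_(surv, surv)]
    after = _offdiag_abs(after_mat)
    if after.size and after.max() > threshold + 1e-12:
        raise AssertionError(
            "internal error: a surviving pair exceeds the threshold"
        )
    mean_b, iqr_b = _mean_iqr(before)
    mean_a, iqr_a = _mean_iqr(after)
    return CorrelationReport(
        threshold=float(threshold),
        removed=removed,
        retained=retained,
        removed_constant=constant,
        mean_abs_corr_before=mean_b,
        mean_abs_corr_after=mean_a,
        iqr_abs_corr_before=iqr_b,
        iqr_abs_corr_after=iqr_a,
    )


def redundancy_summary(X_before: pd.DataFrame, X_after: pd.DataFrame) -> dict[str, float]:
    """Mean/IQR of off-diagonal |r| and high-correlation pair fractions."""
    out = {}
    for tag, X in (("before", X_before), ("after", X_after)):
        corr = np.atleast_2d(np.corrcoef(X.to_numpy(dtype=float), rowvar=False))
        vals = _offdiag_abs(corr)
        mean, iqr = _mean_iqr(vals)
        out[f"mean_abs_corr_{tag}"] = mean
        out[f"iqr_abs_corr_{tag}"] = iqr
        out[f"frac_above_0.8_{tag}"] = float(np.mean(vals > 0.8)) if vals.size else float("nan")
        out[f"frac_above_0.9_{tag}"] = float(np.mean(vals > 0.9)) if vals.size else float("nan")
    return out


class CorrelationFilter(SelectorMixin, BaseEstimator):
    """sklearn transformer applying the elimination rule learned on fit data.

    Parameters
    ----------
    threshold : float in (0, 1], default 0.8
        Maximal allowed absolute pairwise Pearson correlation.
    """

    def __init__(self, threshold: float = 0.8):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        X.columns = [str(c) for c in X.columns]
        self.report_ = eliminate_correlated(X, self.threshold)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        retained = set(self.report_.retained)
        self.support_ = np.array([c in retained for c in X.columns])
        self.retained_ = list(self.report_.retained)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]
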