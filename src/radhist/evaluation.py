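"""ROC/AUC evaluation: permutation significance, FDR screening, cutoffs.

AUC is the Mann-Whitney statistic divided by n+ * n- (ties counted 1/2),
equal to the probability that a random positive outscores a random negative.
Permutation p-values are one-sided with the add-one correction
p = (1 + #{AUC_perm >= AUC_obs}) / (n_iter + 1), which is strictly positive
and type-I valid.  Confidence intervals use the Hanley-McNeil normal
approximation by default, with DeLong available as an option.  The
univariate screen is orientation-free: it reports max(auc, 1 - auc) with a
direction flag and permutes the same oriented statistic, then applies
Benjamini-Hochberg at 5% FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .classifiers import encode_labels

__all__ = [
    "auc", "permutation_pvalue", "fdr_adjust", "roc_result", "ROCResult",
    "univariate_screen", "optimal_cutoff", "confusion_metrics",
    "ConfusionMetrics",
]


def auc(scores, labels) -> float:
    """Mann-Whitney AUC of ``scores`` against binary ``labels``."""
    s = np.asarray(scores, dtype=float)
    y = encode_labels(labels)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _auc_from_ranks(ranks: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized AUC for a (n, p) rank matrix against label matrix y (n, B)."""
    n_pos = y.sum(axis=0)
    n_neg = y.shape[0] - n_pos
    u = ranks.T @ y - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def permutation_pvalue(scores, labels, n_iter: int = 1000, seed: int = 0,
                       oriented: bool = False) -> float:
    """One-sided permutation p-value for AUC (add-one corrected).

    With ``oriented=True`` the statistic is max(auc, 1-auc), matching the
    orientation-free univariate screen.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    s = np.asarray(scores, dtype=float)
    y = encode_labels(labels)
    stat = auc(s, y)
    if oriented:
        stat = max(stat, 1.0 - stat)
    rng = np.random.default_rng(seed)
    ranks = rankdata(s)
    n_pos = int(y.sum())
    count = 0
    for _ in range(n_iter):
        perm = rng.permutation(y)
        u = ranks[perm == 1].sum() - n_pos * (n_pos + 1) / 2.0
        a = u / (n_pos * (len(y) - n_pos))
        if oriented:
            a = max(a, 1.0 - a)
        if a >= stat - 1e-12:
            count += 1
    return (1 + count) / (n_iter + 1)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    p_perm: float
    n_permutations: int


def _hanley_mcneil_se(a: float, n_pos: int, n_neg: int) -> float:
    q1 = a / (2.0 - a)
    q2 = 2.0 * a ** 2 / (1.0 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a ** 2)
           + (n_neg - 1) * (q2 - a ** 2)) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def _delong_se(scores: np.ndarray, y: np.ndarray) -> float:
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    # placement values via midranks
    v_pos = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v_neg = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = v_pos.var(ddof=1) if m > 1 else 0.0
    s01 = v_neg.var(ddof=1) if n > 1 else 0.0
    return float(np.sqrt(s10 / m + s01 / n))


def roc_result(scores, labels, n_iter: int = 1000, seed: int = 0,
               alpha: float = 0.05, ci_method: str = "hanley-mcneil") -> ROCResult:
    """AUC with confidence interval and permutation p-value."""
    s = np.asarray(scores, dtype=float)
    y = encode_labels(labels)
    a = auc(s, y)
    n_pos, n_neg = int(y.sum()), int((y == 0).sum())
    if ci_method == "hanley-mcneil":
        se = _hanley_mcneil_se(a, n_pos, n_neg)
    elif ci_method == "delong":
        se = _delong_se(s, y)
    else:
        raise ValueError("ci_method must be 'hanley-mcneil' or 'delong'")
    z = norm.ppf(1.0 - alpha / 2.0)
    lo = max(0.0, min(a, a - z * se))
    hi = min(1.0, max(a, a + z * se))
    p = permutation_pvalue(s, y, n_iter=n_iter, seed=seed)
    return ROCResult(auc=a, ci_low=lo, ci_high=hi, p_perm=p, n_permutations=n_iter)


def univariate_screen(X: pd.DataFrame, y, n_permutations: int = 1000,
                      seed: int = 0, fdr_level: float = 0.05) -> pd.DataFrame:
    """Per-feature oriented AUC, permutation p, BH q and 5%-FDR flags.

    Returns a frame indexed by feature with columns ``auc`` (oriented,
    >= 0.5), ``direction`` (+1 when the positive class takes higher values),
    ``p_perm``, ``q_fdr``, ``significant``.  One shared set of label
    permutations is used for every feature (features are screened against
    the same null relabelings), which keeps the screen O(n p + p B) instead
    of O(n p B).
    """
    X = pd.DataFrame(X)
    yv = encode_labels(y)
    n, p = X.shape
    ranks = np.apply_along_axis(rankdata, 0, X.to_numpy(dtype=float))
    obs = _auc_from_ranks(ranks, yv[:, None]).ravel()
    oriented = np.maximum(obs, 1.0 - obs)
    direction = np.where(obs >= 0.5, 1, -1)

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(yv) for _ in range(n_permutations)], axis=1)
    null = _auc_from_ranks(ranks, perms)  # (p, B)
    null = np.maximum(null, 1.0 - null)
    count = (null >= oriented[:, None] - 1e-12).sum(axis=1)
    p_perm = (1 + count) / (n_permutations + 1)
    q = fdr_adjust(p_perm)
    return pd.DataFrame({
        "auc": oriented, "direction": direction, "p_perm": p_perm,
        "q_fdr": q, "significant": q <= fdr_level,
    }, index=X.columns)


def optimal_cutoff(scores, labels) -> float:
    """Cutoff maximizing Youden's J = sens + spec - 1 on the training ROC.

    Predictions are positive when score >= cutoff; ties in J resolve to the
    lowest cutoff.
    """
    s = np.asarray(scores, dtype=float)
    y = encode_labels(labels)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("optimal_cutoff requires both classes")
    best_c, best_j = None, -np.inf
    for c in np.unique(s):
        pred = s >= c
        sens = np.mean(pred[y == 1])
        spec = np.mean(~pred[y == 0])
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return float(best_c)


@dataclass(frozen=True)
class ConfusionMetrics:
    cutoff: float
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    defined: bool = True

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff, "tp": self.tp, "fp": self.fp,
            "fn": self.fn, "tn": self.tn, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "ppv": self.ppv, "npv": self.npv,
            "accuracy": self.accuracy, "defined": self.defined,
        }


def confusion_metrics(scores, labels, cutoff: float) -> ConfusionMetrics:
    """Validation confusion metrics at a fixed cutoff (score >= cutoff -> +).

    A single-class validation set yields NaN for the undefined rates and
    ``defined=False``.
    """
    s = np.asarray(scores, dtype=float)
    y = encode_labels(labels)
    pred = s >= cutoff
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))

    def _ratio(num, den):
        return num / den if den > 0 else float("nan")

    both = (tp + fn > 0) and (fp + tn > 0)
    return ConfusionMetrics(
        cutoff=float(cutoff), tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=_ratio(tp, tp + fn), specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp), npv=_ratio(tn, tn + fn),
        accuracy=(tp + tn) / len(y), defined=both,
    )
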