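"""Filter-based feature ranking: impurity scores, distribution-distance
scores, and the Relief family.

Twenty-four scorers are registered.  They fall into three groups:

* **Impurity gains on a class x attribute-value contingency table** built
  from equal-frequency discretized feature values (default 4 bins):
  InfGain, GainRatio, Gini, MDL, DKM, Accuracy, and the equal-column-weight
  variants EqualInf, EqualGini, EqualDKM, plus MDLsmp (MDL on a stratified
  half-subsample).  All logarithms are base 2; higher scores are better; a
  degenerate table (single class or single attribute value) scores 0.

* **Distribution-distance gains**: ImpurityHellinger / EqualHellinger and
  ImpurityEuclid score how far the class distribution inside each
  value-column moves away from the uniform distribution, relative to the
  prior: score = sum_j w_j * P(p(.|j)) - P(p(.)), with column weights
  w_j = p(a_j) for "Impurity" variants and w_j = 1/|a| for "Equal" variants,
  P_hell(p) = 1 - sum_i sqrt(p_i / c) (one minus the Bhattacharyya affinity
  to uniform) and P_euclid(p) = sqrt(sum_i (p_i - 1/c)^2).  This grows with
  class purity, matching the sign convention of the Gini purity gain.

* **Relief family** on raw (min-max normalized) values: for each reference
  instance the k nearest same-class hits and, per other class, k nearest
  misses are found under the normalized Manhattan distance; the weight of
  attribute A decreases with hit differences and increases with miss
  differences, misses weighted by p(class)/(1 - p(class(R))).  Variants
  change the neighbor-contribution weights (equalK / expRank / bestK /
  distance / sqrDistance / merit), the class weighting (avgC / expC), the
  miss pooling (pe), the reference sampling (smp), or reduce to classic
  Relief (k=1, two classes, no class weighting).  Note that for *binary*
  labels the prior miss weight p(t)/(1-p(class(R))) is identically 1, so
  equalK, avgC, expC and pe coincide on two-class data (they differ for
  three or more classes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import gammaln
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "RANKING_METHODS", "Ranking", "ReliefFConfig", "discretize",
    "contingency_table", "impurity_score", "hellinger_impurity_score",
    "relieff_weights", "rank_features", "select_top", "RankingSelector",
]

IMPURITY_METHODS = ("InfGain", "GainRatio", "Gini", "MDL", "DKM", "Accuracy")
EQUAL_METHODS = ("EqualInf", "EqualGini", "EqualDKM")
DISTRIBUTION_METHODS = ("EqualHellinger", "ImpurityHellinger", "ImpurityEuclid")
RELIEF_METHODS = (
    "Relief", "ReliefFequalK", "ReliefFexpRank", "ReliefFbestK",
    "ReliefFdistance", "ReliefFsqrDistance", "ReliefFmerit",
    "ReliefFavgC", "ReliefFexpC", "ReliefFpe", "ReliefFsmp",
)
RANKING_METHODS = IMPURITY_METHODS + EQUAL_METHODS + DISTRIBUTION_METHODS + \
    RELIEF_METHODS + ("MDLsmp",)

_EPS = 1e-12


@dataclass(frozen=True)
class ReliefFConfig:
    """Relief-family knobs: neighbor count k, reference count m (None = all
    instances in order), rank-weight scale sigma for expRank."""

    k: int = 10
    m: int | None = None
    sigma: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.m is not None and self.m < 1:
            raise ValueError("m must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class Ranking:
    """Ordered (feature, score) pairs for one method, scores non-increasing."""

    method: str
    entries: tuple[tuple[str, float], ...]

    @property
    def features(self) -> list[str]:
        return [name for name, _ in self.entries]

    @property
    def scores(self) -> dict[str, float]:
        return dict(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rank": np.arange(1, len(self.entries) + 1),
             "feature": [n for n, _ in self.entries],
             "score": [s for _, s in self.entries],
             "method": self.method})


# ---------------------------------------------------------------------------
# discretization and contingency tables
# ---------------------------------------------------------------------------

def discretize(values, n_bins: int = 4) -> np.ndarray:
    """Equal-frequency binning into integer labels 0..n_bins-1.

    Bin edges are the i/n_bins sample quantiles; duplicate edges collapse,
    so fewer distinct values give fewer bins.  Deterministic.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot discretize an empty sequence")
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.searchsorted(edges, x, side="left").astype(np.int64)


def contingency_table(attr_values, labels) -> np.ndarray:
    """Class x attribute-value count matrix n_ij (classes in sorted order)."""
    a = np.asarray(attr_values)
    y = np.asarray(labels)
    classes, yi = np.unique(y, return_inverse=True)
    vals, ai = np.unique(a, return_inverse=True)
    t = np.zeros((len(classes), len(vals)), dtype=np.int64)
    np.add.at(t, (yi, ai), 1)
    return t


# ---------------------------------------------------------------------------
# impurity scores
# ---------------------------------------------------------------------------

def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def _log2_multinom(n: int, parts: np.ndarray) -> float:
    return float((gammaln(n + 1) - gammaln(parts + 1).sum()) / np.log(2.0))


def _log2_binom(n: int, k: int) -> float:
    return float((gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)) / np.log(2.0))


def _dkm_term(p_max: float) -> float:
    return 2.0 * np.sqrt(max(p_max * (1.0 - p_max), 0.0))


def _hell_purity(p: np.ndarray) -> float:
    c = len(p)
    return float(1.0 - np.sum(np.sqrt(p / c)))


def _euclid_purity(p: np.ndarray) -> float:
    c = len(p)
    return float(np.sqrt(np.sum((p - 1.0 / c) ** 2)))


def _table_probs(t: np.ndarray):
    t = np.asarray(t, dtype=float)
    n = t.sum()
    p_class = t.sum(axis=1) / n
    col_n = t.sum(axis=0)
    keep = col_n > 0
    t = t[:, keep]
    col_n = col_n[keep]
    p_col = col_n / n
    p_cond = t / col_n  # p(class | value)
    return n, p_class, p_col, p_cond, t


def impurity_score(method: str, table) -> float:
    """Score a contingency table with one of the impurity-gain criteria.

    ``table`` is the class x value count matrix.  Degenerate tables (one
    class, or a single value column for the gain criteria) score 0.
    """
    t = np.asarray(table, dtype=float)
    if t.sum() < 2:
        raise ValueError("contingency table needs n >= 2")
    n, p_class, p_col, p_cond, t = _table_probs(t)
    if (p_class > 0).sum() < 2:
        return 0.0

    if method == "InfGain" or method == "GainRatio":
        prior = _entropy(p_class)
        post = sum(p_col[j] * _entropy(p_cond[:, j]) for j in range(t.shape[1]))
        gain = prior - post
        if method == "InfGain":
            return float(gain)
        split_info = _entropy(p_col)
        return float(gain / split_info) if split_info > 0 else 0.0
    if method == "Gini":
        prior = float(np.sum(p_class ** 2))
        post = float(np.sum(p_col * np.sum(p_cond ** 2, axis=0)))
        return post - prior
    if method == "DKM":
        imax = int(np.argmax(p_class))
        prior = _dkm_term(p_class[imax])
        post = float(np.sum(p_col * np.array(
            [_dkm_term(p_cond[imax, j]) for j in range(t.shape[1])])))
        return prior - post
    if method == "Accuracy":
        joint = t / n
        return float(joint.max(axis=0).sum() - p_class.max())
    if method == "MDL":
        c = t.shape[0]
        n_i = t.sum(axis=1)
        prior = _log2_multinom(int(n), n_i) + _log2_binom(int(n) + c - 1, c - 1)
        post = sum(
            _log2_multinom(int(t[:, j].sum()), t[:, j]) +
            _log2_binom(int(t[:, j].sum()) + c - 1, c - 1)
            for j in range(t.shape[1])
        )
        return float((prior - post) / n)
    if method in EQUAL_METHODS:
        j_count = t.shape[1]
        w = np.full(j_count, 1.0 / j_count)
        if method == "EqualInf":
            prior = _entropy(p_class)
            post = sum(w[j] * _entropy(p_cond[:, j]) for j in range(j_count))
            return float(prior - post)
        if method == "EqualGini":
            prior = 1.0 - float(np.sum(p_class ** 2))
            post = float(np.sum(w * (1.0 - np.sum(p_cond ** 2, axis=0))))
            return float(prior - post)
        imax = int(np.argmax(p_class))
        prior = _dkm_term(p_class[imax])
        post = float(np.sum(w * np.array(
            [_dkm_term(p_cond[imax, j]) for j in range(j_count)])))
        return float(prior - post)
    raise ValueError(f"unknown impurity method {method!r}")


def hellinger_impurity_score(variant: str, table) -> float:
    """Distribution-distance gains (Hellinger/Euclid against uniform).

    ``Impurity*`` variants weight value-columns by p(a_j); ``Equal*``
    variants weight them equally.  EqualGini/EqualInf/EqualDKM are routed to
    the corresponding equal-weight impurity gains.
    """
    if variant in EQUAL_METHODS:
        return impurity_score(variant, table)
    t = np.asarray(table, dtype=float)
    if t.sum() < 2:
        raise ValueError("contingency table needs n >= 2")
    n, p_class, p_col, p_cond, t = _table_probs(t)
    if (p_class > 0).sum() < 2:
        return 0.0
    j_count = t.shape[1]
    if variant in ("ImpurityHellinger", "EqualHellinger"):
        purity = _hell_purity
    elif variant == "ImpurityEuclid":
        purity = _euclid_purity
    else:
        raise ValueError(f"unknown distribution variant {variant!r}")
    w = p_col if variant.startswith("Impurity") else np.full(j_count, 1.0 / j_count)
    post = float(np.sum(w * np.array([purity(p_cond[:, j]) for j in range(j_count)])))
    return post - purity(p_class)


# ---------------------------------------------------------------------------
# Relief family
# ---------------------------------------------------------------------------

def _neighbor_order(dist_row: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """Candidates sorted by (distance, index) — stable deterministic ties."""
    d = dist_row[candidates]
    return candidates[np.lexsort((candidates, d))]


def _contribution(variant: str, diffs: np.ndarray, dists: np.ndarray,
                  sigma: float) -> np.ndarray:
    """Per-attribute contribution of a sorted neighbor list.

    ``diffs`` is (k, p) attribute differences, ``dists`` the (k,) distances.
    """
    k = len(dists)
    if variant in ("equalK", "classic"):
        return diffs.mean(axis=0)
    if variant == "expRank":
        ranks = np.arange(1, k + 1, dtype=float)
        w = np.exp(-((ranks / sigma) ** 2))
        return (w / w.sum()) @ diffs
    if variant == "bestK":
        cummean = np.cumsum(diffs, axis=0) / np.arange(1, k + 1)[:, None]
        return cummean.max(axis=0)
    if variant == "distance":
        w = 1.0 / (dists + _EPS)
        return (w / w.sum()) @ diffs
    if variant == "sqrDistance":
        w = 1.0 / (dists ** 2 + _EPS)
        return (w / w.sum()) @ diffs
    if variant == "merit":
        return (diffs / np.maximum(dists, _EPS)[:, None]).mean(axis=0)
    raise ValueError(f"unknown contribution variant {variant!r}")


_RELIEF_CONTRIB = {
    "Relief": "classic", "ReliefFequalK": "equalK", "ReliefFexpRank": "expRank",
    "ReliefFbestK": "bestK", "ReliefFdistance": "distance",
    "ReliefFsqrDistance": "sqrDistance", "ReliefFmerit": "merit",
    "ReliefFavgC": "equalK", "ReliefFexpC": "equalK", "ReliefFpe": "equalK",
    "ReliefFsmp": "equalK",
}


def relieff_weights(features, labels, variant: str = "ReliefFequalK",
                    config: ReliefFConfig | None = None) -> np.ndarray:
    """Relief-family attribute weights.

    Features are min-max normalized internally so per-attribute differences
    lie in [0, 1]; instance distance is the sum of normalized differences
    (normalized Manhattan).  A class with fewer than k other members
    contributes all its available members.
    """
    if variant not in _RELIEF_CONTRIB:
        raise ValueError(f"unknown Relief variant {variant!r}")
    config = config or ReliefFConfig()
    config.validate()
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2D array")
    y = np.asarray(labels)
    n, p = X.shape
    classes, y_idx = np.unique(y, return_inverse=True)
    counts = np.bincount(y_idx)
    if (counts < 2).any():
        raise ValueError("each class needs at least 2 samples")
    priors = counts / n

    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0  # constant features: diff is 0 regardless
    Xn = (X - X.min(axis=0)) / span
    D = cdist(Xn, Xn, metric="cityblock")

    k = 1 if variant == "Relief" else config.k
    if variant == "Relief" and len(classes) != 2:
        raise ValueError("classic Relief is defined for two classes only")
    contrib = _RELIEF_CONTRIB[variant]

    if variant == "ReliefFsmp":
        rng = np.random.default_rng(config.seed)
        m = config.m or n
        refs = rng.integers(0, n, size=m)
    else:
        refs = np.arange(n) if config.m is None else np.arange(min(config.m, n))
    m = len(refs)

    by_class = [np.flatnonzero(y_idx == c) for c in range(len(classes))]
    W = np.zeros(p)
    for i in refs:
        ci = y_idx[i]
        hits_pool = by_class[ci][by_class[ci] != i]
        hits = _neighbor_order(D[i], hits_pool)[:min(k, len(hits_pool))]
        hit_con = _contribution(contrib, np.abs(Xn[hits] - Xn[i]), D[i][hits],
                                config.sigma)
        if variant == "ReliefFpe":
            # pooled misses: k nearest other-class instances, each weighted
            # by its own class prior ratio
            pool = np.flatnonzero(y_idx != ci)
            near = _neighbor_order(D[i], pool)[:min(k, len(pool))]
            ratio = priors[y_idx[near]] / (1.0 - priors[ci])
            diffs = np.abs(Xn[near] - Xn[i])
            miss_con = (ratio[:, None] * diffs).sum(axis=0) / len(near)
        else:
            miss_con = np.zeros(p)
            others = [c for c in range(len(classes)) if c != ci]
            if variant == "Relief":
                cw = {others[0]: 1.0}
            elif variant == "ReliefFavgC":
                cw = {c: 1.0 / len(others) for c in others}
            elif variant == "ReliefFexpC":
                e = np.array([np.exp(priors[c]) for c in others])
                e = e / e.sum()
                cw = dict(zip(others, e))
            else:
                cw = {c: priors[c] / (1.0 - priors[ci]) for c in others}
            for c in others:
                near = _neighbor_order(D[i], by_class[c])[:min(k, len(by_class[c]))]
                con = _contribution(contrib, np.abs(Xn[near] - Xn[i]),
                                    D[i][near], config.sigma)
                miss_con += cw[c] * con
        W += (miss_con - hit_con) / m
    return W


# ---------------------------------------------------------------------------
# ranking front end
# ---------------------------------------------------------------------------

def _stratified_half(y_idx: np.ndarray, seed: int) -> np.ndarray:
    """Deterministic stratified half-subsample (>= 2 per class)."""
    rng = np.random.default_rng(seed)
    keep = []
    for c in np.unique(y_idx):
        members = np.flatnonzero(y_idx == c)
        size = max(2, len(members) // 2)
        keep.append(rng.choice(members, size=min(size, len(members)), replace=False))
    return np.sort(np.concatenate(keep))


def rank_features(X: pd.DataFrame, y, method: str, *, n_bins: int = 4,
                  relieff: ReliefFConfig | None = None, seed: int = 0) -> Ranking:
    """Score every feature with ``method`` and return the complete ranking.

    Impurity-family scorers run on equal-frequency discretized values;
    Relief-family scorers on the raw values.  Ties are broken by feature
    name, so rankings are deterministic.
    """
    if method not in RANKING_METHODS:
        raise ValueError(f"unknown ranking method {method!r}; "
                         f"registry: {', '.join(RANKING_METHODS)}")
    X = pd.DataFrame(X)
    y = np.asarray(y)
    names = [str(c) for c in X.columns]
    if method in RELIEF_METHODS:
        cfg = relieff or ReliefFConfig(seed=seed)
        weights = relieff_weights(X.to_numpy(dtype=float), y, method, cfg)
        scores = dict(zip(names, weights))
    else:
        classes, y_idx = np.unique(y, return_inverse=True)
        sub = _stratified_half(y_idx, seed) if method == "MDLsmp" else None
        base = "MDL" if method == "MDLsmp" else method
        scores = {}
        for name in names:
            vals = discretize(X[name].to_numpy(dtype=float), n_bins)
            if sub is not None:
                t = contingency_table(vals[sub], y_idx[sub])
            else:
                t = contingency_table(vals, y_idx)
            if base in IMPURITY_METHODS:
                scores[name] = impurity_score(base, t)
            else:
                scores[name] = hellinger_impurity_score(base, t)
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return Ranking(method=method, entries=tuple((n, float(s)) for n, s in ordered))


def select_top(ranking: Ranking, size: int) -> list[str]:
    """First ``size`` feature names; capped (with a warning) if too large."""
    if size < 1:
        raise ValueError("size must be >= 1")
    if size > len(ranking.entries):
        import warnings

        warnings.warn(
            f"requested {size} features but only {len(ranking.entries)} are "
            "ranked; returning all", stacklevel=2)
        size = len(ranking.entries)
    return ranking.features[:size]


class RankingSelector(SelectorMixin, BaseEstimator):
    """sklearn selector keeping the ``n_features`` top-ranked features.

    Parameters mirror :func:`rank_features`; fitting stores the full
    ``ranking_`` for inspection.
    """

    def __init__(self, method: str = "ReliefFdistance", n_features: int = 5,
                 n_bins: int = 4, k: int = 10, sigma: float = 20.0,
                 seed: int = 0):
        self.method = method
        self.n_features = n_features
        self.n_bins = n_bins
        self.k = k
        self.sigma = sigma
        self.seed = seed

    def fit(self, X, y):
        X = pd.DataFrame(X)
        X.columns = [str(c) for c in X.columns]
        cfg = ReliefFConfig(k=self.k, sigma=self.sigma, seed=self.seed)
        self.ranking_ = rank_features(X, y, self.method, n_bins=self.n_bins,
                                      relieff=cfg, seed=self.seed)
        chosen = set(select_top(self.ranking_, self.n_features))
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.support_ = np.array([c in chosen for c in X.columns])
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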