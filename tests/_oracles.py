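"""Independent brute-force oracles used by the test suite.

Everything here is written as plain loops over definitions (pair
enumeration, run walking, neighbor scans), deliberately sharing no code
with the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# discretization (equal-width min-max, same contract as the package)
# ---------------------------------------------------------------------------

def discretize_minmax(volume, mask, n_bins):
    vol = np.asarray(volume, dtype=float)
    mask = np.asarray(mask).astype(bool)
    vals = vol[mask]
    lo, hi = vals.min(), vals.max()
    levels = np.full(vol.shape, -1, dtype=int)
    for idx in np.ndindex(vol.shape):
        if not mask[idx]:
            continue
        if hi == lo:
            levels[idx] = 0
        else:
            b = int((vol[idx] - lo) / (hi - lo) * n_bins)
            levels[idx] = min(b, n_bins - 1)
    return levels


# ---------------------------------------------------------------------------
# GLCM by exhaustive pair enumeration
# ---------------------------------------------------------------------------

def glcm_matrix_bruteforce(volume, mask, n_bins, distance, direction):
    levels = discretize_minmax(volume, mask, n_bins)
    shape = levels.shape
    counts = np.zeros((n_bins, n_bins))
    off = tuple(distance * c for c in direction)
    for idx in np.ndindex(shape):
        if levels[idx] < 0:
            continue
        nb = tuple(i + o for i, o in zip(idx, off))
        if all(0 <= nb[a] < shape[a] for a in range(3)) and levels[nb] >= 0:
            counts[levels[idx], levels[nb]] += 1
            counts[levels[nb], levels[idx]] += 1  # symmetric
    return counts / counts.sum() if counts.sum() else counts


def glcm_features_bruteforce(p):
    ng = p.shape[0]
    feats = {}

    def log2(v):
        return math.log2(v) if v > 0 else 0.0

    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    sd_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng)))
    sd_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng)))
    p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    p_diff = {k: 0.0 for k in range(ng)}
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] += p[i][j]
            p_diff[abs(i - j)] += p[i][j]

    feats["autocorrelation"] = sum((i + 1) * (j + 1) * p[i][j]
                                   for i in range(ng) for j in range(ng))
    for name, power in (("cluster_tendency", 2), ("cluster_shade", 3),
                        ("cluster_prominence", 4)):
        feats[name] = sum((i + 1 + j + 1 - mu_x - mu_y) ** power * p[i][j]
                          for i in range(ng) for j in range(ng))
    feats["contrast"] = sum((i - j) ** 2 * p[i][j]
                            for i in range(ng) for j in range(ng))
    if sd_x > 0 and sd_y > 0:
        feats["correlation1"] = (feats["autocorrelation"] - mu_x * mu_y) / (sd_x * sd_y)
    else:
        feats["correlation1"] = 0.0
    feats["difference_entropy"] = -sum(log2(v) * v for v in p_diff.values())
    feats["dissimilarity"] = sum(abs(i - j) * p[i][j]
                                 for i in range(ng) for j in range(ng))
    feats["energy"] = sum(p[i][j] ** 2 for i in range(ng) for j in range(ng))
    hxy = -sum(log2(p[i][j]) * p[i][j] for i in range(ng) for j in range(ng))
    feats["entropy"] = hxy
    feats["homogeneity1"] = sum(p[i][j] / (1 + abs(i - j))
                                for i in range(ng) for j in range(ng))
    feats["homogeneity2"] = sum(p[i][j] / (1 + (i - j) ** 2)
                                for i in range(ng) for j in range(ng))
    hx = -sum(log2(v) * v for v in px)
    hy = -sum(log2(v) * v for v in py)
    hxy1 = -sum(p[i][j] * log2(px[i] * py[j])
                for i in range(ng) for j in range(ng) if p[i][j] > 0)
    hxy2 = -sum(log2(px[i] * py[j]) * px[i] * py[j]
                for i in range(ng) for j in range(ng))
    feats["imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    feats["imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    feats["idmn"] = sum(p[i][j] / (1 + ((i - j) / ng) ** 2)
                        for i in range(ng) for j in range(ng))
    feats["idn"] = sum(p[i][j] / (1 + abs(i - j) / ng)
                       for i in range(ng) for j in range(ng))
    feats["inverse_variance"] = sum(p[i][j] / (i - j) ** 2
                                    for i in range(ng) for j in range(ng) if i != j)
    feats["max_probability"] = max(p[i][j] for i in range(ng) for j in range(ng))
    sa = sum(k * v for k, v in p_sum.items())
    feats["sum_average"] = sa
    feats["sum_entropy"] = -sum(log2(v) * v for v in p_sum.values())
    feats["sum_variance"] = sum((k - sa) ** 2 * v for k, v in p_sum.items())
    feats["variance"] = sum((i + 1 - mu_x) ** 2 * p[i][j]
                            for i in range(ng) for j in range(ng))
    return feats


def glcm_features_averaged_bruteforce(volume, mask, n_bins, distance, directions):
    per_dir = []
    for d in directions:
        m = glcm_matrix_bruteforce(volume, mask, n_bins, distance, d)
        if m.sum() > 0:
            per_dir.append(glcm_features_bruteforce(m))
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLRLM by exhaustive run walking
# ---------------------------------------------------------------------------

def glrlm_runs_bruteforce(volume, mask, n_bins, direction):
    """List of (level, run length) for all maximal runs along direction."""
    levels = discretize_minmax(volume, mask, n_bins)
    shape = levels.shape
    d = tuple(direction)
    runs = []
    for start in np.ndindex(shape):
        if levels[start] < 0:
            continue
        prev = tuple(s - c for s, c in zip(start, d))
        prev_ok = all(0 <= prev[a] < shape[a] for a in range(3))
        if prev_ok and levels[prev] == levels[start]:
            continue  # not a run start
        length = 1
        cur = start
        while True:
            nxt = tuple(c + o for c, o in zip(cur, d))
            if not all(0 <= nxt[a] < shape[a] for a in range(3)):
                break
            if levels[nxt] != levels[start]:
                break
            length += 1
            cur = nxt
        runs.append((int(levels[start]), length))
    return runs


def glrlm_features_bruteforce(runs, n_masked):
    nr = len(runs)
    feats = {
        "short_run_emphasis": sum(1.0 / l ** 2 for _, l in runs) / nr,
        "long_run_emphasis": sum(float(l ** 2) for _, l in runs) / nr,
        "run_percentage": nr / n_masked,
        "low_gray_level_run_emphasis": sum(1.0 / (g + 1) ** 2 for g, _ in runs) / nr,
        "high_gray_level_run_emphasis": sum(float((g + 1) ** 2) for g, _ in runs) / nr,
        "short_run_low_gray_level_emphasis":
            sum(1.0 / ((g + 1) ** 2 * l ** 2) for g, l in runs) / nr,
        "short_run_high_gray_level_emphasis":
            sum((g + 1) ** 2 / l ** 2 for g, l in runs) / nr,
        "long_run_low_gray_level_emphasis":
            sum(l ** 2 / (g + 1) ** 2 for g, l in runs) / nr,
        "long_run_high_gray_level_emphasis":
            sum(float((g + 1) ** 2 * l ** 2) for g, l in runs) / nr,
    }
    by_level: dict[int, int] = {}
    by_length: dict[int, int] = {}
    for g, l in runs:
        by_level[g] = by_level.get(g, 0) + 1
        by_length[l] = by_length.get(l, 0) + 1
    feats["gray_level_nonuniformity"] = sum(v ** 2 for v in by_level.values()) / nr
    feats["run_length_nonuniformity"] = sum(v ** 2 for v in by_length.values()) / nr
    return feats


def glrlm_features_averaged_bruteforce(volume, mask, n_bins, directions):
    n_masked = int(np.asarray(mask).astype(bool).sum())
    per_dir = [
        glrlm_features_bruteforce(
            glrlm_runs_bruteforce(volume, mask, n_bins, d), n_masked)
        for d in directions
    ]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# Relief family by exhaustive neighbor scans
# ---------------------------------------------------------------------------

def relieff_bruteforce(X, y, variant, k, sigma=20.0, refs=None):
    """Loop-based Relief weights matching the documented variant semantics."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    classes = sorted(set(y.tolist()))
    priors = {c: float(np.mean(y == c)) for c in classes}
    Xn = X.copy()
    for a in range(p):
        lo, hi = X[:, a].min(), X[:, a].max()
        Xn[:, a] = (X[:, a] - lo) / (hi - lo) if hi > lo else 0.0

    def dist(i, j):
        return sum(abs(Xn[i, a] - Xn[j, a]) for a in range(p))

    def nearest(i, pool, kk):
        ordered = sorted(pool, key=lambda j: (dist(i, j), j))
        return ordered[: min(kk, len(ordered))]

    def contribution(i, neigh):
        kk = len(neigh)
        dists = [dist(i, j) for j in neigh]
        diffs = [[abs(Xn[i, a] - Xn[j, a]) for a in range(p)] for j in neigh]
        eps = 1e-12
        if variant in ("ReliefFequalK", "Relief", "ReliefFavgC", "ReliefFexpC",
                       "ReliefFpe", "ReliefFsmp"):
            w = [1.0 / kk] * kk
        elif variant == "ReliefFexpRank":
            raw = [math.exp(-(((r + 1) / sigma) ** 2)) for r in range(kk)]
            s = sum(raw)
            w = [v / s for v in raw]
        elif variant == "ReliefFdistance":
            raw = [1.0 / (d + eps) for d in dists]
            s = sum(raw)
            w = [v / s for v in raw]
        elif variant == "ReliefFsqrDistance":
            raw = [1.0 / (d ** 2 + eps) for d in dists]
            s = sum(raw)
            w = [v / s for v in raw]
        elif variant == "ReliefFmerit":
            return [
                sum(diffs[j][a] / max(dists[j], eps) for j in range(kk)) / kk
                for a in range(p)
            ]
        elif variant == "ReliefFbestK":
            out = []
            for a in range(p):
                best = -math.inf
                acc = 0.0
                for j in range(kk):
                    acc += diffs[j][a]
                    best = max(best, acc / (j + 1))
                out.append(best)
            return out
        else:
            raise ValueError(variant)
        return [sum(w[j] * diffs[j][a] for j in range(kk)) for a in range(p)]

    kk = 1 if variant == "Relief" else k
    if refs is None:
        refs = list(range(n))
    m = len(refs)
    W = [0.0] * p
    for i in refs:
        ci = y[i]
        hits = nearest(i, [j for j in range(n) if y[j] == ci and j != i], kk)
        hit_con = contribution(i, hits)
        if variant == "ReliefFpe":
            pool = [j for j in range(n) if y[j] != ci]
            near = nearest(i, pool, kk)
            miss_con = [0.0] * p
            for j in near:
                ratio = priors[y[j]] / (1.0 - priors[ci])
                dif = [abs(Xn[i, a] - Xn[j, a]) for a in range(p)]
                for a in range(p):
                    miss_con[a] += ratio * dif[a] / len(near)
        else:
            miss_con = [0.0] * p
            others = [c for c in classes if c != ci]
            if variant == "Relief":
                weights = {others[0]: 1.0}
            elif variant == "ReliefFavgC":
                weights = {c: 1.0 / len(others) for c in others}
            elif variant == "ReliefFexpC":
                raw = {c: math.exp(priors[c]) for c in others}
                s = sum(raw.values())
                weights = {c: v / s for c, v in raw.items()}
            else:
                weights = {c: priors[c] / (1.0 - priors[ci]) for c in others}
            for c in others:
                near = nearest(i, [j for j in range(n) if y[j] == c], kk)
                con = contribution(i, near)
                for a in range(p):
                    miss_con[a] += weights[c] * con[a]
        for a in range(p):
            W[a] += (miss_con[a] - hit_con[a]) / m
    return np.array(W)


# ---------------------------------------------------------------------------
# AUC by pair counting; naive Bayes by the odds formula
# ---------------------------------------------------------------------------

def auc_pair_counting(scores, labels):
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def naive_bayes_odds(x, mu_pos, sd_pos, mu_neg, sd_neg, prior_pos):
    """Posterior p(+|x) from the prior-odds times likelihood-ratio formula."""
    def pdf(v, mu, sd):
        return math.exp(-0.5 * ((v - mu) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))

    odds = prior_pos / (1.0 - prior_pos)
    for v, mp, sp, mn, sn in zip(x, mu_pos, sd_pos, mu_neg, sd_neg):
        odds *= pdf(v, mp, sp) / pdf(v, mn, sn)
    return odds / (1.0 + odds)
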