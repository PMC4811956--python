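"""Gray-level co-occurrence (GLCM) and run-length (GLRLM) texture features.

Intensities inside the mask are discretized to ``n_bins`` equal-width bins
between the masked minimum and maximum (min-max binning makes every texture
feature invariant to adding a constant to the image).  Co-occurrences are
counted over the 13 unique 3D direction vectors at a given voxel distance,
symmetrized and normalized per direction; runs are maximal sequences of
equal gray level along each direction, broken by mask boundaries.  The 22
GLCM and 11 GLRLM features are computed per direction and averaged, the
standard convention for rotationally fair 3D texture analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DIRECTIONS_13", "GLCMatrix", "GLRLMatrix",
    "discretize_volume", "build_glcm", "glcm_features",
    "build_glrlm", "glrlm_features", "GLCM_NAMES", "GLRLM_NAMES",
]

#: The 13 unique 3D offsets (one per direction, up to sign).
DIRECTIONS_13 = (
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

GLCM_NAMES = (
    "autocorrelation", "cluster_prominence", "cluster_shade", "cluster_tendency",
    "contrast", "correlation1", "difference_entropy", "dissimilarity", "energy",
    "entropy", "homogeneity1", "homogeneity2", "imc1", "imc2", "idmn", "idn",
    "inverse_variance", "max_probability", "sum_average", "sum_entropy",
    "sum_variance", "variance",
)

GLRLM_NAMES = (
    "short_run_emphasis", "long_run_emphasis", "gray_level_nonuniformity",
    "run_length_nonuniformity", "run_percentage", "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis", "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis", "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis",
)


def discretize_volume(volume: np.ndarray, mask: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width binning of masked voxels to integer levels 0..n_bins-1.

    Voxels outside the mask get level -1.  A constant region maps to level 0.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask).astype(bool)
    vals = volume[mask]
    levels = np.full(volume.shape, -1, dtype=np.int64)
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        levels[mask] = 0
        return levels
    idx = np.floor((volume[mask] - lo) / (hi - lo) * n_bins).astype(np.int64)
    levels[mask] = np.clip(idx, 0, n_bins - 1)
    return levels


def _pair_slices(shape, offset):
    """Slices (src, dst) so that src + offset = dst, both in bounds."""
    src, dst = [], []
    for dim, d in zip(shape, offset):
        if d >= 0:
            src.append(slice(0, dim - d))
            dst.append(slice(d, dim))
        else:
            src.append(slice(-d, dim))
            dst.append(slice(0, dim + d))
    return tuple(src), tuple(dst)


@dataclass(frozen=True)
class GLCMatrix:
    """Per-direction symmetric normalized co-occurrence matrices.

    ``matrices`` has shape (n_directions, n_bins, n_bins); each slice sums
    to 1 (directions with no valid voxel pair are dropped at build time).
    """

    matrices: np.ndarray
    n_bins: int
    distance: int
    directions: tuple[tuple[int, int, int], ...]


def build_glcm(volume, mask, n_bins: int = 32, distance: int = 1,
               directions=DIRECTIONS_13) -> GLCMatrix:
    mask = np.asarray(mask).astype(bool)
    if mask.sum() < 2:
        raise ValueError("GLCM requires at least 2 masked voxels")
    levels = discretize_volume(volume, mask, n_bins)
    mats, used = [], []
    for d in directions:
        off = tuple(int(distance) * c for c in d)
        s_src, s_dst = _pair_slices(levels.shape, off)
        a = levels[s_src]
        b = levels[s_dst]
        valid = (a >= 0) & (b >= 0)
        if not valid.any():
            continue
        counts = np.bincount(
            a[valid] * n_bins + b[valid], minlength=n_bins * n_bins
        ).reshape(n_bins, n_bins).astype(float)
        counts = counts + counts.T  # symmetric: count (i,j) and (j,i)
        mats.append(counts / counts.sum())
        used.append(tuple(d))
    if not mats:
        raise ValueError("no co-occurring voxel pairs at this distance")
    return GLCMatrix(np.stack(mats), n_bins, int(distance), tuple(used))


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    sd_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))
    sd_y = float(np.sqrt(np.sum((i - mu_y) ** 2 * py)))

    def xlog2(v):
        v = np.asarray(v, dtype=float)
        out = np.zeros_like(v)
        nz = v > 0
        out[nz] = v[nz] * np.log2(v[nz])
        return out

    # p_{x+y}(k), k = 2..2*ng and p_{x-y}(k), k = 0..ng-1
    ksum = (ii + jj).astype(int)
    kdiff = np.abs(ii - jj).astype(int)
    p_sum = np.bincount(ksum.ravel(), weights=p.ravel(), minlength=2 * ng + 1)[2:]
    p_diff = np.bincount(kdiff.ravel(), weights=p.ravel(), minlength=ng)
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)

    entropy = float(-np.sum(xlog2(p)))
    hx = float(-np.sum(xlog2(px)))
    hy = float(-np.sum(xlog2(py)))
    pxy_prod = np.outer(px, py)
    nz = pxy_prod > 0
    hxy1 = float(-np.sum(p[nz] * np.log2(pxy_prod[nz])))
    hxy2 = float(-np.sum(xlog2(pxy_prod)))
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    contrast = float(np.sum((ii - jj) ** 2 * p))
    sum_avg = float(np.sum(k_sum * p_sum))
    diff_mask = ii != jj
    inv_var = float(np.sum(p[diff_mask] / (ii - jj)[diff_mask] ** 2))
    mu = mu_x  # symmetric matrix: mu_x == mu_y
    if sd_x > 0 and sd_y > 0:
        correl1 = float((np.sum(ii * jj * p) - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correl1 = 0.0
    return {
        "autocorrelation": float(np.sum(ii * jj * p)),
        "cluster_prominence": float(np.sum((ii + jj - mu_x - mu_y) ** 4 * p)),
        "cluster_shade": float(np.sum((ii + jj - mu_x - mu_y) ** 3 * p)),
        "cluster_tendency": float(np.sum((ii + jj - mu_x - mu_y) ** 2 * p)),
        "contrast": contrast,
        "correlation1": correl1,
        "difference_entropy": float(-np.sum(xlog2(p_diff))),
        "dissimilarity": float(np.sum(np.abs(ii - jj) * p)),
        "energy": float(np.sum(p ** 2)),
        "entropy": entropy,
        "homogeneity1": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "homogeneity2": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "imc1": imc1,
        "imc2": imc2,
        "idmn": float(np.sum(p / (1.0 + ((ii - jj) / ng) ** 2))),
        "idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "inverse_variance": inv_var,
        "max_probability": float(p.max()),
        "sum_average": sum_avg,
        "sum_entropy": float(-np.sum(xlog2(p_sum))),
        "sum_variance": float(np.sum((k_sum - sum_avg) ** 2 * p_sum)),
        "variance": float(np.sum((ii - mu) ** 2 * p)),
    }


def glcm_features(glcm: GLCMatrix) -> dict[str, float]:
    """The 22 co-occurrence features, averaged over directions."""
    per_dir = [_glcm_features_single(m) for m in glcm.matrices]
    return {name: float(np.mean([d[name] for d in per_dir])) for name in GLCM_NAMES}


# ---------------------------------------------------------------------------
# run length
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GLRLMatrix:
    """Per-direction run-length count matrices (gray level x run length).

    ``counts`` has shape (n_directions, n_bins, max_run_length); entry
    (d, g, l-1) is the number of maximal runs of level g and length l along
    direction d.  ``n_masked`` is the number of masked voxels (run
    percentage denominator).
    """

    counts: np.ndarray
    n_bins: int
    directions: tuple[tuple[int, int, int], ...]
    n_masked: int


def _runs_one_direction(levels: np.ndarray, direction) -> np.ndarray:
    """Lengths/levels of all maximal masked runs along ``direction``.

    Returns an array of (level, length) rows.  Voxels outside the mask
    (level -1) break runs.  A run along d is identical to the run along -d.
    """
    d = np.asarray(direction, dtype=np.int64)
    coords = np.argwhere(levels >= 0)
    lev = levels[levels >= 0]
    # Parameterize each lattice line v(t) = v0 + t*d by t from one nonzero axis.
    ax = int(np.flatnonzero(d)[0])
    t = coords[:, ax] * d[ax]  # d[ax] is +-1 so t increments by 1 along the line
    line_id = coords - t[:, None] * d[None, :]
    order = np.lexsort((t, line_id[:, 2], line_id[:, 1], line_id[:, 0]))
    t_s = t[order]
    lev_s = lev[order]
    line_s = line_id[order]
    same_line = np.all(line_s[1:] == line_s[:-1], axis=1)
    contiguous = np.diff(t_s) == 1
    same_level = lev_s[1:] == lev_s[:-1]
    boundary = ~(same_line & contiguous & same_level)
    starts = np.concatenate(([0], np.flatnonzero(boundary) + 1))
    ends = np.concatenate((np.flatnonzero(boundary) + 1, [len(lev_s)]))
    lengths = ends - starts
    return np.column_stack((lev_s[starts], lengths))


def build_glrlm(volume, mask, n_bins: int = 32,
                directions=DIRECTIONS_13) -> GLRLMatrix:
    mask = np.asarray(mask).astype(bool)
    if mask.sum() < 1:
        raise ValueError("GLRLM requires at least one masked voxel")
    levels = discretize_volume(volume, mask, n_bins)
    max_len = int(mask.sum())
    counts = np.zeros((len(directions), n_bins, max_len), dtype=float)
    for k, d in enumerate(directions):
        runs = _runs_one_direction(levels, d)
        np.add.at(counts[k], (runs[:, 0], runs[:, 1] - 1), 1.0)
    rmax = max(1, int(np.max(np.nonzero(counts.sum(axis=(0, 1)))[0])) + 1)
    return GLRLMatrix(counts[:, :, :rmax], n_bins,
                      tuple(tuple(d) for d in directions), int(mask.sum()))


def _glrlm_features_single(c: np.ndarray, n_masked: int) -> dict[str, float]:
    ng, rmax = c.shape
    nr = c.sum()
    i = np.arange(1, ng + 1, dtype=float)[:, None]   # gray level index
    l = np.arange(1, rmax + 1, dtype=float)[None, :]  # run length
    g_marg = c.sum(axis=1)
    l_marg = c.sum(axis=0)
    return {
        "short_run_emphasis": float(np.sum(c / l ** 2) / nr),
        "long_run_emphasis": float(np.sum(c * l ** 2) / nr),
        "gray_level_nonuniformity": float(np.sum(g_marg ** 2) / nr),
        "run_length_nonuniformity": float(np.sum(l_marg ** 2) / nr),
        "run_percentage": float(nr / n_masked),
        "low_gray_level_run_emphasis": float(np.sum(c / i ** 2) / nr),
        "high_gray_level_run_emphasis": float(np.sum(c * i ** 2) / nr),
        "short_run_low_gray_level_emphasis": float(np.sum(c / (i ** 2 * l ** 2)) / nr),
        "short_run_high_gray_level_emphasis": float(np.sum(c * i ** 2 / l ** 2) / nr),
        "long_run_low_gray_level_emphasis": float(np.sum(c * l ** 2 / i ** 2) / nr),
        "long_run_high_gray_level_emphasis": float(np.sum(c * (i * l) ** 2) / nr),
    }


def glrlm_features(glrlm: GLRLMatrix) -> dict[str, float]:
    """The 11 run-length features, averaged over directions."""
    per_dir = [
        _glrlm_features_single(c, glrlm.n_masked) for c in glrlm.counts
    ]
    return {name: float(np.mean([d[name] for d in per_dir])) for name in GLRLM_NAMES}
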