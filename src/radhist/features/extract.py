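"""Assembly of the full 440-feature radiomic vector.

The canonical naming scheme (matching the printed feature names of the
study this pipeline reproduces the shape of):

* original image: ``Stats_<s>`` (15), ``Shape_<s>`` (8), ``Glcm_<s>`` (22),
  ``Rlgl_<s>`` (11);
* each wavelet subband SUB in {LLL..HHH}: ``Wavelet_<SUB>_stats_<s>`` (15),
  ``Wavelet_<SUB>_glcm_<s>`` (22), ``Wavelet_<SUB>_rlgl_<s>`` (11).

56 + 8 x 48 = 440 features.  Short names are camelCase (``Stats_min``,
``Glcm_clusShade``, ``Rlgl_lowGrayLevelRunEmphasis``, ...).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..image import as_mask, as_volume
from .firstorder import first_order_stats
from .shape import shape_features
from .texture import build_glcm, build_glrlm, glcm_features, glrlm_features
from .wavelet import SUBBAND_LABELS, wavelet_decompose

__all__ = ["ExtractionConfig", "extract_all", "feature_names", "RadiomicFeatureExtractor"]

STATS_SHORT = {
    "energy": "energy", "total_energy": "totalEnergy", "entropy": "entropy",
    "minimum": "min", "maximum": "max", "mean": "mean", "median": "median",
    "range": "range", "mean_absolute_deviation": "mad",
    "root_mean_square": "rms", "skewness": "skewness", "kurtosis": "kurtosis",
    "standard_deviation": "sd", "uniformity": "uniformity", "variance": "var",
}
SHAPE_SHORT = {
    "volume": "volume", "surface_area": "surfaceArea",
    "surface_to_volume_ratio": "surface2volumeRatio", "sphericity": "sphericity",
    "compactness1": "compactness1", "compactness2": "compactness2",
    "spherical_disproportion": "sphericalDisproportion",
    "max_3d_diameter": "max3dDiameter",
}
GLCM_SHORT = {
    "autocorrelation": "autoCorrelation", "cluster_prominence": "clusProm",
    "cluster_shade": "clusShade", "cluster_tendency": "clusTend",
    "contrast": "contrast", "correlation1": "correl1",
    "difference_entropy": "diffEntropy", "dissimilarity": "dissimilarity",
    "energy": "energy", "entropy": "entropy", "homogeneity1": "homogeneity1",
    "homogeneity2": "homogeneity2", "imc1": "imc1", "imc2": "imc2",
    "idmn": "idmn", "idn": "idn", "inverse_variance": "invVariance",
    "max_probability": "maxProb", "sum_average": "sumAvg",
    "sum_entropy": "sumEntropy", "sum_variance": "sumVariance",
    "variance": "variance",
}
GLRLM_SHORT = {
    "short_run_emphasis": "shortRunEmphasis",
    "long_run_emphasis": "longRunEmphasis",
    "gray_level_nonuniformity": "grayLevelNonuniformity",
    "run_length_nonuniformity": "runLengthNonuniformity",
    "run_percentage": "runPercentage",
    "low_gray_level_run_emphasis": "lowGrayLevelRunEmphasis",
    "high_gray_level_run_emphasis": "highGrayLevelRunEmphasis",
    "short_run_low_gray_level_emphasis": "shortRunLowGrayLevelEmphasis",
    "short_run_high_gray_level_emphasis": "shortRunHighGrayLevelEmphasis",
    "long_run_low_gray_level_emphasis": "longRunLowGrayLevelEmphasis",
    "long_run_high_gray_level_emphasis": "longRunHighGrayLevelEmphasis",
}


@dataclass(frozen=True)
class ExtractionConfig:
    """Extraction settings: texture bin count, GLCM distance, wavelet family."""

    n_bins: int = 32
    glcm_distance: int = 1
    wavelet: str = "coif1"

    def validate(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.glcm_distance < 1:
            raise ValueError("glcm_distance must be >= 1")


def feature_names(config: ExtractionConfig | None = None) -> list[str]:
    """The canonical ordered list of all 440 feature names."""
    names = [f"Stats_{s}" for s in STATS_SHORT.values()]
    names += [f"Shape_{s}" for s in SHAPE_SHORT.values()]
    names += [f"Glcm_{s}" for s in GLCM_SHORT.values()]
    names += [f"Rlgl_{s}" for s in GLRLM_SHORT.values()]
    for sub in SUBBAND_LABELS:
        names += [f"Wavelet_{sub}_stats_{s}" for s in STATS_SHORT.values()]
        names += [f"Wavelet_{sub}_glcm_{s}" for s in GLCM_SHORT.values()]
        names += [f"Wavelet_{sub}_rlgl_{s}" for s in GLRLM_SHORT.values()]
    return names


def _intensity_texture(values, mask, voxel_volume, config) -> tuple[dict, dict, dict]:
    stats = first_order_stats(values[mask], n_bins=config.n_bins,
                              voxel_volume=voxel_volume)
    glcm = glcm_features(build_glcm(values, mask, n_bins=config.n_bins,
                                    distance=config.glcm_distance))
    glrlm = glrlm_features(build_glrlm(values, mask, n_bins=config.n_bins))
    return stats, glcm, glrlm


def extract_all(volume, mask, config: ExtractionConfig | None = None) -> dict[str, float]:
    """Compute the 440 radiomic features of one volume/mask pair.

    Requires at least 2 masked voxels (texture is undefined on a single
    voxel) and a mask shaped like the volume.
    """
    config = config or ExtractionConfig()
    config.validate()
    vol = as_volume(volume)
    msk = as_mask(mask)
    if vol.shape != msk.shape:
        raise ValueError("volume and mask shapes differ")
    if msk.n_voxels < 2:
        raise ValueError("texture features require at least 2 masked voxels")
    m = msk.flags
    out: dict[str, float] = {}

    stats, glcm, glrlm = _intensity_texture(vol.values, m, vol.voxel_volume, config)
    out.update({f"Stats_{STATS_SHORT[k]}": v for k, v in stats.items()})
    out.update({f"Shape_{SHAPE_SHORT[k]}": v
                for k, v in shape_features(m, vol.spacing).items()})
    out.update({f"Glcm_{GLCM_SHORT[k]}": v for k, v in glcm.items()})
    out.update({f"Rlgl_{GLRLM_SHORT[k]}": v for k, v in glrlm.items()})

    for sub, band in wavelet_decompose(vol.values, config.wavelet).items():
        stats, glcm, glrlm = _intensity_texture(band, m, vol.voxel_volume, config)
        out.update({f"Wavelet_{sub}_stats_{STATS_SHORT[k]}": v for k, v in stats.items()})
        out.update({f"Wavelet_{sub}_glcm_{GLCM_SHORT[k]}": v for k, v in glcm.items()})
        out.update({f"Wavelet_{sub}_rlgl_{GLRLM_SHORT[k]}": v for k, v in glrlm.items()})
    return out


class RadiomicFeatureExtractor:
    """sklearn-style transformer: list of (volume, mask) pairs -> feature frame.

    Stateless (``fit`` records the output feature names only); ``transform``
    returns a pandas DataFrame with one row per sample and 440 columns.
    """

    def __init__(self, n_bins: int = 32, glcm_distance: int = 1, wavelet: str = "coif1"):
        self.n_bins = n_bins
        self.glcm_distance = glcm_distance
        self.wavelet = wavelet

    def get_params(self, deep: bool = True) -> dict:
        return {"n_bins": self.n_bins, "glcm_distance": self.glcm_distance,
                "wavelet": self.wavelet}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self) -> ExtractionConfig:
        return ExtractionConfig(self.n_bins, self.glcm_distance, self.wavelet)

    def fit(self, X=None, y=None):
        self.feature_names_out_ = feature_names(self._config())
        return self

    def transform(self, X):
        import pandas as pd

        rows = [extract_all(vol, msk, self._config()) for vol, msk in X]
        return pd.DataFrame(rows)

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)
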