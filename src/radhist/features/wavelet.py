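"""Single-level undecimated 3D wavelet decomposition (coiflet-1 by default).

The transform is separable: along each axis the volume is filtered with
either the low-pass (L) or high-pass (H) decomposition filter, without
downsampling, with symmetric (half-sample mirror) boundary extension.  The
eight subbands are labeled by the filter applied per axis in array order,
e.g. ``HLL`` = high-pass on axis 0, low-pass on axes 1 and 2.  Every subband
keeps the shape of the input, so the tumor mask stays aligned and texture
features can be recomputed on each subband.  Filters are taken from
PyWavelets; filtering is cross-correlation with the decomposition filters,
centered (scipy.ndimage origin convention).
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pywt
from scipy import ndimage

__all__ = ["wavelet_decompose", "SUBBAND_LABELS"]

SUBBAND_LABELS = tuple("".join(s) for s in product("LH", repeat=3))


def wavelet_decompose(volume: np.ndarray, wavelet: str = "coif1") -> dict[str, np.ndarray]:
    """Return the 8 undecimated subbands {'LLL', 'LLH', ..., 'HHH'}."""
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("wavelet_decompose requires a 3D volume")
    w = pywt.Wavelet(wavelet)
    filters = {"L": np.asarray(w.dec_lo), "H": np.asarray(w.dec_hi)}
    out = {}
    for labels in SUBBAND_LABELS:
        sub = volume
        for axis, lab in enumerate(labels):
            sub = ndimage.correlate1d(sub, filters[lab], axis=axis, mode="reflect")
        out[labels] = sub
    return out
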