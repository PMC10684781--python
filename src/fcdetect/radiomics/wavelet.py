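"""Single-level 3D stationary wavelet decomposition into 8 sub-bands.

The stationary (undecimated) transform keeps every sub-band at the input
resolution, so the same ROI mask applies to all of them. Sub-bands are
named by the filter applied along each axis: L = low-pass, H = high-pass,
first letter = axis 0. Default kernel: coiflet-1.
"""

from __future__ import annotations

import numpy as np
import pywt

from fcdetect.volume import Volume

WAVELET_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

_KEY_MAP = {"a": "L", "d": "H"}


def wavelet_subbands(image: Volume, wavelet: str = "coif1") -> dict[str, Volume]:
    """Decompose a volume into its 8 first-level wavelet sub-bands.

    Dimensions must be at least the filter length; odd dimensions are
    symmetrically padded to even and cropped back after the transform.
    """
    data = np.asarray(image.data, dtype=float)
    wav = pywt.Wavelet(wavelet)
    if any(s < wav.dec_len for s in data.shape):
        raise ValueError(f"image shape {data.shape} too small for wavelet {wavelet} (filter length {wav.dec_len})")
    pad = [(0, s % 2) for s in data.shape]
    padded = np.pad(data, pad, mode="symmetric")
    coeffs = pywt.swtn(padded, wav, level=1)[0]
    crop = tuple(slice(0, s) for s in data.shape)
    out = {}
    for key, arr in coeffs.items():
        name = "".join(_KEY_MAP[c] for c in key)
        out[name] = image.like(arr[crop])
    return {name: out[name] for name in WAVELET_SUBBANDS}
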