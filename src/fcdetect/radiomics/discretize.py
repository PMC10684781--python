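"""Gray-level discretization of ROI intensities for texture matrices."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class DiscretizedROI:
    """ROI intensities quantized to integer gray levels 1..n_levels.

    ``levels`` is a full-grid integer array, 0 outside the mask.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    bin_edges: np.ndarray

    @property
    def roi_levels(self) -> np.ndarray:
        """Gray levels of the mask voxels only (1D)."""
        return self.levels[self.mask]


def discretize(image: np.ndarray, mask: np.ndarray, n_levels: int = 32) -> DiscretizedROI:
    """Equal-width binning of the ROI intensity range into n_levels levels.

    The ROI minimum maps to level 1 and the maximum to level n_levels. A
    constant ROI collapses to a single level (flagged with a warning).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    vals = np.asarray(image, dtype=float)[mask]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(mask.shape, dtype=np.int32)
    if hi == lo:
        warnings.warn("constant ROI: all voxels mapped to gray level 1", stacklevel=2)
        levels[mask] = 1
        edges = np.array([lo, lo])
        return DiscretizedROI(levels, mask, n_levels, edges)
    edges = np.linspace(lo, hi, n_levels + 1)
    q = np.floor((vals - lo) / (hi - lo) * n_levels).astype(np.int32) + 1
    levels[mask] = np.clip(q, 1, n_levels)
    return DiscretizedROI(levels, mask, n_levels, edges)
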