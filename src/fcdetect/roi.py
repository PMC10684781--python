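"""Radiomics ROI construction from tissue probability maps and an atlas.

Four ROI kinds are built per region per hemisphere:

* ``gm`` / ``wm`` - tissue masks by probability threshold (default 0.5);
* ``gm_wm`` - their union;
* ``gwm`` - the gray-white boundary band: voxels that are either
  near-certain gray matter (gm >= 1 - eps) or partial-volume white matter
  (0 < wm < 1 - eps), restricted to a band of configurable width around the
  gray/white interface. Without the band restriction the threshold rule
  alone would sweep in every pure-gray voxel and the "boundary" ROI would
  not be a boundary.

Hemispheres are always defined by atlas label codes, never by a midline
plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from fcdetect.volume import Volume

ROI_KINDS = ("gm", "wm", "gm_wm", "gwm")

#: comparison slack for the "probability >= 1.0" boundary rule; literal
#: float equality would select almost nothing on a smooth ramp
GWM_EPS = 1e-6

#: half-width (mm) of the band around the gray/white interface kept in GWM
GWM_BAND_MM = 2.0

MIN_ROI_VOXELS = 8


@dataclass
class ROIMask:
    """A binary ROI bound to a region, hemisphere and ROI kind."""

    mask: Volume
    roi_kind: str
    region: str = "frontal"
    hemisphere: str = "left"

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask.data))

    @property
    def indices(self) -> np.ndarray:
        return np.argwhere(self.mask.data)


def _interface_band(gm: np.ndarray, wm: np.ndarray, voxel_size: float, band_mm: float) -> np.ndarray:
    """Voxels within band_mm of the gray/white interface {gm == wm} inside brain."""
    inside = (gm + wm) > 0.5
    wm_side = inside & (wm >= gm)
    gm_side = inside & (wm < gm)
    if not wm_side.any() or not gm_side.any():
        return np.zeros_like(inside)
    d_to_wm = ndimage.distance_transform_edt(~wm_side, sampling=voxel_size)
    d_to_gm = ndimage.distance_transform_edt(~gm_side, sampling=voxel_size)
    dist = np.where(wm_side, d_to_gm, d_to_wm)
    return inside & (dist <= band_mm)


def build_roi(
    gm_prob: Volume,
    wm_prob: Volume,
    region_mask: Volume,
    roi_kind: str,
    region: str = "frontal",
    hemisphere: str = "left",
    *,
    gm_threshold: float = 0.5,
    wm_threshold: float = 0.5,
    gwm_eps: float = GWM_EPS,
    gwm_band_mm: float = GWM_BAND_MM,
    min_voxels: int = MIN_ROI_VOXELS,
) -> ROIMask:
    """Build one radiomics ROI inside a region.

    Raises ValueError on grid mismatch; warns and returns an empty mask if
    the ROI has fewer than ``min_voxels`` voxels.
    """
    if roi_kind not in ROI_KINDS:
        raise ValueError(f"roi_kind must be one of {ROI_KINDS}, got {roi_kind!r}")
    gm, wm = np.asarray(gm_prob.data, float), np.asarray(wm_prob.data, float)
    region_arr = np.asarray(region_mask.data) > 0
    if gm.shape != wm.shape or gm.shape != region_arr.shape:
        raise ValueError("gm_prob, wm_prob and region_mask must share one grid")

    if roi_kind == "gm":
        mask = gm >= gm_threshold
    elif roi_kind == "wm":
        mask = wm >= wm_threshold
    elif roi_kind == "gm_wm":
        mask = (gm >= gm_threshold) | (wm >= wm_threshold)
    else:  # gwm: boundary-threshold rule restricted to the interface band,
        # kept inside the tissue union so GWM is always a subset of GM|WM
        rule = (gm >= 1.0 - gwm_eps) | ((wm > 0) & (wm < 1.0 - gwm_eps))
        band = _interface_band(gm, wm, float(gm_prob.voxel_size[0]), gwm_band_mm)
        tissue = (gm >= gm_threshold) | (wm >= wm_threshold)
        mask = rule & band & tissue

    mask = mask & region_arr
    if mask.sum() < min_voxels:
        warnings.warn(
            f"ROI {roi_kind}/{region}/{hemisphere} has {int(mask.sum())} voxels "
            f"(< {min_voxels}); returning empty mask",
            stacklevel=2,
        )
        mask = np.zeros_like(mask)
    return ROIMask(mask=gm_prob.like(mask), roi_kind=roi_kind, region=region, hemisphere=hemisphere)


def frontal_union(subregion_masks: list[ROIMask], region: str = "frontal") -> ROIMask:
    """Voxelwise union of same-kind, same-hemisphere subregion ROIs.

    The frontal lobe is the combination of all its subregions; the union is
    idempotent and rejects mixed ROI kinds or hemispheres.
    """
    if not subregion_masks:
        raise ValueError("need at least one mask")
    kinds = {m.roi_kind for m in subregion_masks}
    hemis = {m.hemisphere for m in subregion_masks}
    if len(kinds) > 1:
        raise ValueError(f"mixed roi_kinds in union: {sorted(kinds)}")
    if len(hemis) > 1:
        raise ValueError(f"mixed hemispheres in union: {sorted(hemis)}")
    out = np.zeros(subregion_masks[0].mask.shape, dtype=bool)
    for m in subregion_masks:
        out |= m.mask.data.astype(bool)
    return ROIMask(
        mask=subregion_masks[0].mask.like(out),
        roi_kind=subregion_masks[0].roi_kind,
        region=region,
        hemisphere=next(iter(hemis)),
    )
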