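"""Left-right asymmetry features and the two-step feature normalization.

The asymmetry index of a feature f is

    asymmetry = 2 (f_left - f_right) / (f_left + f_right)

bounded in [-2, 2] for non-negative inputs and invariant to positive
rescaling of both sides. The left-hemisphere sample carries +asymmetry and
the right-hemisphere sample -asymmetry, so a lateralized abnormality gives
the two hemisphere samples of one subject equal-magnitude, opposite-sign
asymmetry blocks.

Normalization is two-step: (1) intra-subject z-scoring - each sample's
feature vector is standardized, removing per-subject global scale; for
controls the same scoring uses their own rows; (2) every feature is then
re-scaled by the control-pool mean and standard deviation, so controls end
up with per-feature mean 0 / SD 1 and patients are expressed in control-SD
units. The axis of the intra-subject step is configurable (see ``axis``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

ASYM_PREFIX = "asym_"


def asymmetry_index(f_left, f_right):
    """Signed left-right asymmetry, 2(l - r)/(l + r); 0 when l + r == 0.

    Accepts scalars or arrays. The zero-denominator convention reads
    "equal and opposite or both absent" as no lateralization.
    """
    l = np.asarray(f_left, dtype=float)
    r = np.asarray(f_right, dtype=float)
    denom = l + r
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, 2.0 * (l - r) / np.where(denom != 0, denom, 1.0), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class PairedFeatureTable:
    """Per-subject paired left/right feature rows plus sample labels.

    ``features`` is indexed by (subject, hemisphere) with one shared feature
    name set; ``labels`` aligns with the rows (1 = lesioned sample).
    """

    features: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.labels.index):
            raise ValueError("features and labels must share an index")
        counts = self.features.groupby(level=0).size()
        if (counts != 2).any():
            bad = counts[counts != 2].index.tolist()
            raise ValueError(f"subjects without exactly one left/right pair: {bad}")

    @property
    def subjects(self) -> list:
        return list(self.features.index.get_level_values(0).unique())


def augment_with_asymmetry(table: PairedFeatureTable, mode: str = "asymmetry") -> pd.DataFrame:
    """Append signed asymmetry features to each hemisphere row.

    mode="original" passes the raw features through; mode="asymmetry"
    doubles the feature count by appending, for every feature, +asymmetry
    on the left row and -asymmetry on the right row.
    """
    if mode not in ("original", "asymmetry"):
        raise ValueError(f"mode must be 'original' or 'asymmetry', got {mode!r}")
    feats = table.features
    if mode == "original":
        return feats.copy()
    left = feats.xs("left", level=1)
    right = feats.xs("right", level=1)
    asym = pd.DataFrame(
        asymmetry_index(left.to_numpy(), right.to_numpy()),
        index=left.index,
        columns=[ASYM_PREFIX + c for c in feats.columns],
    )
    blocks = []
    for hemi, sign in (("left", 1.0), ("right", -1.0)):
        block = sign * asym
        block.index = pd.MultiIndex.from_product([asym.index, [hemi]], names=feats.index.names)
        blocks.append(block)
    signed = pd.concat(blocks).reindex(feats.index)
    return pd.concat([feats, signed], axis=1)


@dataclass
class ControlMoments:
    """Stored step-2 scaling (control-pool mean/SD per feature), reusable at
    an independent validation site."""

    center: pd.Series
    scale: pd.Series

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        return (table - self.center) / self.scale

    def to_dict(self) -> dict:
        return {"center": self.center.to_dict(), "scale": self.scale.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "ControlMoments":
        return cls(center=pd.Series(d["center"]), scale=pd.Series(d["scale"]))


def _intra_subject_zscore(table: pd.DataFrame, axis: str) -> pd.DataFrame:
    """Step-1 scoring. Asymmetry-index columns pass through untouched: the
    index is already an intra-subject, dimensionless quantity, and folding
    it into the row statistics would re-inject the subject-global scale the
    step exists to remove."""
    raw_cols = [c for c in table.columns if not str(c).startswith(ASYM_PREFIX)]
    out = table.copy()
    if not raw_cols:
        return out
    raw = table[raw_cols]
    if axis == "features":
        mu = raw.mean(axis=1)
        sd = raw.std(axis=1, ddof=0).replace(0.0, 1.0)
        out[raw_cols] = raw.sub(mu, axis=0).div(sd, axis=0)
    elif axis == "samples":
        def _z(g: pd.DataFrame) -> pd.DataFrame:
            if len(g) < 2:  # single-sample subject: leave for step-2 scaling
                return g
            sd = g.std(ddof=0).replace(0.0, 1.0)
            return (g - g.mean()) / sd
        out[raw_cols] = raw.groupby(level=0, group_keys=False).apply(_z)
    else:
        raise ValueError(f"axis must be 'features' or 'samples', got {axis!r}")
    return out


def normalize(
    patients: pd.DataFrame,
    controls: pd.DataFrame,
    axis: str = "features",
) -> tuple[pd.DataFrame, pd.DataFrame, ControlMoments]:
    """Two-step normalization of patient and control feature tables.

    Both tables are indexed by (subject, sample) and share feature names.
    Step 1 applies intra-subject z-scoring (per row across features by
    default, or per feature across each subject's samples with
    axis="samples"). Step 2 re-scales every feature by the control-pool
    mean/SD computed from the step-1 controls; a zero control SD falls back
    to scale 1 with a warning. Deterministic; returns the stored moments so
    the identical scaling can be replayed on new cohorts.
    """
    if list(patients.columns) != list(controls.columns):
        raise ValueError("patients and controls must share feature names")
    pat1 = _intra_subject_zscore(patients, axis)
    ctl1 = _intra_subject_zscore(controls, axis)

    center = ctl1.mean()
    scale = ctl1.std(ddof=0)
    zero = scale == 0.0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} feature(s) with zero control SD; scale set to 1",
            stacklevel=2,
        )
        scale = scale.mask(zero, 1.0)
    moments = ControlMoments(center=center, scale=scale)
    return moments.apply(pat1), moments.apply(ctl1), moments
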