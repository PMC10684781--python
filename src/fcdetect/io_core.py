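"""Shared IO: feature tables (CSV + manifest JSON), YAML configs,
control-moment stores and run provenance."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fcdetect.asymmetry import ControlMoments
from fcdetect.phantom import PhantomConfig, SubjectRecord
from fcdetect.radiomics.extract import feature_manifest
from fcdetect.volume import Volume, read_volume, write_volume

__all__ = [
    "read_volume", "write_volume",
    "read_feature_table", "write_feature_table",
    "read_phantom_config", "write_phantom_config",
    "save_control_moments", "load_control_moments",
    "write_subject_nifti", "write_morph_table", "config_hash",
]

_FLOAT_FMT = "%.15g"  # >= 12 significant digits survive the round-trip


def write_feature_table(table: pd.DataFrame, path: str | Path, manifest: bool = True) -> None:
    """Write a sample x feature table as CSV plus a feature-manifest JSON.

    Duplicate feature names are rejected; the manifest records each
    feature's provenance tags (modality, image, family).
    """
    path = Path(path)
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature names: {dupes}")
    table.to_csv(path, float_format=_FLOAT_FMT)
    if manifest and len(table.columns):
        mf = feature_manifest(table).reset_index().to_dict(orient="records")
        path.with_suffix(".manifest.json").write_text(json.dumps(mf, indent=1))


def read_feature_table(path: str | Path, index_col=None) -> pd.DataFrame:
    """Read a feature table CSV; index columns are auto-detected from the
    header (unnamed leading columns become the index)."""
    path = Path(path)
    head = pd.read_csv(path, nrows=0)
    if index_col is None:
        n_unnamed = 0
        for c in head.columns:
            if str(c).startswith("Unnamed:") or c in ("subject", "hemisphere", "region"):
                n_unnamed += 1
            else:
                break
        index_col = list(range(n_unnamed)) if n_unnamed else None
    df = pd.read_csv(path, index_col=index_col)
    if df.columns.duplicated().any():
        raise ValueError("duplicate feature names in table")
    return df


def write_phantom_config(cfg: PhantomConfig, path: str | Path) -> None:
    d = asdict(cfg)
    d["grid_shape"] = list(d["grid_shape"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_phantom_config(path: str | Path) -> PhantomConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["grid_shape"] = tuple(d["grid_shape"])
    return PhantomConfig(**d)


def save_control_moments(moments: ControlMoments, path: str | Path) -> None:
    """Persist step-2 scaling for reuse at an independent validation site."""
    Path(path).write_text(json.dumps(moments.to_dict(), indent=1))


def load_control_moments(path: str | Path) -> ControlMoments:
    return ControlMoments.from_dict(json.loads(Path(path).read_text()))


def write_subject_nifti(subject: SubjectRecord, out_dir: str | Path) -> None:
    """Dump one subject's volumes, probability maps, atlas and lesion mask
    as NIfTI-1 files under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for mod, vol in subject.volumes.items():
        write_volume(vol, out / f"{subject.subject_id}_{mod}.nii.gz")
    write_volume(subject.gm_prob, out / f"{subject.subject_id}_gmprob.nii.gz")
    write_volume(subject.wm_prob, out / f"{subject.subject_id}_wmprob.nii.gz")
    write_volume(subject.atlas, out / f"{subject.subject_id}_atlas.nii.gz", dtype=np.int16)
    write_volume(subject.lesion_mask, out / f"{subject.subject_id}_lesion.nii.gz", dtype=np.uint8)


def write_morph_table(subject: SubjectRecord, path: str | Path) -> None:
    """Long-format morphology CSV: subject, hemisphere, region, feature, value."""
    long = subject.morph_table.stack().reset_index()
    long.columns = ["hemisphere", "region", "feature", "value"]
    long.insert(0, "subject", subject.subject_id)
    long.to_csv(path, index=False, float_format=_FLOAT_FMT)


def config_hash(cfg) -> str:
    """Stable short hash of a (nested-dataclass) configuration, for
    provenance lines in reports."""
    def default(o):
        if hasattr(o, "__dataclass_fields__"):
            return {f: getattr(o, f) for f in o.__dataclass_fields__}
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, (set, frozenset, tuple)):
            return sorted(map(str, o)) if isinstance(o, (set, frozenset)) else list(o)
        return str(o)

    blob = json.dumps(cfg, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
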