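"""Two-stage lesion detection: lateralize the affected frontal lobe, then
detect lesioned subregions on that lobe and score the merged prediction.

Stage 1 classifies every hemisphere's frontal lobe (label 1 = lesioned
lobe) with subject-stratified cross-validation, so the two hemispheres of
one subject never straddle a train/test split. Stage 2 trains one
classifier per frontal subregion (the paracentral parcel is excluded, as
it is never part of the modeled resections) on the affected lobe of each
patient and one seeded random lobe per control. At inference only the
stage-1-positive lobe's subregions are scored; positive subregions are
merged into one voxel set and compared with the ground-truth lesion by
Dice (with intersection-over-truth and Jaccard alongside). A one-stage
baseline (subregion detection on both lobes, no lateralization gate) is
available for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from fcdetect.asymmetry import (
    ControlMoments,
    PairedFeatureTable,
    _intra_subject_zscore,
    augment_with_asymmetry,
)
from fcdetect.detector import (
    Metrics,
    MLPConfig,
    SelectionConfig,
    evaluate,
    select_features,
    train_mlp,
    youden_threshold,
)
from fcdetect.phantom import (
    PARACENTRAL,
    CohortDataset,
    PhantomConfig,
    generate_cohort,
)
from fcdetect.radiomics.extract import FeatureSpec, extract_roi_feature_vector
from fcdetect.roi import ROIMask, build_roi
from fcdetect.volume import Volume

RADIOMIC_ROI_KINDS = ("gm", "wm", "gm_wm", "gwm")
FEATURE_SOURCES = RADIOMIC_ROI_KINDS + ("mf",)
FEATURE_MODES = ("original", "asymmetry")

#: the 10-group test design: 4 radiomic ROIs + morphology, each with and
#: without asymmetry features
TEST_DESIGN = tuple((src, mode) for src in FEATURE_SOURCES for mode in FEATURE_MODES)


@dataclass
class PipelineConfig:
    """End-to-end run configuration (phantom -> features -> both stages)."""

    n_patients: int = 37
    n_controls: int = 20
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    roi_kind: str = "gm_wm"
    feature_mode: str = "asymmetry"
    feature_spec: FeatureSpec = field(default_factory=FeatureSpec.fast)
    selection: SelectionConfig = field(default_factory=lambda: SelectionConfig(n_trees=200, threshold_grid_size=12, eval_trees=40))
    #: optional lighter search for the 10 per-subregion classifiers; None
    #: reuses ``selection``
    stage2_selection: SelectionConfig | None = None
    mlp: MLPConfig = field(default_factory=MLPConfig)
    cv_folds: int = 5
    min_overlap_fraction: float = 0.0
    normalization_axis: str = "features"
    one_stage_baseline: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.roi_kind not in FEATURE_SOURCES:
            raise ValueError(f"roi_kind must be one of {FEATURE_SOURCES}")
        if self.feature_mode not in FEATURE_MODES:
            raise ValueError(f"feature_mode must be one of {FEATURE_MODES}")


# ------------------------------------------------------------------ labels

def make_subregion_labels(
    lesion_mask: Volume,
    atlas: Volume,
    subregion_names: tuple[str, ...],
    min_overlap_fraction: float = 0.0,
) -> dict:
    """Stage labels from the ground-truth lesion.

    stage1: per-hemisphere 0/1; stage2: per (hemisphere, subregion) 0/1,
    positive iff the lesion covers more than ``min_overlap_fraction`` of
    the subregion (default: any shared voxel). The paracentral parcel is
    excluded from stage 2. Lesion voxels outside the atlas are flagged.
    """
    from fcdetect.phantom import RIGHT_OFFSET

    les = np.asarray(lesion_mask.data) > 0
    atl = np.asarray(atlas.data)
    if (les & (atl == 0)).any():
        warnings.warn("lesion voxels outside the atlas", stacklevel=2)
    stage2 = {}
    stage1 = {"left": 0, "right": 0}
    for hemi in ("left", "right"):
        off = 0 if hemi == "left" else RIGHT_OFFSET
        for idx, name in enumerate(subregion_names):
            region = atl == idx + 1 + off
            size = region.sum()
            overlap = (les & region).sum()
            hit = int(size > 0 and overlap > min_overlap_fraction * size)
            if name != PARACENTRAL:
                stage2[(hemi, name)] = hit
            if hit:
                stage1[hemi] = 1
    return {"stage1": stage1, "stage2": stage2}


def stage2_region_names(config: PhantomConfig) -> tuple[str, ...]:
    """Subregions carrying a stage-2 classifier (paracentral excluded)."""
    return tuple(n for n in config.subregion_names if n != PARACENTRAL)


# --------------------------------------------------------------- features

def _morph_vector(subject, hemisphere: str) -> pd.Series:
    block = subject.morph_table.xs(hemisphere, level="hemisphere")
    vec = {}
    for region, row in block.iterrows():
        for feat, val in row.items():
            vec[f"{region}__{feat}"] = float(val)
    return pd.Series(vec, dtype=float)


def frontal_feature_table(cohort: CohortDataset, roi_kind: str, spec: FeatureSpec) -> PairedFeatureTable:
    """Stage-1 features: one row per hemisphere per subject.

    Radiomic kinds extract from the frontal ROI (union of all subregions);
    ``mf`` flattens the per-region morphology table of that hemisphere.
    """
    rows: dict[tuple[str, str], pd.Series] = {}
    labels: dict[tuple[str, str], int] = {}
    for s in cohort:
        for hemi in ("left", "right"):
            if roi_kind == "mf":
                vec = _morph_vector(s, hemi)
            else:
                region = s.gm_prob.like(s.hemisphere_mask(hemi))
                roi = build_roi(s.gm_prob, s.wm_prob, region, roi_kind, "frontal", hemi)
                vec = extract_roi_feature_vector(s, roi, spec)
            rows[(s.subject_id, hemi)] = vec
            labels[(s.subject_id, hemi)] = int(s.lesion_side == hemi)
    feats = pd.DataFrame(rows).T
    feats.index = pd.MultiIndex.from_tuples(feats.index, names=["subject", "hemisphere"])
    lab = pd.Series(labels)
    lab.index = feats.index
    return PairedFeatureTable(features=feats, labels=lab)


def region_feature_tables(
    cohort: CohortDataset, roi_kind: str, spec: FeatureSpec
) -> dict[str, PairedFeatureTable]:
    """Stage-2 features: per subregion, one row per hemisphere per subject."""
    names = stage2_region_names(cohort.config)
    rows: dict[str, dict] = {n: {} for n in names}
    labels: dict[str, dict] = {n: {} for n in names}
    for s in cohort:
        lab = make_subregion_labels(s.lesion_mask, s.atlas, cohort.config.subregion_names)
        for hemi in ("left", "right"):
            for region in names:
                if roi_kind == "mf":
                    vec = s.morph_table.loc[(hemi, region)].astype(float)
                else:
                    rmask = s.gm_prob.like(s.region_mask(region, hemi, cohort.config.subregion_names))
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        roi = build_roi(s.gm_prob, s.wm_prob, rmask, roi_kind, region, hemi)
                        vec = extract_roi_feature_vector(s, roi, spec)
                rows[region][(s.subject_id, hemi)] = vec
                labels[region][(s.subject_id, hemi)] = lab["stage2"][(hemi, region)]
    out = {}
    for region in names:
        feats = pd.DataFrame(rows[region]).T
        feats.index = pd.MultiIndex.from_tuples(feats.index, names=["subject", "hemisphere"])
        feats = feats.fillna(0.0)  # empty-ROI rows carry no signal
        lab = pd.Series(labels[region])
        lab.index = feats.index
        out[region] = PairedFeatureTable(features=feats, labels=lab)
    return out


# ------------------------------------------------------------- CV plumbing

@dataclass
class _FoldModel:
    selected: list[str]
    moments: ControlMoments
    mlp: object
    threshold: float


def _prepare(table: PairedFeatureTable, mode: str, axis: str) -> pd.DataFrame:
    """Asymmetry augmentation followed by the intra-subject step; both are
    per-subject transforms, so they can run once outside the CV loop."""
    aug = augment_with_asymmetry(table, mode)
    return _intra_subject_zscore(aug, axis)


def _fit_fold(
    feats: pd.DataFrame,
    labels: pd.Series,
    control_ids: set,
    train_subjects: set,
    sel_cfg: SelectionConfig,
    mlp_cfg: MLPConfig,
) -> _FoldModel | None:
    subj = feats.index.get_level_values("subject")
    tr = subj.isin(train_subjects)
    ctl_tr = tr & subj.isin(control_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ctl = feats[ctl_tr]
        center = ctl.mean()
        scale = ctl.std(ddof=0).replace(0.0, 1.0)
    moments = ControlMoments(center=center, scale=scale)
    Xtr = moments.apply(feats[tr])
    ytr = labels[tr].to_numpy()
    if len(np.unique(ytr)) < 2:
        return None
    selected = select_features(Xtr.to_numpy(), ytr, sel_cfg, feature_names=list(Xtr.columns))
    mlp = train_mlp(Xtr[selected].to_numpy(), ytr, mlp_cfg)
    train_scores = mlp.decision_scores(Xtr[selected].to_numpy())
    thr = youden_threshold(ytr, train_scores)
    return _FoldModel(selected=selected, moments=moments, mlp=mlp, threshold=thr)


def _score(model: _FoldModel, feats: pd.DataFrame) -> np.ndarray:
    X = model.moments.apply(feats)[model.selected].to_numpy()
    return model.mlp.decision_scores(X)


def _subject_folds(cohort: CohortDataset, n_folds: int, seed: int) -> dict[str, int]:
    ids = [s.subject_id for s in cohort]
    y = [int(s.is_patient) for s in cohort]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    fold_of = {}
    for f, (_, test) in enumerate(skf.split(np.zeros(len(ids)), y)):
        for i in test:
            fold_of[ids[i]] = f
    return fold_of


# ----------------------------------------------------------------- stages

@dataclass
class Stage1Result:
    scores: pd.Series  # (subject, hemisphere) -> lesion score
    labels: pd.Series
    metrics: Metrics
    fold_of: dict[str, int]

    def predicted_lobe(self, subject_id: str) -> str:
        s = self.scores.loc[subject_id]
        return "left" if s["left"] >= s["right"] else "right"


def run_stage1(
    cohort: CohortDataset,
    feature_mode: str = "asymmetry",
    roi_kind: str = "gm_wm",
    spec: FeatureSpec | None = None,
    sel_cfg: SelectionConfig | None = None,
    mlp_cfg: MLPConfig | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    table: PairedFeatureTable | None = None,
    normalization_axis: str = "features",
) -> Stage1Result:
    """Lateralization: cross-validated per-hemisphere lesion scores.

    Folds are subject-stratified (a subject's two hemispheres share a
    fold). Pass ``table`` to reuse precomputed features.
    """
    spec = spec or FeatureSpec.fast()
    sel_cfg = sel_cfg or SelectionConfig(n_trees=200, threshold_grid_size=12, eval_trees=40)
    mlp_cfg = mlp_cfg or MLPConfig()
    if table is None:
        table = frontal_feature_table(cohort, roi_kind, spec)
    feats = _prepare(table, feature_mode, normalization_axis)
    labels = table.labels

    control_ids = {s.subject_id for s in cohort.controls}
    fold_of = _subject_folds(cohort, cv_folds, seed)
    ss = np.random.SeedSequence(seed)
    fold_seeds = np.random.default_rng(ss).integers(0, 2**31 - 1, size=cv_folds)

    scores = pd.Series(np.nan, index=feats.index)
    subj = feats.index.get_level_values("subject")
    for f in range(cv_folds):
        train_subjects = {sid for sid, ff in fold_of.items() if ff != f}
        test_mask = subj.isin({sid for sid, ff in fold_of.items() if ff == f})
        scfg = SelectionConfig(**{**asdict(sel_cfg), "seed": int(fold_seeds[f])})
        mcfg = MLPConfig(**{**asdict(mlp_cfg), "seed": int(fold_seeds[f])})
        model = _fit_fold(feats, labels, control_ids, train_subjects, scfg, mcfg)
        if model is None:
            warnings.warn(f"stage-1 fold {f}: single-class training labels, skipped", stacklevel=2)
            continue
        scores[test_mask] = _score(model, feats[test_mask])
    ok = scores.notna()
    metrics = evaluate(labels[ok].to_numpy(), scores[ok].to_numpy())
    return Stage1Result(scores=scores, labels=labels, metrics=metrics, fold_of=fold_of)


@dataclass
class Stage2Result:
    region_scores: dict[str, pd.Series]  # region -> per-subject oof score (stage-2 lobe)
    region_labels: dict[str, pd.Series]
    region_metrics: dict[str, Metrics]
    pooled_metrics: Metrics
    models: dict[tuple[str, int], _FoldModel]
    prepared: dict[str, pd.DataFrame]  # region -> prepared both-lobe feature rows
    fold_of: dict[str, int]
    sample_lobe: dict[str, str]

    @property
    def n_classifiers(self) -> int:
        return len(self.region_scores)

    def predict_regions(self, subject_id: str, lobe: str) -> list[tuple[str, str]]:
        """Positive subregions of one lobe, via the subject's fold models."""
        f = self.fold_of[subject_id]
        out = []
        for region, feats in self.prepared.items():
            model = self.models.get((region, f))
            if model is None:
                continue
            row = feats.loc[[(subject_id, lobe)]]
            if float(_score(model, row)[0]) >= model.threshold:
                out.append((lobe, region))
        return out


def run_stage2(
    cohort: CohortDataset,
    feature_mode: str = "asymmetry",
    roi_kind: str = "gm_wm",
    spec: FeatureSpec | None = None,
    sel_cfg: SelectionConfig | None = None,
    mlp_cfg: MLPConfig | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    tables: dict[str, PairedFeatureTable] | None = None,
    normalization_axis: str = "features",
) -> Stage2Result:
    """Subregion detection: one cross-validated classifier per subregion.

    Training samples are the affected lobe of each patient and one seeded
    lobe per control. Folds reuse a single subject-level split; a fold
    whose training labels are single-class is skipped with a warning.
    """
    spec = spec or FeatureSpec.fast()
    sel_cfg = sel_cfg or SelectionConfig(n_trees=200, threshold_grid_size=12, eval_trees=40)
    mlp_cfg = mlp_cfg or MLPConfig()
    if tables is None:
        tables = region_feature_tables(cohort, roi_kind, spec)

    sample_lobe = dict(cohort.subregion_stage_samples())
    control_ids = {s.subject_id for s in cohort.controls}
    fold_of = _subject_folds(cohort, cv_folds, seed + 1)
    ss = np.random.SeedSequence(seed + 1)
    fold_seeds = np.random.default_rng(ss).integers(0, 2**31 - 1, size=cv_folds)

    region_scores: dict[str, pd.Series] = {}
    region_labels: dict[str, pd.Series] = {}
    region_metrics: dict[str, Metrics] = {}
    models: dict[tuple[str, int], _FoldModel] = {}
    prepared: dict[str, pd.DataFrame] = {}

    for region, table in tables.items():
        feats = _prepare(table, feature_mode, normalization_axis)
        prepared[region] = feats
        # stage-2 sample rows: one lobe per subject
        sample_index = [(sid, lobe) for sid, lobe in sample_lobe.items()]
        sfeats = feats.loc[sample_index]
        slabels = table.labels.loc[sample_index]

        scores = pd.Series(np.nan, index=[sid for sid, _ in sample_index])
        for f in range(cv_folds):
            train_subjects = {sid for sid, ff in fold_of.items() if ff != f}
            scfg = SelectionConfig(**{**asdict(sel_cfg), "seed": int(fold_seeds[f])})
            mcfg = MLPConfig(**{**asdict(mlp_cfg), "seed": int(fold_seeds[f])})
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = _fit_fold(sfeats, slabels, control_ids, train_subjects, scfg, mcfg)
            if model is None:
                warnings.warn(f"stage-2 region {region} fold {f}: single-class training labels, skipped", stacklevel=2)
                continue
            models[(region, f)] = model
            test_ids = [sid for sid, ff in fold_of.items() if ff == f]
            rows = sfeats.loc[[(sid, sample_lobe[sid]) for sid in test_ids]]
            scores[test_ids] = _score(model, rows)

        lab = pd.Series({sid: int(l) for (sid, _), l in slabels.items()})
        region_scores[region] = scores
        region_labels[region] = lab
        ok = scores.notna()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            region_metrics[region] = evaluate(lab[ok].to_numpy(), scores[ok].to_numpy()) if ok.any() else Metrics(
                np.nan, np.nan, np.nan, np.nan, np.nan, 0.5, 0
            )

    all_lab = np.concatenate([region_labels[r][region_scores[r].notna()].to_numpy() for r in region_scores])
    all_sc = np.concatenate([region_scores[r][region_scores[r].notna()].to_numpy() for r in region_scores])
    pooled = evaluate(all_lab, all_sc)
    return Stage2Result(
        region_scores=region_scores,
        region_labels=region_labels,
        region_metrics=region_metrics,
        pooled_metrics=pooled,
        models=models,
        prepared=prepared,
        fold_of=fold_of,
        sample_lobe=sample_lobe,
    )


# ---------------------------------------------------------------- overlap

def merge_and_overlap(
    predicted_subregions: list[tuple[str, str]],
    lesion_mask: Volume,
    atlas: Volume,
    subregion_names: tuple[str, ...],
) -> dict[str, float]:
    """Merge predicted subregions into one voxel set and score the overlap
    with the ground-truth lesion.

    Returns Dice (2|P&T| / (|P|+|T|), the default), recall (|P&T|/|T|) and
    Jaccard (|P&T|/|PuT|). An empty prediction scores 0.
    """
    from fcdetect.phantom import RIGHT_OFFSET

    truth = np.asarray(lesion_mask.data) > 0
    if not truth.any():
        raise ValueError("subject has no ground-truth lesion")
    atl = np.asarray(atlas.data)
    pred = np.zeros_like(truth)
    for hemi, region in predicted_subregions:
        code = subregion_names.index(region) + 1 + (RIGHT_OFFSET if hemi == "right" else 0)
        pred |= atl == code
    inter = float((pred & truth).sum())
    p, t = float(pred.sum()), float(truth.sum())
    union = p + t - inter
    return {
        "dice": 2.0 * inter / (p + t) if p + t > 0 else 0.0,
        "recall": inter / t,
        "jaccard": inter / union if union > 0 else 0.0,
    }


# --------------------------------------------------------------- pipeline

@dataclass
class DetectionReport:
    """Full two-stage run: per-stage metrics, predictions and overlaps."""

    config: PipelineConfig
    stage1: Stage1Result
    stage2: Stage2Result
    predicted_subregions: dict[str, list[tuple[str, str]]]
    overlap: pd.DataFrame  # per-patient dice/recall/jaccard
    one_stage_overlap: pd.DataFrame | None = None

    @property
    def mean_overlap(self) -> dict[str, float]:
        return {k: float(self.overlap[k].mean()) for k in ("dice", "recall", "jaccard")}

    def to_dict(self) -> dict:
        d = {
            "roi_kind": self.config.roi_kind,
            "feature_mode": self.config.feature_mode,
            "seed": self.config.seed,
            "stage1": self.stage1.metrics.to_dict(),
            "stage2_pooled": self.stage2.pooled_metrics.to_dict(),
            "stage2_per_region": {r: m.to_dict() for r, m in self.stage2.region_metrics.items()},
            "mean_overlap": self.mean_overlap,
            "n_stage2_classifiers": self.stage2.n_classifiers,
        }
        if self.one_stage_overlap is not None:
            d["one_stage_mean_overlap"] = {
                k: float(self.one_stage_overlap[k].mean()) for k in ("dice", "recall", "jaccard")
            }
        return d


def run_pipeline(config: PipelineConfig, cohort: CohortDataset | None = None) -> DetectionReport:
    """Execute phantom -> ROIs -> features -> normalization -> stage 1 ->
    stage 2 -> merge/overlap, fully seeded."""
    if cohort is None:
        phantom_cfg = config.phantom
        cohort = generate_cohort(config.n_patients, config.n_controls, phantom_cfg, config.seed)

    s1 = run_stage1(
        cohort, config.feature_mode, config.roi_kind, config.feature_spec,
        config.selection, config.mlp, config.cv_folds, config.seed,
        normalization_axis=config.normalization_axis,
    )
    s2 = run_stage2(
        cohort, config.feature_mode, config.roi_kind, config.feature_spec,
        config.stage2_selection or config.selection, config.mlp, config.cv_folds, config.seed,
        normalization_axis=config.normalization_axis,
    )

    names = cohort.config.subregion_names
    predicted: dict[str, list[tuple[str, str]]] = {}
    rows = {}
    one_rows = {}
    for s in cohort:
        if s.is_patient:
            lobe = s1.predicted_lobe(s.subject_id)
            regions = s2.predict_regions(s.subject_id, lobe)
            predicted[s.subject_id] = regions
            rows[s.subject_id] = merge_and_overlap(regions, s.lesion_mask, s.atlas, names)
            if config.one_stage_baseline:
                both = s2.predict_regions(s.subject_id, "left") + s2.predict_regions(s.subject_id, "right")
                one_rows[s.subject_id] = merge_and_overlap(both, s.lesion_mask, s.atlas, names)
        else:
            # controls have no truth lesion; they contribute no overlap score
            predicted[s.subject_id] = s2.predict_regions(s.subject_id, s2.sample_lobe[s.subject_id])
    overlap = pd.DataFrame(rows).T if rows else pd.DataFrame(columns=["dice", "recall", "jaccard"])
    one_overlap = pd.DataFrame(one_rows).T if one_rows else None
    return DetectionReport(
        config=config,
        stage1=s1,
        stage2=s2,
        predicted_subregions=predicted,
        overlap=overlap,
        one_stage_overlap=one_overlap if config.one_stage_baseline else None,
    )


def sweep(config: PipelineConfig, cohort: CohortDataset | None = None) -> pd.DataFrame:
    """Run the full 10-group test design (4 radiomic ROIs + morphology,
    each with and without asymmetry) on one cohort; one report row per group."""
    if cohort is None:
        cohort = generate_cohort(config.n_patients, config.n_controls, config.phantom, config.seed)
    rows = []
    for src, mode in TEST_DESIGN:
        cfg = PipelineConfig(**{**asdict_shallow(config), "roi_kind": src, "feature_mode": mode})
        rep = run_pipeline(cfg, cohort=cohort)
        rows.append({
            "source": src,
            "mode": mode,
            "stage1_auc": rep.stage1.metrics.auc,
            "stage1_sensitivity": rep.stage1.metrics.sensitivity,
            "stage2_auc": rep.stage2.pooled_metrics.auc,
            "mean_dice": rep.mean_overlap["dice"],
        })
    return pd.DataFrame(rows)


def asdict_shallow(config: PipelineConfig) -> dict:
    """Shallow field dict of a PipelineConfig (sub-configs stay objects)."""
    return {f: getattr(config, f) for f in config.__dataclass_fields__}
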