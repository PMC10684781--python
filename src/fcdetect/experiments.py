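"""Reference study conditions: structural audits and seeded simulation
studies of the two-stage pipeline.

These functions define the package's standard desk-scale experiments:

* ``structural_counts`` - the auditable counts of the method (features per
  image, wavelet expansion, per-ROI total, sample-design sizes, number of
  stage-2 classifiers, test-design groups), computed by running the actual
  extraction and cohort assembly.
* ``stage1_auc_study`` - cross-validated lateralization AUC of phantom
  cohorts at a named lesion-effect level, averaged over seeds. The null
  preset calibrates the pipeline (chance AUC); the strong preset measures
  its power.
* ``mode_comparison_study`` - paired (same cohorts, same folds) comparison
  of asymmetry-mode vs original-mode stage-1 AUC at a moderate lateralized
  effect, where inter-subject anatomical variability dominates absolute
  feature values and asymmetry should win.
* ``overlap_comparison_study`` - paired comparison of the two-stage merged
  prediction overlap (Dice) against a one-stage baseline that scores both
  lobes without lateralization.

Cohort sizes (14 patients + 10 controls for AUC/overlap studies, 10 + 8
for the mode comparison) are chosen so each study resolves its effect while
a full multi-seed battery stays desk-scale; the phantom grid and effect
presets are the generator defaults.
"""

from __future__ import annotations

import warnings

import numpy as np

from fcdetect.detector import MLPConfig, SelectionConfig
from fcdetect.phantom import EFFECT_PRESETS, PhantomConfig, generate_cohort, generate_subject
from fcdetect.radiomics import (
    FeatureSpec,
    TEXTURE_NAMES,
    extract_roi_feature_vector,
    wavelet_subbands,
)
from fcdetect.roi import build_roi
from fcdetect.two_stage import (
    TEST_DESIGN,
    PipelineConfig,
    frontal_feature_table,
    run_pipeline,
    run_stage1,
    stage2_region_names,
)

#: stage-1 selection search used by all simulation studies
STUDY_SELECTION = SelectionConfig(n_trees=100, threshold_grid_size=6, eval_trees=25, cv_folds=3)
#: lighter search for the 10 per-subregion classifiers
STUDY_STAGE2_SELECTION = SelectionConfig(n_trees=60, threshold_grid_size=4, eval_trees=20, cv_folds=2)
STUDY_MLP = MLPConfig(epochs=150, patience=15)


def _study_seeds(base_seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(np.random.SeedSequence(base_seed))
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def structural_counts(seed: int = 0) -> dict[str, float]:
    """Recompute every auditable structural count of the method."""
    cfg = PhantomConfig(seed=seed)
    subject = generate_subject(cfg, is_patient=False, seed=seed)
    region = subject.gm_prob.like(subject.hemisphere_mask("left"))
    roi = build_roi(subject.gm_prob, subject.wm_prob, region, "gm_wm", "frontal", "left")
    vec = extract_roi_feature_vector(subject, roi, FeatureSpec.full())

    def n_with(prefix: str) -> int:
        return int(sum(1 for name in vec.index if name.startswith(prefix)))

    t1_original = n_with("T1_original_")
    shape = n_with("mask_original_shape_")
    wavelet_feats = n_with("T1_wavelet-")
    bands = wavelet_subbands(subject.volumes["T1"])

    family_counts = {fam: len(names) for fam, names in TEXTURE_NAMES.items()}

    # small grids suffice for the sample-design arithmetic
    design_cohort = generate_cohort(37, 20, PhantomConfig(grid_shape=(8, 8, 8), seed=seed), seed=seed)

    return {
        "features_per_original_image": float(t1_original + shape),
        "wavelet_features": float(wavelet_feats),
        "features_per_roi_total": float(len(vec)),
        "wavelet_subbands": float(len(bands)),
        "glcm_features": float(family_counts["glcm"]),
        "glrlm_features": float(family_counts["glrlm"]),
        "glszm_features": float(family_counts["glszm"]),
        "ngtdm_features": float(family_counts["ngtdm"]),
        "gldm_features": float(family_counts["gldm"]),
        "stage1_samples_37p_20c": float(len(design_cohort.hemisphere_samples())),
        "stage2_samples_37p_20c": float(len(design_cohort.subregion_stage_samples())),
        "stage2_classifiers": float(len(stage2_region_names(cfg))),
        "test_design_groups": float(len(TEST_DESIGN)),
    }


def stage1_auc_study(
    effect: str,
    n_seeds: int = 10,
    n_patients: int = 14,
    n_controls: int = 10,
    base_seed: int = 0,
) -> dict:
    """Mean cross-validated stage-1 AUC (GM&WM asymmetry features) of
    seeded phantom cohorts at one lesion-effect preset."""
    aucs = []
    for seed in _study_seeds(base_seed, n_seeds):
        ph = PhantomConfig(seed=seed, lesion_effect=dict(EFFECT_PRESETS[effect]))
        cohort = generate_cohort(n_patients, n_controls, ph, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_stage1(
                cohort, "asymmetry", "gm_wm",
                sel_cfg=STUDY_SELECTION, mlp_cfg=STUDY_MLP, cv_folds=5, seed=seed,
            )
        aucs.append(res.metrics.auc)
    return {"mean_auc": float(np.mean(aucs)), "aucs": aucs, "n": n_seeds * 2 * (n_patients + n_controls)}


def mode_comparison_study(
    n_seeds: int = 8,
    n_patients: int = 10,
    n_controls: int = 8,
    effect: str = "moderate",
    base_seed: int = 0,
) -> dict:
    """Paired asymmetry-vs-original stage-1 AUC on shared cohorts."""
    asym, orig = [], []
    for seed in _study_seeds(base_seed, n_seeds):
        ph = PhantomConfig(seed=seed, lesion_effect=dict(EFFECT_PRESETS[effect]))
        cohort = generate_cohort(n_patients, n_controls, ph, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = frontal_feature_table(cohort, "gm_wm", FeatureSpec.fast())
            kw = dict(sel_cfg=STUDY_SELECTION, mlp_cfg=STUDY_MLP, cv_folds=5, seed=seed, table=table)
            asym.append(run_stage1(cohort, "asymmetry", "gm_wm", **kw).metrics.auc)
            orig.append(run_stage1(cohort, "original", "gm_wm", **kw).metrics.auc)
    return {
        "mean_auc_asymmetry": float(np.mean(asym)),
        "mean_auc_original": float(np.mean(orig)),
        "mean_paired_difference": float(np.mean(np.array(asym) - np.array(orig))),
        "n": n_seeds * 2 * (n_patients + n_controls),
    }


def overlap_comparison_study(
    n_seeds: int = 10,
    n_patients: int = 14,
    n_controls: int = 10,
    effect: str = "strong",
    base_seed: int = 0,
) -> dict:
    """Paired two-stage vs one-stage merged-prediction Dice on shared
    strong-effect cohorts."""
    two, one, s1auc = [], [], []
    for seed in _study_seeds(base_seed, n_seeds):
        cfg = PipelineConfig(
            n_patients=n_patients,
            n_controls=n_controls,
            phantom=PhantomConfig(seed=seed, lesion_effect=dict(EFFECT_PRESETS[effect])),
            selection=STUDY_SELECTION,
            stage2_selection=STUDY_STAGE2_SELECTION,
            mlp=STUDY_MLP,
            cv_folds=5,
            one_stage_baseline=True,
            seed=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = run_pipeline(cfg)
        two.append(rep.mean_overlap["dice"])
        one.append(float(rep.one_stage_overlap["dice"].mean()))
        s1auc.append(rep.stage1.metrics.auc)
    return {
        "mean_dice_two_stage": float(np.mean(two)),
        "mean_dice_one_stage": float(np.mean(one)),
        "mean_stage1_auc": float(np.mean(s1auc)),
        "n": n_seeds * n_patients,
    }
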