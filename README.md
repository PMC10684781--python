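# fcdetect

Two-stage, asymmetry-driven detection of focal cortical dysplasia (FCD)
in frontal lobe epilepsy from multimodal 3D volumes (T1, FLAIR, PET), with
a synthetic phantom cohort so the whole pipeline runs and validates
offline, end to end, with known ground truth.

FCD is the leading cause of surgically treatable pediatric epilepsy, and
its radiological signature — cortical thickening, blurring of the
gray-white boundary, FLAIR hyperintensity, PET hypometabolism — is often
subtle and easily missed. This package is for researchers in radiomics and
epilepsy imaging who want a fully testable reference implementation of the
two-stage detection design: first decide *which* frontal lobe harbors the
lesion, then decide *which subregions* of that lobe are involved, and
score the merged prediction against the ground-truth lesion.

## The method

1. **ROIs.** Per hemisphere and per Desikan-Killiany frontal subregion,
   four radiomics ROIs are built from tissue probability maps: gray matter
   (GM), white matter (WM), their union (GM&WM), and the gray-white
   boundary band (GWM); the frontal lobe is the union of its subregions.
2. **Features.** Per ROI, 1,037 radiomic features: 93 intensity features
   (18 first-order + 24 GLCM + 16 GLRLM + 16 GLSZM + 5 NGTDM + 14 GLDM)
   for each of the original T1, its 8 stationary-wavelet sub-bands
   (LLL … HHH), the original FLAIR and PET, plus 14 shape descriptors
   computed once from the mask (107 per original image). A 10-feature
   per-region morphological table (thickness, GWM contrast, curvature, …)
   is the non-radiomic alternative.
3. **Asymmetry.** For every feature, `asymmetry = 2(f_left − f_right) /
   (f_left + f_right)`, signed + for the left and − for the right sample —
   scale-invariant and bounded in [−2, 2], canceling the large
   inter-subject anatomical variability of a pediatric cohort.
4. **Normalization, selection, classification.** Intra-subject z-scoring
   followed by control-pool z-scoring; random-forest importance selection
   with a CV-tuned threshold; an MLP (hidden layers 40 and 10, two softmax
   outputs, dropout 0.4 on the input layer, Adam, cross-entropy).
   Metrics: accuracy, balanced accuracy, sensitivity, specificity, AUC at
   the Youden-optimal threshold.
5. **Two stages.** Stage 1 lateralizes the affected lobe from frontal-ROI
   features (subject-stratified cross-validation). Stage 2 trains one
   classifier per subregion (10; paracentral excluded) on affected lobes
   and scores only the stage-1-positive lobe; positive subregions are
   merged and compared with the lesion by Dice / recall / Jaccard.

The phantom generates mirrored-hemisphere subjects with a logistic-ramp
gray/white interface, 11 atlas sectors per side, and lateralized lesions
with configurable intensity shift, texture perturbation, boundary blurring
and cortical thickening — all seeded and bit-reproducible. See
`docs/methods.md` for the full model description and design rationale.

## Worked example

```python
from fcdetect.phantom import PhantomConfig
from fcdetect.two_stage import PipelineConfig, run_pipeline
from fcdetect.experiments import STUDY_SELECTION, STUDY_STAGE2_SELECTION, STUDY_MLP

cfg = PipelineConfig(
    n_patients=14, n_controls=10,
    phantom=PhantomConfig(seed=42),          # strong lesion effect by default
    selection=STUDY_SELECTION, stage2_selection=STUDY_STAGE2_SELECTION,
    mlp=STUDY_MLP, cv_folds=5, seed=42,
)
report = run_pipeline(cfg)
print(f"stage-1 AUC: {report.stage1.metrics.auc:.3f}  sensitivity: {report.stage1.metrics.sensitivity:.3f}")
print(f"stage-2 pooled AUC: {report.stage2.pooled_metrics.auc:.3f}  classifiers: {report.stage2.n_classifiers}")
print(f"mean overlap: dice {report.mean_overlap['dice']:.3f}  recall {report.mean_overlap['recall']:.3f}")
```

prints

```
stage-1 AUC: 0.811  sensitivity: 0.786
stage-2 pooled AUC: 0.550  classifiers: 10
mean overlap: dice 0.294  recall 0.392
```

Stage 1 lateralizes most of the 14 patients' lesions on this 24-subject
cohort (AUC 0.811 over 48 hemisphere samples); the ten stage-2 subregion
classifiers are weaker at this cohort size (each sees only a couple of
positive examples), yet the merged prediction still recovers on average
29% of the lesion extent by Dice and 39% by recall. Larger cohorts and
stronger lesion effects push stage-1 AUC toward 1 (see the reference
studies in `fcdetect.experiments`).

A CLI covers the same ground from a shell:

```bash
fcdetect simulate --n-patients 2 --n-controls 1 --seed 1 --out cohort/   # NIfTI + CSV
fcdetect extract  --roi gm_wm --full --out features.csv
fcdetect run-all  --roi gm_wm --mode asymmetry --n-patients 14 --n-controls 10
fcdetect sweep    --n-patients 14 --n-controls 10                        # all 10 test groups
```

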