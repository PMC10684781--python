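# Methods

`fcdetect` implements a two-stage, asymmetry-driven pipeline for localizing
focal cortical dysplasia (FCD) in frontal lobe epilepsy from multimodal 3D
volumes, together with a synthetic phantom cohort that supplies ground
truth for every stage. This note records the models, the parameters that
matter, the numerical choices, and what the phantom does and does not show
about real data.

## The detection model

**Stage 1 — lateralization.** Every subject contributes two samples, one
per frontal lobe (label 1 = lesioned lobe, 0 = healthy). Features are
extracted from a frontal ROI of one of four kinds — gray matter (GM),
white matter (WM), their union (GM&WM), or the gray-white boundary band
(GWM) — or taken from a per-region morphological table (MF). A
cross-validated classifier scores each lobe; the higher-scoring lobe of a
patient is the predicted affected side.

**Stage 2 — subregion detection.** One classifier per frontal subregion
(10 of the 11 Desikan-Killiany frontal parcels; paracentral is excluded
because the modeled resections never involve it) is trained on the
affected lobe of each patient and one seeded random lobe per control
(sample label: does the lesion overlap that subregion). At inference only
the stage-1-positive lobe's subregions are scored; positive subregions are
merged into one voxel set P and compared with the ground-truth lesion T by
Dice 2|P∩T|/(|P|+|T|) (default), with intersection-over-truth |P∩T|/|T|
and Jaccard |P∩T|/|P∪T| reported alongside. The overlap metric itself is a
design choice — no single canonical one exists for merged-parcel
predictions — and reporting all three keeps results auditable. A one-stage
baseline (both lobes scored, no gate) exists for comparison.

**Asymmetry features.** For a feature f measured on both hemispheres,

    asymmetry = 2 (f_left − f_right) / (f_left + f_right),

attached with sign +/− to the left/right sample respectively. It is
antisymmetric, invariant to positive rescaling of both sides, bounded in
[−2, 2] for non-negative inputs, and defined as 0 when f_left + f_right = 0
(no lateralization either way; flagged). "Asymmetry mode" appends the
signed asymmetry of every feature to the raw per-hemisphere features,
doubling the feature count; asymmetry is computed on raw features, before
normalization.

## Radiomic features

Per ROI the canonical vector is 1,037 features: 93 intensity-derived
features (18 first-order, 24 GLCM, 16 GLRLM, 16 GLSZM, 5 NGTDM, 14 GLDM)
for each of 11 images — the original T1, its 8 first-level wavelet
sub-bands, the original FLAIR and PET — plus 14 shape descriptors computed
once from the mask. Shape is a property of the mask alone, so it is never
repeated per modality; this is what makes the totals 93 + 14 = 107 per
original image and 93 × 11 + 14 = 1,037 per ROI. Feature names carry full
provenance tags (`<modality>_<image>_<family>_<feature>`) so every count
is auditable from the manifest.

Numerical choices:

* **Discretization** — equal-width binning of the ROI intensity range,
  default 32 levels (configurable); ROI minimum maps to level 1. Texture
  features are therefore invariant to adding a constant to the image.
* **Texture matrices** — GLCM: symmetric co-occurrence over the 13 unique
  distance-1 offsets of the 26-neighborhood, features averaged over
  offsets. GLRLM: run lengths along the same 13 directions, averaged.
  GLSZM: 26-connected iso-level zones. NGTDM/GLDM: 26-neighborhoods; GLDM
  dependence = 1 + number of neighbors with an identical level (α = 0).
  Degenerate ROIs (single voxel / single level) follow the limiting
  conventions: undefined ratios are 0, single-level normalizers take their
  boundary value; all outputs stay finite.
* **Wavelets** — single-level stationary (undecimated) 3D transform,
  coiflet-1 kernel, symmetric padding; all 8 sub-bands stay at input
  resolution so one mask serves all of them. The inverse transform
  reproduces the input to machine precision (tested).
* **Shape** — marching-cubes mesh for surface area and mesh volume; PCA of
  the voxel point cloud for axis lengths; convex-hull-accelerated maximum
  diameters. Voxelized surfaces carry a staircase bias, so sphericity of a
  digital ball plateaus near ~0.9 rather than 1.

## ROIs

GM and WM masks binarize the tissue probability maps at 0.5 (configurable);
GM&WM is their union. The GWM boundary ROI keeps voxels that are
near-certain GM (p ≥ 1 − ε, ε = 1e−6; literal float equality with 1.0
selects almost nothing on a smooth ramp) or partial-volume WM
(0 < p < 1 − ε), restricted to a 2 mm band around the GM/WM interface and
to the GM|WM tissue union. Without the band restriction the threshold rule
alone would sweep in every pure-GM voxel and the "boundary" ROI would not
be a boundary; the tissue-union restriction keeps GWM ⊆ GM&WM.
Hemispheres are always defined by atlas labels, never a midline plane.

## Normalization

Two steps. **Step 1, intra-subject:** each sample's raw feature vector is
z-scored across features (row-wise), removing subject-global scale; the
same transform is applied to control samples. Asymmetry-index columns pass
through untouched: the index is already an intra-subject, dimensionless
quantity, and folding it into the row statistics re-injects exactly the
subject-global anatomical variability the step exists to remove (this
measurably erases the asymmetry advantage). **Step 2:** every feature is
re-scaled by the control-pool mean/SD computed from step-1 controls —
inside cross-validation, from training-fold controls only — so controls
end up mean 0 / SD 1 per feature and patients are expressed in control-SD
units. Zero control SD falls back to scale 1 with a warning. The moments
are serializable so an independent validation site can replay the exact
scaling.

The axis of the intra-subject step is genuinely open; the alternative
("samples": per feature across a subject's two hemispheres) is available
via configuration but is not the default because with two samples it
collapses every feature to a ±1 sign, discarding magnitude and, when
controls are pooled instead, introducing a class-detectable distribution
artifact that inflates chance-level AUC.

## Feature selection and classifier

A random forest ranks features by impurity importance; candidate
thresholds span 0 to the maximum importance (50 even steps by default) and
are scored by k-fold CV balanced accuracy of a lighter forest, evaluating
each distinct feature subset once; the best subset wins, ties toward the
smaller subset, and the selection never returns an empty set. The
classifier is an MLP with hidden layers of 40 and 10 ReLU units, two
softmax outputs, and dropout 0.4 on the input layer, trained full-batch
with Adam (lr 1e−3) on the cross-entropy loss, up to 200 epochs with early
stopping (patience 20) on a held-out fifth of the training fold. The
input-dropout layer is part of the specified architecture, so the network
is implemented directly on numpy arrays; it is deterministic given its
seed. Metrics: AUC as a rank statistic (midrank ties); hard predictions at
the Youden cut (maximizing sensitivity + specificity, lowest cut on ties);
balanced accuracy = (sensitivity + specificity)/2. Cross-validation folds
are subject-stratified so the two hemispheres of one subject never
straddle a train/test split.

## The phantom

Each subject is two mirrored hemisphere blocks: a ball-like WM core
(radius 18 mm) under a GM ribbon (thickness 5 mm), with tissue probability
maps built from the radial distance through a logistic ramp (width 1.5 mm)
— so the GM/WM interface has a realistic partial-volume profile and the
GWM ROI rule has something to find. Eleven angular sectors per hemisphere
stand in for the Desikan-Killiany frontal parcels. Default grid 32×36×36
voxels at 2 mm isotropic.

Intensities per modality are mixtures of nominal tissue levels
(T1: WM 100 > GM 70; FLAIR: GM 80 > WM 60; PET: GM 90 >> WM 30) plus
additive Gaussian scanner noise (sd 2–3). Subject-level anatomy jitter
(radius and thickness, sd 10%) is shared by both hemispheres — the modeled
cohort is pediatric with a wide developmental age range, so inter-subject
anatomical variability is large; this is precisely the nuisance that
absolute features must fight and asymmetry features cancel. A small
independent left/right jitter (sd 2%) models normal hemispheric asymmetry;
setting it to 0 gives an exactly mirrored brain (used by symmetry tests).

Patients carry a lesion in 1–2 adjacent non-paracentral subregions of one
hemisphere, confined to the cortical band. The lesion effect has three
components, all ≥ 0 and all zero for the null preset: `intensity_shift`
(fraction of the GM/WM contrast; T1 darkens, FLAIR brightens, PET shows
hypometabolism), `texture_amplitude` (local intensity-variance increase;
also widens the logistic ramp, i.e. gray-white boundary blurring), and
`thickness_increase` (fractional cortical thickening). Presets: null
(0/0/0), moderate (0.12/0.15/0.10), strong (0.50/0.50/0.30) — chosen as
small-but-detectable vs radiologically obvious fractions of tissue
contrast. The morphological table draws 10 per-region features (cortical
thickness, GWM intensity contrast, curvature, sulcal depth, local cortical
deformation, FLAIR intensity, doughnut maps, PET SUVR, GM/WM volume) from
Gaussians with per-subject offsets; lesioned regions are shifted in the
clinically expected direction. All randomness flows from one seed through
named child streams, so a patient with an all-zero effect is bit-identical
to the control from the same seed — the basis of the null calibration.

**What the phantom does not emulate:** MR physics (bias fields, partial
Fourier, motion), registration error, gyrification (sectors are convex
slabs, unlike real parcels), multi-site effects, and pathology in
controls (the clinical control group had temporal-lobe epilepsy; phantom
controls are clean, though extra-frontal abnormality could be added via
configuration). Passing tests therefore demonstrate the pipeline's
correctness and its statistical behavior under known effects — not
clinical-grade performance on real scans.

## Study conditions

The reference experiments (`fcdetect.experiments`) use desk-scale problem
sizes chosen so each study resolves its effect within minutes on one CPU:
AUC calibration/power studies use 10 seeded cohorts of 14 patients + 10
controls with 5-fold CV; the asymmetry-vs-original comparison uses 8
paired cohorts of 10 + 8 at the moderate effect; the two-stage vs
one-stage overlap comparison uses 10 paired cohorts of 14 + 10 at the
strong effect. Simulation studies restrict extraction to first-order
features of the three original images (the `fast` feature spec): at
phantom resolution the texture and wavelet channels add cost but little
discriminative signal, while the full 1,037-feature extraction is
exercised by the structural audits. The per-subregion classifiers use a
lighter selection search than the single stage-1 classifier, since the
selection CV dominates runtime and the asymmetry signal needs little
tuning.

## Known limitations

* Texture feature values depend on the discretization bin count; only the
  32-level default is exercised end to end.
* The GWM band width (2 mm) is a reconstruction of the intended boundary
  ribbon, not a published parameter.
* With very small cohorts some subregions have single-class training folds;
  those folds are skipped with a warning and their samples carry no
  out-of-fold score.
* Stage-2 sensitivity is limited by the few positive samples per subregion
  at desk-scale cohort sizes; absolute Dice values are accordingly modest
  and only the paired two-stage/one-stage contrast is interpreted.
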