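"""Synthetic multimodal phantom subjects with known lateralized cortical lesions.

Each phantom subject is a pair of mirrored hemisphere blocks. A hemisphere
is a ball-like white-matter core wrapped in a gray-matter ribbon; tissue
probability maps follow a logistic ramp in the signed distance to the
gray/white interface, so the gray-white boundary (GWM) has a realistic
partial-volume profile. Eleven angular sectors per hemisphere play the role
of the Desikan-Killiany frontal subregions. Patients carry a lesion confined
to one or two adjacent subregions on exactly one side; the lesion shifts
T1/FLAIR/PET intensities, adds local texture noise, thickens the cortex and
widens the gray-white ramp (boundary blurring) - the canonical radiological
traits of focal cortical dysplasia. A morphological feature table
(thickness, contrast, curvature, ...) is drawn per region from Gaussians
with configured lesion shifts; no surfaces are reconstructed.

All randomness flows from a single seed through named child streams
(anatomy, lesion geometry, lesion texture, scanner noise, morphology), so a
patient generated with an all-zero lesion effect is bit-identical to the
control generated from the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from fcdetect.volume import Volume

# Desikan-Killiany frontal parcels, one per angular sector.
FRONTAL_SUBREGIONS: tuple[str, ...] = (
    "caudalmiddlefrontal",
    "frontalpole",
    "lateralorbitofrontal",
    "medialorbitofrontal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "precentral",
    "rostralmiddlefrontal",
    "superiorfrontal",
)
PARACENTRAL = "paracentral"

# Right-hemisphere atlas codes are left code + this offset.
RIGHT_OFFSET = 100

# Nominal tissue intensities per modality: (background, gray, white).
MODALITY_LEVELS: dict[str, tuple[float, float, float]] = {
    "T1": (30.0, 70.0, 100.0),
    "FLAIR": (10.0, 80.0, 60.0),
    "PET": (5.0, 90.0, 30.0),
}

# Direction of the lesion intensity change, in units of |gray - white|
# contrast: T1 darkens (white matter turns gray-like), FLAIR brightens,
# PET shows hypometabolism.
LESION_INTENSITY_SIGN = {"T1": -1.0, "FLAIR": +1.0, "PET": -1.0}

# Morphological features: (base, between-subject sd, within-region sd,
# lesion direction). Units: thickness/sulcal depth mm, volumes cm^3,
# intensities arbitrary scanner units, the rest dimensionless.
MORPH_FEATURES: dict[str, tuple[float, float, float, float]] = {
    "cortical_thickness": (2.5, 0.15, 0.10, +1.0),
    "gwm_intensity_contrast": (0.30, 0.03, 0.02, -1.0),
    "mean_curvature": (0.12, 0.012, 0.008, +1.0),
    "sulcal_depth": (5.0, 0.4, 0.3, +1.0),
    "local_cortical_deformation": (0.50, 0.05, 0.04, +1.0),
    "flair_intensity": (80.0, 5.0, 3.0, +1.0),
    "doughnut_map": (0.40, 0.04, 0.03, +1.0),
    "pet_suvr": (1.20, 0.10, 0.06, -1.0),
    "gm_volume": (10.0, 0.8, 0.5, +1.0),
    "wm_volume": (12.0, 1.0, 0.6, -1.0),
}
MORPH_FEATURE_NAMES = tuple(MORPH_FEATURES)

# Named lesion-effect presets, as fractions of tissue contrast (intensity
# shift, texture amplitude) or of cortical thickness (thickness increase).
EFFECT_PRESETS: dict[str, dict[str, float]] = {
    "null": {"intensity_shift": 0.0, "texture_amplitude": 0.0, "thickness_increase": 0.0},
    "moderate": {"intensity_shift": 0.12, "texture_amplitude": 0.15, "thickness_increase": 0.10},
    "strong": {"intensity_shift": 0.50, "texture_amplitude": 0.50, "thickness_increase": 0.30},
}


@dataclass
class PhantomConfig:
    """Geometry, contrast and effect parameters of the phantom cohort.

    grid_shape : voxels per axis; the first axis is split into the two
        hemisphere blocks, so it must be even.
    voxel_size_mm : isotropic spacing.
    lesion_effect : dict with keys ``intensity_shift`` (fraction of the
        gray/white contrast), ``texture_amplitude`` (local noise, fraction
        of contrast; also widens the gray-white ramp), and
        ``thickness_increase`` (fractional cortical thickening). All >= 0;
        all zero means no lesion effect at all.
    noise_sd : additive scanner-noise sd per modality (intensity units).
    hemisphere_asym_sd : relative sd of independent left/right anatomy
        jitter (radius and thickness). 0 gives an exactly mirrored brain.
    """

    grid_shape: tuple[int, int, int] = (32, 36, 36)
    voxel_size_mm: float = 2.0
    n_subregions_per_hemisphere: int = 11
    lesion_effect: dict[str, float] = field(default_factory=lambda: dict(EFFECT_PRESETS["strong"]))
    noise_sd: dict[str, float] = field(default_factory=lambda: {"T1": 2.0, "FLAIR": 2.0, "PET": 3.0})
    seed: int = 0
    # anatomy
    wm_core_radius_mm: float = 18.0
    cortical_thickness_mm: float = 5.0
    ramp_width_mm: float = 1.5
    subject_jitter_sd: float = 0.10
    hemisphere_asym_sd: float = 0.02
    lesion_max_subregions: int = 2

    def __post_init__(self) -> None:
        if any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if self.grid_shape[0] % 2 != 0:
            raise ValueError("grid_shape[0] must be even (two hemisphere blocks)")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.n_subregions_per_hemisphere < 2:
            raise ValueError("need at least 2 subregions")
        if any(v < 0 for v in self.lesion_effect.values()):
            raise ValueError("lesion_effect components must be >= 0")

    @property
    def subregion_names(self) -> tuple[str, ...]:
        n = self.n_subregions_per_hemisphere
        if n == len(FRONTAL_SUBREGIONS):
            return FRONTAL_SUBREGIONS
        return tuple(f"subregion{i + 1:02d}" for i in range(n))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return aff


@dataclass
class SubjectRecord:
    """One phantom subject: volumes, tissue maps, atlas, truth and morphology."""

    subject_id: str
    volumes: dict[str, Volume]
    gm_prob: Volume
    wm_prob: Volume
    atlas: Volume
    lesion_mask: Volume
    morph_table: pd.DataFrame  # index (hemisphere, region), columns = morphology features
    is_patient: bool
    lesion_side: str  # "left" | "right" | "none"
    lesion_subregions: frozenset[str]

    def region_mask(self, region: str, hemisphere: str, names: tuple[str, ...]) -> np.ndarray:
        """Binary voxel mask of one subregion on one side."""
        code = names.index(region) + 1
        if hemisphere == "right":
            code += RIGHT_OFFSET
        return self.atlas.data == code

    def hemisphere_mask(self, hemisphere: str) -> np.ndarray:
        a = self.atlas.data
        if hemisphere == "left":
            return (a > 0) & (a <= RIGHT_OFFSET)
        return a > RIGHT_OFFSET


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _half_grid_geometry(cfg: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Radial distance (mm) from the hemisphere centre and angular sector
    index on the left half-grid."""
    hx = cfg.grid_shape[0] // 2
    ny, nz = cfg.grid_shape[1], cfg.grid_shape[2]
    ii, jj, kk = np.meshgrid(np.arange(hx), np.arange(ny), np.arange(nz), indexing="ij")
    c = np.array([(hx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0])
    d = (np.stack([ii, jj, kk], axis=-1) - c) * cfg.voxel_size_mm
    r = np.sqrt((d**2).sum(axis=-1))
    phi = np.arctan2(d[..., 2], d[..., 1])  # angle in the coronal-ish plane
    n = cfg.n_subregions_per_hemisphere
    sector = np.floor((phi + np.pi) / (2 * np.pi) * n).astype(int)
    sector = np.clip(sector, 0, n - 1)
    return r, sector


def _tissue_probs(r: np.ndarray, r0: float, thickness: float, width: float) -> tuple[np.ndarray, np.ndarray]:
    wm = _sigmoid((r0 - r) / width)
    brain = _sigmoid((r0 + thickness - r) / width)
    return brain - wm, wm


def _choose_lesion(rng: np.random.Generator, cfg: PhantomConfig) -> tuple[str, list[int]]:
    """Pick a side and 1..lesion_max_subregions adjacent sectors avoiding the
    paracentral parcel (never resected in the modeled surgical cohorts)."""
    names = cfg.subregion_names
    side = "left" if rng.random() < 0.5 else "right"
    n = cfg.n_subregions_per_hemisphere
    k = int(rng.integers(1, cfg.lesion_max_subregions + 1))
    excluded = {names.index(PARACENTRAL)} if PARACENTRAL in names else set()
    candidates = [
        s for s in range(n)
        if not ({(s + j) % n for j in range(k)} & excluded)
    ]
    start = int(rng.choice(candidates))
    return side, [(start + j) % n for j in range(k)]


def generate_subject(config: PhantomConfig, is_patient: bool, seed: int) -> SubjectRecord:
    """Generate one phantom subject, deterministically for a fixed seed.

    Patients receive a lesion in >= 1 subregion on exactly one hemisphere;
    controls carry no lesion anywhere. With an all-zero ``lesion_effect`` a
    patient is bit-identical to the control drawn from the same seed.
    """
    ss = np.random.SeedSequence(seed)
    rng_anat, rng_lesion, rng_tex, rng_noise, rng_morph = (np.random.default_rng(s) for s in ss.spawn(5))
    names = config.subregion_names

    r, sector = _half_grid_geometry(config)

    # subject-level anatomy jitter, shared by both hemispheres
    jit = 1.0 + config.subject_jitter_sd * rng_anat.standard_normal(2)
    r0, thick = config.wm_core_radius_mm * jit[0], config.cortical_thickness_mm * jit[1]
    # small independent left/right jitter (normal anatomical asymmetry)
    asym = 1.0 + config.hemisphere_asym_sd * rng_anat.standard_normal((2, 2))

    side, lesion_sectors = _choose_lesion(rng_lesion, config)
    if not is_patient:
        side, lesion_sectors = "none", []

    eff = config.lesion_effect
    widened = config.ramp_width_mm * (1.0 + eff.get("texture_amplitude", 0.0))
    thickened = 1.0 + eff.get("thickness_increase", 0.0)

    halves: dict[str, dict[str, np.ndarray]] = {}
    for h_idx, hemi in enumerate(("left", "right")):
        gm, wm = _tissue_probs(r, r0 * asym[h_idx, 0], thick * asym[h_idx, 1], config.ramp_width_mm)
        brain = gm + wm
        atlas_half = np.where(brain > 0.5, sector + 1, 0)

        lesion = np.zeros(r.shape, dtype=bool)
        if hemi == side and lesion_sectors:
            in_sectors = np.isin(sector, lesion_sectors)
            band = r >= (r0 * asym[h_idx, 0] - 2.0 * config.voxel_size_mm)
            lesion = in_sectors & band & (atlas_half > 0)
            # blurred, thickened cortex inside the lesion
            gm_l, wm_l = _tissue_probs(r, r0 * asym[h_idx, 0], thick * asym[h_idx, 1] * thickened, widened)
            gm = np.where(lesion, gm_l, gm)
            wm = np.where(lesion, wm_l, wm)
        halves[hemi] = {"gm": gm, "wm": wm, "atlas": atlas_half, "lesion": lesion}

    def assemble(key: str, right_offset: float = 0.0) -> np.ndarray:
        left = halves["left"][key]
        right = halves["right"][key][::-1, :, :]  # mirror across the midline
        if right_offset:
            right = np.where(right > 0, right + right_offset, right)
        return np.concatenate([left, right], axis=0)

    gm_prob = assemble("gm")
    wm_prob = assemble("wm")
    atlas = assemble("atlas", right_offset=RIGHT_OFFSET).astype(np.int16)
    lesion_mask = assemble("lesion").astype(bool)

    volumes: dict[str, Volume] = {}
    aff = config.affine
    for mod, (bg, g, w) in MODALITY_LEVELS.items():
        img = bg + (g - bg) * gm_prob + (w - bg) * wm_prob
        contrast = abs(g - w)
        shift = LESION_INTENSITY_SIGN[mod] * eff.get("intensity_shift", 0.0) * contrast
        img = img + shift * lesion_mask
        # lesion texture: locally increased intensity variance
        img = img + eff.get("texture_amplitude", 0.0) * contrast * rng_tex.standard_normal(img.shape) * lesion_mask
        img = img + config.noise_sd.get(mod, 0.0) * rng_noise.standard_normal(img.shape)
        volumes[mod] = Volume(img.astype(np.float32), aff)

    lesion_regions = frozenset(names[s] for s in lesion_sectors)
    morph = _morph_table(config, rng_morph, side, lesion_regions)

    return SubjectRecord(
        subject_id=f"sub-{seed:06d}",
        volumes=volumes,
        gm_prob=Volume(gm_prob.astype(np.float32), aff),
        wm_prob=Volume(wm_prob.astype(np.float32), aff),
        atlas=Volume(atlas, aff),
        lesion_mask=Volume(lesion_mask, aff),
        morph_table=morph,
        is_patient=is_patient,
        lesion_side=side,
        lesion_subregions=lesion_regions,
    )


def _morph_table(
    config: PhantomConfig,
    rng: np.random.Generator,
    lesion_side: str,
    lesion_regions: frozenset[str],
) -> pd.DataFrame:
    """Gaussian per-region morphology with configured lesion shifts."""
    eff = config.lesion_effect
    names = config.subregion_names
    rows = []
    index = []
    subj_offsets = {f: rng.standard_normal() for f in MORPH_FEATURE_NAMES}
    for hemi in ("left", "right"):
        for region in names:
            lesioned = hemi == lesion_side and region in lesion_regions
            vals = []
            for feat, (base, between, within, sign) in MORPH_FEATURES.items():
                v = base + between * subj_offsets[feat] + within * rng.standard_normal()
                if lesioned:
                    if feat in ("cortical_thickness", "gm_volume", "wm_volume"):
                        v += sign * eff.get("thickness_increase", 0.0) * base
                    else:
                        v += sign * eff.get("intensity_shift", 0.0) * 4.0 * within
                vals.append(v)
            rows.append(vals)
            index.append((hemi, region))
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["hemisphere", "region"]),
        columns=list(MORPH_FEATURE_NAMES),
    )


@dataclass
class CohortDataset:
    """A cohort of phantom subjects plus the two stage-sample designs.

    Stage 1 (lateralization) uses every hemisphere of every subject:
    2 x (n_patients + n_controls) samples. Stage 2 (subregion detection)
    uses one lobe per subject - the affected lobe for patients, a seeded
    random lobe for controls: n_patients + n_controls samples.
    """

    subjects: list[SubjectRecord]
    config: PhantomConfig
    control_lobes: dict[str, str]
    seed: int

    @property
    def patients(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.is_patient]

    @property
    def controls(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if not s.is_patient]

    def hemisphere_samples(self) -> list[tuple[str, str, int]]:
        """(subject_id, hemisphere, label) for stage 1; label 1 = lesioned lobe."""
        out = []
        for s in self.subjects:
            for hemi in ("left", "right"):
                out.append((s.subject_id, hemi, int(s.lesion_side == hemi)))
        return out

    def subregion_stage_samples(self) -> list[tuple[str, str]]:
        """(subject_id, lobe) for stage 2: affected lobe for patients, the
        seeded random lobe for controls."""
        out = []
        for s in self.subjects:
            lobe = s.lesion_side if s.is_patient else self.control_lobes[s.subject_id]
            out.append((s.subject_id, lobe))
        return out

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)


def generate_cohort(n_patients: int, n_controls: int, config: PhantomConfig, seed: int) -> CohortDataset:
    """Generate a seeded cohort of patients and controls."""
    if n_patients < 0 or n_controls < 0:
        raise ValueError("counts must be >= 0")
    ss = np.random.SeedSequence(seed)
    lobes_rng = np.random.default_rng(ss.spawn(1)[0])
    # child seeds for subjects, kept below 2**31 for portability
    subj_seeds = np.random.default_rng(ss).integers(0, 2**31 - 1, size=n_patients + n_controls)
    subjects = []
    control_lobes: dict[str, str] = {}
    for i in range(n_patients + n_controls):
        is_patient = i < n_patients
        rec = generate_subject(config, is_patient, int(subj_seeds[i]))
        rec.subject_id = f"{'pat' if is_patient else 'ctl'}-{i:04d}"
        subjects.append(rec)
        if not is_patient:
            control_lobes[rec.subject_id] = "left" if lobes_rng.random() < 0.5 else "right"
    return CohortDataset(subjects=subjects, config=config, control_lobes=control_lobes, seed=seed)
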