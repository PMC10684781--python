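"""Phantom generator: determinism, ground-truth invariants, cohort design."""

import numpy as np
import pandas as pd
import pytest

from fcdetect.phantom import (
    EFFECT_PRESETS,
    FRONTAL_SUBREGIONS,
    PhantomConfig,
    generate_cohort,
    generate_subject,
)


def _all_volumes(s):
    return {**s.volumes, "gm": s.gm_prob, "wm": s.wm_prob, "atlas": s.atlas, "lesion": s.lesion_mask}


class TestGenerateSubject:
    def test_same_seed_is_bit_identical(self):
        cfg = PhantomConfig(seed=3)
        a = generate_subject(cfg, True, seed=42)
        b = generate_subject(cfg, True, seed=42)
        for key, vol in _all_volumes(a).items():
            assert np.array_equal(vol.data, _all_volumes(b)[key].data), key
        pd.testing.assert_frame_equal(a.morph_table, b.morph_table)

    def test_control_has_no_lesion(self, control_subject):
        assert not control_subject.is_patient
        assert control_subject.lesion_side == "none"
        assert control_subject.lesion_subregions == frozenset()
        assert control_subject.lesion_mask.data.sum() == 0

    def test_patient_lesion_on_exactly_one_side(self, patient_subject):
        s = patient_subject
        assert s.lesion_side in ("left", "right")
        assert len(s.lesion_subregions) >= 1
        les = s.lesion_mask.data > 0
        assert les.any()
        other = "right" if s.lesion_side == "left" else "left"
        assert not (les & s.hemisphere_mask(other)).any()

    def test_lesion_confined_to_named_subregions(self, patient_subject):
        s = patient_subject
        allowed = np.zeros(s.atlas.shape, dtype=bool)
        for name in s.lesion_subregions:
            allowed |= s.region_mask(name, s.lesion_side, FRONTAL_SUBREGIONS)
        assert (np.asarray(s.lesion_mask.data, bool) <= allowed).all()

    def test_tissue_probabilities_valid(self, control_subject):
        gm, wm = control_subject.gm_prob.data, control_subject.wm_prob.data
        assert gm.min() >= 0 and wm.min() >= 0
        assert float((gm + wm).max()) <= 1.0 + 1e-6

    def test_zero_effect_patient_equals_control(self):
        cfg = PhantomConfig(seed=5, lesion_effect=dict(EFFECT_PRESETS["null"]))
        pat = generate_subject(cfg, True, seed=77)
        ctl = generate_subject(cfg, False, seed=77)
        for mod in pat.volumes:
            assert np.array_equal(pat.volumes[mod].data, ctl.volumes[mod].data)
        assert np.array_equal(pat.gm_prob.data, ctl.gm_prob.data)
        assert np.array_equal(pat.wm_prob.data, ctl.wm_prob.data)

    def test_morph_table_shift_for_lesioned_regions(self):
        eff = {"intensity_shift": 0.0, "texture_amplitude": 0.0, "thickness_increase": 0.5}
        cfg0 = PhantomConfig(seed=2, lesion_effect=dict(EFFECT_PRESETS["null"]))
        cfg1 = PhantomConfig(seed=2, lesion_effect=eff)
        base = generate_subject(cfg0, True, seed=9)
        shifted = generate_subject(cfg1, True, seed=9)
        assert shifted.lesion_subregions == base.lesion_subregions
        region = next(iter(shifted.lesion_subregions))
        row0 = base.morph_table.loc[(shifted.lesion_side, region)]
        row1 = shifted.morph_table.loc[(shifted.lesion_side, region)]
        assert row1["cortical_thickness"] > row0["cortical_thickness"]
        other = "right" if shifted.lesion_side == "left" else "left"
        pd.testing.assert_series_equal(
            shifted.morph_table.loc[(other, region)], base.morph_table.loc[(other, region)]
        )

    def test_rejects_invalid_config(self):
        with pytest.raises(ValueError):
            PhantomConfig(grid_shape=(0, 10, 10))
        with pytest.raises(ValueError):
            PhantomConfig(voxel_size_mm=-1)
        with pytest.raises(ValueError):
            PhantomConfig(lesion_effect={"intensity_shift": -0.1})


class TestGenerateCohort:
    def test_reference_cohort_sample_counts(self):
        """A 37-patient + 20-control cohort yields 114 hemisphere samples
        and 57 subregion-stage samples."""
        cohort = generate_cohort(37, 20, PhantomConfig(grid_shape=(8, 8, 8), seed=0), seed=0)
        assert len(cohort.hemisphere_samples()) == 114
        assert len(cohort.subregion_stage_samples()) == 57

    def test_empty_cohort(self):
        cohort = generate_cohort(0, 0, PhantomConfig(grid_shape=(8, 8, 8)), seed=0)
        assert len(cohort) == 0
        assert cohort.hemisphere_samples() == []

    def test_cohort_determinism_and_lobes(self):
        cfg = PhantomConfig(grid_shape=(16, 16, 16), seed=0)
        a = generate_cohort(3, 3, cfg, seed=4)
        b = generate_cohort(3, 3, cfg, seed=4)
        assert a.control_lobes == b.control_lobes
        assert [s.lesion_side for s in a] == [s.lesion_side for s in b]
        for s in a.patients:
            assert s.lesion_side in ("left", "right")
        assert set(a.control_lobes.values()) <= {"left", "right"}

    def test_stage1_labels_one_positive_per_patient(self):
        cohort = generate_cohort(4, 2, PhantomConfig(grid_shape=(16, 16, 16)), seed=8)
        labels = {}
        for sid, hemi, lab in cohort.hemisphere_samples():
            labels.setdefault(sid, []).append(lab)
        for s in cohort:
            assert sum(labels[s.subject_id]) == (1 if s.is_patient else 0)


def test_asymmetry_monotone_in_intensity_shift():
    """Stronger lesion intensity shifts produce larger mean |asymmetry| of
    the first-order mean across seeded replicates."""
    from fcdetect.asymmetry import asymmetry_index

    def mean_abs_asym(shift: float) -> float:
        out = []
        for seed in range(20):
            eff = {"intensity_shift": shift, "texture_amplitude": 0.0, "thickness_increase": 0.0}
            cfg = PhantomConfig(seed=seed, lesion_effect=eff)
            s = generate_subject(cfg, True, seed=seed)
            vals = {}
            for hemi in ("left", "right"):
                m = s.hemisphere_mask(hemi)
                vals[hemi] = float(s.volumes["FLAIR"].data[m].mean())
            out.append(abs(asymmetry_index(vals["left"], vals["right"])))
        return float(np.mean(out))

    a0, a1, a2 = mean_abs_asym(0.0), mean_abs_asym(0.3), mean_abs_asym(0.8)
    assert a0 < a1 < a2
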