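"""Two-stage orchestration: labels, overlap arithmetic, stage gating."""

import numpy as np
import pytest

from fcdetect.phantom import FRONTAL_SUBREGIONS, PhantomConfig, generate_cohort
from fcdetect.radiomics import FeatureSpec
from fcdetect.detector import MLPConfig, SelectionConfig
from fcdetect.two_stage import (
    TEST_DESIGN,
    PipelineConfig,
    make_subregion_labels,
    merge_and_overlap,
    run_pipeline,
    stage2_region_names,
)
from fcdetect.volume import Volume

LIGHT_SEL = SelectionConfig(n_trees=50, threshold_grid_size=4, eval_trees=15, cv_folds=2)
LIGHT_MLP = MLPConfig(epochs=60, patience=10)


class TestSubregionLabels:
    def test_empty_lesion_all_zero(self, control_subject):
        lab = make_subregion_labels(control_subject.lesion_mask, control_subject.atlas, FRONTAL_SUBREGIONS)
        assert lab["stage1"] == {"left": 0, "right": 0}
        assert all(v == 0 for v in lab["stage2"].values())

    def test_lesion_inside_one_subregion(self, control_subject):
        s = control_subject
        region = s.region_mask("precentral", "left", FRONTAL_SUBREGIONS)
        lesion = Volume(region.astype(np.uint8), s.atlas.affine)
        lab = make_subregion_labels(lesion, s.atlas, FRONTAL_SUBREGIONS)
        positives = [k for k, v in lab["stage2"].items() if v]
        assert positives == [("left", "precentral")]
        assert lab["stage1"] == {"left": 1, "right": 0}

    def test_ten_stage2_classifiers_on_eleven_region_atlas(self):
        cfg = PhantomConfig()
        assert len(cfg.subregion_names) == 11
        assert len(stage2_region_names(cfg)) == 10
        assert "paracentral" not in stage2_region_names(cfg)

    def test_patient_truth_matches_record(self, patient_subject):
        s = patient_subject
        lab = make_subregion_labels(s.lesion_mask, s.atlas, FRONTAL_SUBREGIONS)
        assert lab["stage1"][s.lesion_side] == 1
        positives = {r for (h, r), v in lab["stage2"].items() if v and h == s.lesion_side}
        assert positives == set(s.lesion_subregions) - {"paracentral"}


class TestMergeAndOverlap:
    def _subject(self):
        cfg = PhantomConfig(seed=0)
        from fcdetect.phantom import generate_subject

        return generate_subject(cfg, True, seed=21)

    def test_perfect_prediction(self, patient_subject):
        s = patient_subject
        # truth = exactly the union of the lesioned subregions
        union = np.zeros(s.atlas.shape, dtype=bool)
        for r in s.lesion_subregions:
            union |= s.region_mask(r, s.lesion_side, FRONTAL_SUBREGIONS)
        truth = Volume(union, s.atlas.affine)
        pred = [(s.lesion_side, r) for r in s.lesion_subregions]
        ov = merge_and_overlap(pred, truth, s.atlas, FRONTAL_SUBREGIONS)
        assert ov["dice"] == 1.0 and ov["recall"] == 1.0 and ov["jaccard"] == 1.0

    def test_disjoint_prediction_scores_zero(self, patient_subject):
        s = patient_subject
        other = "right" if s.lesion_side == "left" else "left"
        pred = [(other, r) for r in s.lesion_subregions]
        ov = merge_and_overlap(pred, s.lesion_mask, s.atlas, FRONTAL_SUBREGIONS)
        assert ov["dice"] == 0.0 and ov["jaccard"] == 0.0

    def test_empty_prediction_scores_zero(self, patient_subject):
        s = patient_subject
        ov = merge_and_overlap([], s.lesion_mask, s.atlas, FRONTAL_SUBREGIONS)
        assert ov == {"dice": 0.0, "recall": 0.0, "jaccard": 0.0}

    def test_half_overlap_arithmetic(self):
        # synthetic two-region atlas: |P| = |T|, |P&T| = |T|/2
        atlas = Volume(np.zeros((4, 4, 4), dtype=np.int16))
        atlas.data[:2, :, :] = 1  # region A: 32 voxels
        truth = np.zeros((4, 4, 4), dtype=bool)
        truth[1:3, :, :] = True  # 32 voxels, half inside region A
        names = ("A",)
        ov = merge_and_overlap([("left", "A")], Volume(truth), atlas, names)
        assert ov["dice"] == pytest.approx(0.5)
        assert ov["jaccard"] == pytest.approx(1.0 / 3.0)
        assert ov["recall"] == pytest.approx(0.5)

    def test_control_without_truth_rejected(self, control_subject):
        with pytest.raises(ValueError):
            merge_and_overlap([], control_subject.lesion_mask, control_subject.atlas, FRONTAL_SUBREGIONS)


def test_test_design_has_ten_groups():
    assert len(TEST_DESIGN) == 10
    assert len({src for src, _ in TEST_DESIGN}) == 5
    assert len({m for _, m in TEST_DESIGN}) == 2


class TestPipeline:
    @pytest.fixture(scope="class")
    def report(self):
        cfg = PipelineConfig(
            n_patients=6,
            n_controls=4,
            phantom=PhantomConfig(seed=2),
            selection=LIGHT_SEL,
            mlp=LIGHT_MLP,
            cv_folds=2,
            one_stage_baseline=True,
            seed=2,
        )
        return run_pipeline(cfg)

    def test_report_schema(self, report):
        d = report.to_dict()
        assert d["n_stage2_classifiers"] == 10
        assert set(d["stage1"]) >= {"accuracy", "balanced_accuracy", "specificity", "sensitivity", "auc"}
        assert set(d["mean_overlap"]) == {"dice", "recall", "jaccard"}
        assert "one_stage_mean_overlap" in d

    def test_all_hemisphere_samples_scored(self, report):
        assert report.stage1.scores.notna().all()
        assert len(report.stage1.scores) == 2 * 10

    def test_patient_overlaps_in_unit_interval(self, report):
        assert ((report.overlap >= 0) & (report.overlap <= 1)).all().all()
        assert len(report.overlap) == 6  # patients only; controls contribute none

    def test_stage2_conditioning_on_lobe(self, report):
        """Flipping the lobe fed to stage-2 inference changes which
        subregion rows are scored (the gating audit)."""
        s2 = report.stage2
        sid = next(iter(report.predicted_subregions))
        left = s2.predict_regions(sid, "left")
        right = s2.predict_regions(sid, "right")
        assert all(h == "left" for h, _ in left)
        assert all(h == "right" for h, _ in right)

    def test_reference_cohort_counts_in_stage_design(self):
        cohort = generate_cohort(37, 20, PhantomConfig(grid_shape=(8, 8, 8)), seed=0)
        assert len(cohort.hemisphere_samples()) == 114
        assert len(cohort.subregion_stage_samples()) == 57

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PipelineConfig(roi_kind="cerebellum")
        with pytest.raises(ValueError):
            PipelineConfig(feature_mode="squared")
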