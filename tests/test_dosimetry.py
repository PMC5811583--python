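"""Deposition quantification: activity, threshold volume, absorbed dose."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scoutdose import (
    DoseConstants,
    PhantomSpec,
    RoiMask,
    SphereSpec,
    VoxelImage,
    absorbed_dose,
    cohort_summary,
    estimate_activity,
    estimate_volume,
    generate_phantom,
    quantify_deposition,
    reference_cohort,
    sphere_margin_masks,
)
from scoutdose.dosimetry import DepositionRecord, three_medians


class TestAbsorbedDose:
    def test_reference_cohort_doses(self):
        """Recomputing each cohort dose from its measured activity/volume
        reproduces the reported value: exactly at one decimal for the four
        low-activity rows, within 0.2 Gy for the two rows whose published
        dose was evidently computed from unrounded inputs."""
        cohort = reference_cohort()
        for _, row in cohort.iterrows():
            dose = absorbed_dose(row["activity_mbq"], row["volume_ml"])
            if row["patient"] in (2, 5):
                assert dose == pytest.approx(row["reported_dose_gy"], abs=0.2)
            else:
                assert round(dose, 1) == row["reported_dose_gy"]

    def test_unit_cancellation(self):
        assert absorbed_dose(1.06, 15.87) == pytest.approx(1.0, rel=1e-12)

    def test_zero_activity_zero_dose(self):
        assert absorbed_dose(0.0, 10.0) == 0.0

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError, match="volume"):
            absorbed_dose(1.0, 0.0)

    @settings(derandomize=True, deadline=None, max_examples=100)
    @given(
        st.floats(0.01, 1e3),
        st.floats(0.1, 1e3),
        st.floats(0.01, 100),
    )
    def test_linear_in_activity_inverse_in_volume(self, a, v, k):
        base = absorbed_dose(a, v)
        assert absorbed_dose(k * a, v) == pytest.approx(k * base, rel=1e-9)
        assert absorbed_dose(a, k * v) == pytest.approx(base / k, rel=1e-9)

    def test_custom_constants(self):
        c = DoseConstants(energy_per_activity=10.0, tissue_density=1.0)
        assert absorbed_dose(2.0, 4.0, c) == pytest.approx(5.0)


class TestEstimateActivity:
    def test_recovers_synthetic_deposition(self, default_scene):
        est = estimate_activity(default_scene.image, default_scene.margin_mask)
        assert est == pytest.approx(3.7, rel=0.01)

    def test_zero_image_gives_zero(self):
        img = VoxelImage(np.zeros((4, 4, 4)), (4.8, 4.8, 4.8))
        mask = RoiMask(np.ones((4, 4, 4), dtype=bool))
        assert estimate_activity(img, mask) == 0.0

    def test_linear_in_voxel_values(self, default_scene):
        doubled = VoxelImage(
            default_scene.image.values * 2,
            default_scene.image.spacing,
            default_scene.image.origin,
        )
        assert estimate_activity(doubled, default_scene.margin_mask) == pytest.approx(
            2 * estimate_activity(default_scene.image, default_scene.margin_mask), rel=1e-12
        )

    def test_empty_mask_rejected(self, default_scene):
        with pytest.raises(ValueError, match="empty"):
            estimate_activity(default_scene.image, RoiMask(np.zeros(default_scene.image.shape, bool)))


class TestEstimateVolume:
    def uniform_region(self):
        vals = np.zeros((8, 8, 8))
        sel = np.zeros((8, 8, 8), dtype=bool)
        sel.ravel()[:100] = True
        vals[sel] = 7.0
        return VoxelImage(vals, (4.8, 4.8, 4.8)), RoiMask(sel)

    @pytest.mark.parametrize("threshold", [0.05, 0.3, 1.0])
    def test_uniform_region_counts_every_voxel(self, threshold):
        img, mask = self.uniform_region()
        assert estimate_volume(img, mask, threshold) == pytest.approx(100 * img.voxel_volume_ml)

    def test_threshold_one_keeps_only_max_attaining_voxels(self, rng):
        vals = rng.uniform(1, 10, (6, 6, 6))
        vals[2, 3, 1] = vals[4, 4, 4] = 11.0  # two exact maxima
        img = VoxelImage(vals, (10, 10, 10))
        mask = RoiMask(np.ones(vals.shape, dtype=bool))
        assert estimate_volume(img, mask, 1.0) == pytest.approx(2.0)

    def test_matches_brute_force_count_on_blurred_sphere(self):
        spec = PhantomSpec(spheres=(SphereSpec((0, 0, 0), 2.6, 1.0),))
        image, _ = generate_phantom(spec)
        mask = sphere_margin_masks(spec)[0]
        threshold = 0.30 * image.values[mask.selected].max()
        count = 0
        idx = np.argwhere(mask.selected)
        for i, j, k in idx:
            if image.values[i, j, k] >= threshold:
                count += 1
        assert estimate_volume(image, mask, 0.30) == pytest.approx(
            count * image.voxel_volume_ml, rel=1e-12
        )

    def test_monotone_non_increasing_in_threshold(self, default_scene):
        fractions = np.linspace(0.05, 1.0, 20)
        vols = [
            estimate_volume(default_scene.image, default_scene.margin_mask, f) for f in fractions
        ]
        assert all(a >= b for a, b in zip(vols, vols[1:]))

    def test_all_zero_region_rejected(self):
        img = VoxelImage(np.zeros((4, 4, 4)), (4.8, 4.8, 4.8))
        mask = RoiMask(np.ones((4, 4, 4), dtype=bool))
        with pytest.raises(ValueError, match="zero"):
            estimate_volume(img, mask)

    def test_threshold_fraction_out_of_range_rejected(self, default_scene):
        with pytest.raises(ValueError, match="threshold_fraction"):
            estimate_volume(default_scene.image, default_scene.margin_mask, 0.0)


class TestQuantifyDeposition:
    def test_end_to_end_median_regime(self, default_scene, default_sweep):
        """A 3.7 MBq deposition in ~15.3 ml quantified at the phantom-
        calibrated threshold recovers the activity within 1% and gives a
        conservative dose: at or above the 3.6 Gy true value, but within the
        partial-volume overestimation range the phantom itself exhibits
        (up to roughly four-fold for mid-size objects at this resolution)."""
        record = quantify_deposition(
            default_scene.image, default_scene.margin_mask, default_sweep.selected_threshold
        )
        true_dose = absorbed_dose(3.7, 15.3)
        assert record.activity_mbq == pytest.approx(3.7, rel=0.01)
        assert true_dose <= record.dose_gy <= 4.0 * true_dose

    def test_zero_activity_deposition_errors_on_volume(self):
        img = VoxelImage(np.zeros((4, 4, 4)), (4.8, 4.8, 4.8))
        mask = RoiMask(np.ones((4, 4, 4), dtype=bool))
        with pytest.raises(ValueError, match="zero"):
            quantify_deposition(img, mask)

    def test_two_depositions_quantified_independently(self):
        from scoutdose import PatientSceneSpec, generate_patient_scene

        base = PatientSceneSpec(deposition_activity_mbq=3.7)
        other = PatientSceneSpec(
            deposition_activity_mbq=7.4,
            deposition_volume_ml=9.6,
            deposition_center_mm=(95.0, -55.0, -60.0),
        )
        a = generate_patient_scene(base)
        b = generate_patient_scene(other)
        combined = VoxelImage(
            a.image.values + b.image.values, a.image.spacing, a.image.origin
        )
        rec_a = quantify_deposition(combined, a.margin_mask)
        rec_b = quantify_deposition(combined, b.margin_mask)
        alone_a = quantify_deposition(a.image, a.margin_mask)
        alone_b = quantify_deposition(b.image, b.margin_mask)
        assert rec_a.dose_gy == pytest.approx(alone_a.dose_gy, rel=0.01)
        assert rec_b.dose_gy == pytest.approx(alone_b.dose_gy, rel=0.01)


class TestCohortSummary:
    def records_from_reference(self):
        return [
            DepositionRecord(
                activity_mbq=row["activity_mbq"],
                volume_ml=row["volume_ml"],
                dose_gy=absorbed_dose(row["activity_mbq"], row["volume_ml"]),
            )
            for _, row in reference_cohort().iterrows()
        ]

    def test_upper_median_dose_matches_reported_value(self):
        summary = cohort_summary(self.records_from_reference())
        assert round(summary["dose_gy"]["upper_median"], 1) == 3.6

    def test_upper_median_volume_and_activity(self):
        summary = cohort_summary(self.records_from_reference())
        assert summary["volume_ml"]["upper_median"] == pytest.approx(15.3)
        assert summary["activity_mbq"]["upper_median"] == pytest.approx(3.7)

    def test_three_median_conventions_on_even_n(self):
        meds = three_medians([1.0, 2.0, 3.0, 10.0])
        assert meds == {"lower_median": 2.0, "median": 2.5, "upper_median": 3.0}

    def test_medians_coincide_for_odd_n(self):
        meds = three_medians([5.0, 1.0, 9.0])
        assert meds["lower_median"] == meds["median"] == meds["upper_median"] == 5.0

    def test_single_record_summary_is_that_record(self):
        rec = DepositionRecord(activity_mbq=2.0, volume_ml=4.0, dose_gy=absorbed_dose(2, 4))
        summary = cohort_summary([rec])
        for stat in ("min", "max", "median", "lower_median", "upper_median"):
            assert summary["dose_gy"][stat] == pytest.approx(rec.dose_gy)

    def test_min_le_medians_le_max(self):
        summary = cohort_summary(self.records_from_reference())
        for q in ("activity_mbq", "volume_ml", "dose_gy"):
            s = summary[q]
            for stat in ("lower_median", "median", "upper_median"):
                assert s["min"] <= s[stat] <= s["max"]

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cohort_summary([])
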