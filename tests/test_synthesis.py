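"""Phantom rendering, degradation operators and dataset generation."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retiqa import (
    DatasetConfig,
    DegradationSpec,
    PhantomSpec,
    apply_degradation,
    derive_overall_likert,
    generate_phantom,
    make_dataset,
    severity_to_likert,
)
from retiqa.categories import degradable_categories
from retiqa.synthesis import category_proxy, fov_mask


class TestPhantom:
    def test_identical_spec_renders_bit_identical_images(self):
        spec = PhantomSpec(seed=5, modality="CF", side_px=96)
        a = generate_phantom(spec)
        b = generate_phantom(spec)
        assert a.tobytes() == b.tobytes()

    @pytest.mark.parametrize("modality,channels", [("CF", 3), ("FA", 1)])
    def test_channel_count_and_range(self, modality, channels):
        img = generate_phantom(PhantomSpec(seed=1, modality=modality, side_px=64))
        assert img.shape == (64, 64, channels)
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_pixels_outside_fov_are_black(self):
        spec = PhantomSpec(seed=3, modality="CF", side_px=128, fov_fraction=0.8)
        img = generate_phantom(spec)
        outside = ~fov_mask(128, 0.8)
        assert np.all(img[outside] == 0.0)

    def test_nonzero_fraction_bounded_by_disc_area(self):
        img = generate_phantom(
            PhantomSpec(seed=9, modality="CF", side_px=128, fov_fraction=0.9)
        )
        frac = (img.max(axis=-1) > 0).mean()
        assert frac <= math.pi * (0.9 / 2) ** 2 + 0.01

    def test_early_fa_phase_is_darker_than_peak(self):
        lo = generate_phantom(PhantomSpec(seed=4, modality="FA", fa_phase=0.0))
        hi = generate_phantom(PhantomSpec(seed=4, modality="FA", fa_phase=1.0))
        assert lo.mean() < hi.mean()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"side_px": 32},
            {"fov_fraction": 0.4},
            {"fov_fraction": 1.2},
            {"vessel_branches": 2},
            {"fa_phase": 1.5},
            {"modality": "OCT"},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        base = dict(seed=0, modality="FA")
        base.update(kwargs)
        with pytest.raises(ValueError):
            generate_phantom(PhantomSpec(**base))


class TestDegradations:
    def test_empty_spec_list_is_identity_with_grade_one_labels(self, cf_phantom):
        out, likert = apply_degradation(cf_phantom, [])
        assert np.array_equal(out, cf_phantom)
        assert set(likert) == set(degradable_categories("CF"))
        assert all(v == 1 for v in likert.values())

    def test_severity_zero_everywhere_is_identity(self, fa_phantom):
        specs = [
            DegradationSpec(cat, 0.0, seed=3) for cat in degradable_categories("FA")
        ]
        out, likert = apply_degradation(fa_phantom, specs)
        assert np.array_equal(out, fa_phantom)
        assert all(v == 1 for v in likert.values())

    def test_focus_ladder_reduces_gradient_magnitude(self, cf_phantom):
        grads = []
        for sev in (0.2, 0.5, 0.9):
            out, _ = apply_degradation(cf_phantom, [DegradationSpec("focus", sev, seed=1)])
            grads.append(category_proxy(out, "focus"))
        assert grads[0] > grads[1] > grads[2]

    def test_full_contrast_compression_reduces_std(self, cf_phantom):
        out, _ = apply_degradation(cf_phantom, [DegradationSpec("contrast", 1.0, seed=1)])
        assert category_proxy(out, "contrast") <= category_proxy(cf_phantom, "contrast")

    def test_duplicate_category_rejected(self, cf_phantom):
        specs = [DegradationSpec("focus", 0.3), DegradationSpec("focus", 0.6)]
        with pytest.raises(ValueError, match="duplicate"):
            apply_degradation(cf_phantom, specs)

    def test_modality_mismatch_rejected(self, cf_phantom):
        with pytest.raises(ValueError, match="does not apply"):
            apply_degradation(cf_phantom, [DegradationSpec("noise", 0.5)])

    def test_proxies_monotone_in_severity_across_phantoms(self):
        """Label-image consistency: each category's statistic tracks severity.

        Checked on 20 seed-matched phantoms per modality-category pair with
        a three-step severity ladder.
        """
        ladders = {"CF": degradable_categories("CF"), "FA": degradable_categories("FA")}
        increasing = {"shadow_reflection", "noise"}
        for modality, cats in ladders.items():
            for cat in cats:
                ok = 0
                for seed in range(20):
                    img = generate_phantom(
                        PhantomSpec(seed=seed, modality=modality, side_px=64)
                    )
                    vals = []
                    for sev in (0.1, 0.5, 0.9):
                        out, _ = apply_degradation(
                            img, [DegradationSpec(cat, sev, seed=seed + 1)]
                        )
                        ref = img if cat == "shadow_reflection" else None
                        vals.append(category_proxy(out, cat, reference=ref))
                    if cat in increasing:
                        ok += vals[0] < vals[1] < vals[2]
                    else:
                        ok += vals[0] > vals[1] > vals[2]
                assert ok >= 19, f"{modality}/{cat}: monotone in only {ok}/20 phantoms"


class TestLikertMapping:
    @pytest.mark.parametrize(
        "severity,grade",
        [(0.0, 1), (0.14, 1), (0.15, 2), (0.34, 2), (0.40, 3), (0.55, 4), (0.74, 4),
         (0.75, 5), (1.0, 5)],
    )
    def test_severity_bins(self, severity, grade):
        assert severity_to_likert(severity) == grade

    @pytest.mark.parametrize("severity", [-0.1, 1.1])
    def test_out_of_range_severity_rejected(self, severity):
        with pytest.raises(ValueError):
            severity_to_likert(severity)

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=200, derandomize=True)
    def test_nondecreasing_step_function(self, s):
        g = severity_to_likert(s)
        assert 1 <= g <= 5
        if s <= 0.99:
            assert severity_to_likert(min(1.0, s + 0.01)) >= g

    def test_overall_is_worst_category(self):
        assert derive_overall_likert({"contrast": 1, "focus": 1, "illumination": 1,
                                      "shadow_reflection": 1}) == 1
        assert derive_overall_likert({"contrast": 2, "focus": 4, "noise": 1}) == 4
        with pytest.raises(ValueError):
            derive_overall_likert({})

    @given(st.dictionaries(st.sampled_from(degradable_categories("CF")),
                           st.integers(1, 5), min_size=1))
    @settings(max_examples=100, derandomize=True)
    def test_overall_dominates_every_category(self, likert):
        overall = derive_overall_likert(likert)
        assert all(overall >= v for v in likert.values())


class TestMakeDataset:
    def test_patient_splits_are_disjoint_and_exhaustive(self, tiny_dataset):
        _, manifest, _ = tiny_dataset
        by_split = {
            s: set(g["patient_id"]) for s, g in manifest.groupby("split")
        }
        assert set(by_split) == {"train", "validation", "test"}
        assert not (by_split["train"] & by_split["validation"])
        assert not (by_split["train"] & by_split["test"])
        assert not (by_split["validation"] & by_split["test"])

    def test_visit_sizes_within_bounds(self, tiny_dataset):
        _, manifest, config = tiny_dataset
        sizes = manifest.groupby("visit_id").size()
        lo, hi = config.images_per_visit
        assert sizes.between(lo, hi).all()

    def test_quota_mode_hits_exact_split_sizes(self, tiny_dataset):
        _, manifest, config = tiny_dataset
        counts = manifest["split"].value_counts()
        assert (counts["train"], counts["validation"], counts["test"]) == (48, 12, 24)

    def test_overall_label_fraction_on_training_split(self, tmp_path):
        config = DatasetConfig(
            modality="CF", seed=5, n_images_per_split=(150, 9, 18),
            side_px=64, overall_label_fraction=0.8,
        )
        manifest = make_dataset(config, tmp_path)
        train = manifest[manifest["split"] == "train"]
        n_labelled = train["likert_overall"].notna().sum()
        # binomial(150, 0.8): allow 4 sigma around the expectation
        sigma = math.sqrt(150 * 0.8 * 0.2)
        assert abs(n_labelled - 120) <= 4 * sigma
        # validation/test always keep the overall label
        rest = manifest[manifest["split"] != "train"]
        assert rest["likert_overall"].notna().all()

    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        config = DatasetConfig(
            modality="FA", seed=9, n_images_per_split=(9, 3, 6), side_px=64
        )
        m1 = make_dataset(config, tmp_path / "a")
        m2 = make_dataset(config, tmp_path / "b")
        csv_a = (tmp_path / "a" / "manifest.csv").read_bytes()
        csv_b = (tmp_path / "b" / "manifest.csv").read_bytes()
        assert csv_a == csv_b
        img = m1["image_path"].iloc[0]
        assert (tmp_path / "a" / img).read_bytes() == (tmp_path / "b" / img).read_bytes()

    def test_images_per_visit_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            DatasetConfig(modality="CF", images_per_visit=(2, 8)).validate()
        with pytest.raises(ValueError):
            DatasetConfig(modality="CF", images_per_visit=(3, 20)).validate()

    def test_likert_labels_cover_all_degradable_categories(self, tiny_dataset):
        _, manifest, _ = tiny_dataset
        for cat in degradable_categories("CF"):
            assert manifest[f"likert_{cat}"].notna().all()
        # FA-only category stays empty for a CF dataset
        assert manifest["likert_noise"].isna().all()
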