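import dataclasses

import numpy as np
import pytest

from oracles import zncc_all_offsets
from sonoquant import synth
from sonoquant.detect import (
    MatchConfig,
    StructureDetection,
    binarize_bbox,
    detect_structures,
    generate_variants,
    match_template,
    refine_contour,
    validate_order,
)
from sonoquant.errors import DegenerateTemplateError, TemplateSizeError
from sonoquant.preprocess import (
    ROIBox,
    bilateral_filter,
    compute_roi,
    rescale_to_byte,
    to_unit_interval,
)


def preprocess_roi(image):
    roi = compute_roi(image)
    byte = rescale_to_byte(bilateral_filter(to_unit_interval(roi.crop(image.pixels))))
    return roi, byte


class TestMatchTemplate:
    def test_exact_subwindow_scores_one(self, rng):
        image = rng.integers(0, 256, (64, 64), dtype=np.uint8)
        r, c = 23, 41
        patch = image[r : r + 9, c : c + 9]
        m = match_template(image, patch)
        assert (m.bbox.top_row, m.bbox.left_col) == (r, c)
        assert m.score == pytest.approx(1.0, abs=1e-9)

    def test_negated_patch_anticorrelates(self, rng):
        image = rng.integers(0, 256, (40, 40), dtype=np.uint8)
        patch = 255 - image[10:19, 10:19]
        # score at the negated window is exactly -1; check via direct call
        window = image[10:19, 10:19].astype(float)
        p = patch.astype(float)
        w0, p0 = window - window.mean(), p - p.mean()
        score = (w0 * p0).sum() / np.sqrt((w0 * w0).sum() * (p0 * p0).sum())
        assert score == pytest.approx(-1.0, abs=1e-12)

    def test_argmax_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            image = rng.integers(0, 256, (64, 64), dtype=np.uint8)
            patch = rng.integers(0, 256, (9, 9), dtype=np.uint8)
            er, ec, es = zncc_all_offsets(image, patch)
            m = match_template(image, patch)
            assert (m.bbox.top_row, m.bbox.left_col) == (er, ec)
            assert m.score == pytest.approx(es, abs=1e-9)

    def test_oversized_patch_rejected(self):
        with pytest.raises(TemplateSizeError):
            match_template(np.zeros((8, 8)), np.ones((8, 9)))

    def test_zero_variance_patch_rejected(self, rng):
        image = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        with pytest.raises(DegenerateTemplateError):
            match_template(image, np.full((5, 5), 7, dtype=np.uint8))


class TestGenerateVariants:
    def test_identity_configuration_returns_original_only(self, rng):
        patch = rng.integers(0, 256, (10, 10), dtype=np.uint8)
        cfg = MatchConfig(variant_scales=(), variant_contrasts=())
        variants = generate_variants(patch, cfg)
        assert len(variants) == 1 and np.array_equal(variants[0], patch)

    def test_scale_and_contrast_variant_count_and_shapes(self, rng):
        patch = rng.integers(0, 256, (10, 10), dtype=np.uint8)
        cfg = MatchConfig(variant_scales=(0.9, 1.1), variant_contrasts=(0.8, 1.2))
        variants = generate_variants(patch, cfg)
        assert len(variants) == 5
        assert variants[1].shape == (9, 9)
        assert variants[2].shape == (11, 11)
        assert variants[3].shape == variants[4].shape == (10, 10)

    def test_unit_contrast_is_pixel_identical(self, rng):
        patch = rng.integers(0, 256, (8, 12), dtype=np.uint8)
        cfg = MatchConfig(variant_scales=(), variant_contrasts=(1.0,))
        assert np.array_equal(generate_variants(patch, cfg)[1], patch)

    def test_tiny_scale_variants_skipped(self):
        patch = np.arange(16, dtype=np.uint8).reshape(4, 4)
        cfg = MatchConfig(variant_scales=(0.5,), variant_contrasts=())
        assert len(generate_variants(patch, cfg)) == 1


class TestDetectStructures:
    def test_noiseless_self_templated_phantom_recovers_all_rows(self, noiseless_abdomen):
        image, truth = noiseless_abdomen
        templates = synth.extract_templates(image, truth)
        roi, byte = preprocess_roi(image)
        dets = detect_structures(byte, templates, truth.descriptor)
        assert len(dets) == len(truth.boundary_rows)
        for d in dets:
            true_row = truth.boundary_rows[d.structure_id] - roi.top_row
            assert abs(d.interface_row - true_row) <= 1.0
            assert d.match.score >= 0.99

    def test_scale_mismatched_library_rescued_by_variant_fallback(self, noiseless_abdomen):
        from skimage.transform import resize

        image, truth = noiseless_abdomen
        templates = synth.extract_templates(image, truth)
        shrunk = dataclasses.replace(templates)
        shrunk.entries = [
            dataclasses.replace(
                e,
                patch=np.clip(
                    np.floor(
                        resize(
                            e.patch.astype(float),
                            (int(e.patch.shape[0] * 0.75), int(e.patch.shape[1] * 0.75)),
                            order=1, anti_aliasing=False, preserve_range=True,
                        ) + 0.5
                    ), 0, 255,
                ).astype(np.uint8),
            )
            for e in templates.entries
        ]
        _, byte = preprocess_roi(image)
        cfg = MatchConfig(accept_score=0.95, variant_scales=(4 / 3,), variant_contrasts=())
        dets = detect_structures(byte, shrunk, truth.descriptor, cfg)
        assert dets, "fallback variants should rescue a scale-mismatched library"
        assert any(d.match.variant_index > 0 for d in dets)

    def test_pure_noise_yields_no_detection_at_strict_threshold(self, rng, abdomen_templates):
        noise = rng.integers(0, 256, (400, 460), dtype=np.uint8)
        cfg = MatchConfig(accept_score=0.95)
        descriptor = abdomen_templates.entries[0].descriptor
        assert detect_structures(noise, abdomen_templates, descriptor, cfg) == []

    def test_detection_is_deterministic(self, abdomen_phantom, abdomen_templates):
        image, truth = abdomen_phantom
        _, byte = preprocess_roi(image)
        a = detect_structures(byte, abdomen_templates, truth.descriptor)
        b = detect_structures(byte, abdomen_templates, truth.descriptor)
        assert [(d.structure_id, d.interface_row, d.match.score) for d in a] == [
            (d.structure_id, d.interface_row, d.match.score) for d in b
        ]


def _det(sid, top, height, score):
    bbox = ROIBox(0, 30, top, top + height)
    from sonoquant.detect import MatchResult

    return StructureDetection(
        match=MatchResult(structure_id=sid, score=score, bbox=bbox),
        contour=np.zeros((0, 2)),
        interface_row=top + (height - 1) / 2,
    )


class TestValidateOrder:
    def test_monotone_set_passes_unchanged(self, abdomen_templates):
        dets = [
            _det("skin_fat", 10, 10, 0.9),
            _det("fascia", 40, 10, 0.9),
            _det("muscle_wall", 90, 10, 0.9),
        ]
        assert validate_order(dets, abdomen_templates) == dets

    def test_inverted_pair_drops_lower_score(self, abdomen_templates):
        dets = [
            _det("skin_fat", 50, 10, 0.7),   # below fascia: violation
            _det("fascia", 20, 10, 0.95),
        ]
        out = validate_order(dets, abdomen_templates)
        assert [d.structure_id for d in out] == ["fascia"]

    def test_random_perturbations_always_end_monotone(self, rng, abdomen_templates):
        ids = ["skin_fat", "fascia", "muscle_wall", "peritoneum"]
        for _ in range(100):
            dets = [
                _det(sid, int(rng.integers(0, 300)), 12, float(rng.random()))
                for sid in ids
            ]
            out = validate_order(dets, abdomen_templates)
            rows = [d.interface_row for d in out]
            assert rows == sorted(rows)
            assert len(set(rows)) == len(rows)


class TestRefineContour:
    def test_solid_rectangle_contour_and_interface(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[20:40, 10:50] = True
        det = _det("skin_fat", 15, 30, 0.9)
        det.match = dataclasses.replace(det.match, bbox=ROIBox(5, 55, 15, 45))
        out = refine_contour(mask, det, kernel_radius=2)
        assert out.interface_row == pytest.approx(20.0)
        rows = out.contour[:, 0]
        cols = out.contour[:, 1]
        assert rows.min() == pytest.approx(19.5) and rows.max() == pytest.approx(39.5)
        assert cols.min() == pytest.approx(9.5) and cols.max() == pytest.approx(49.5)

    def test_salt_specks_removed(self, rng):
        clean = np.zeros((60, 60), dtype=bool)
        clean[20:40, 10:50] = True
        noisy = clean.copy()
        specks = rng.integers(0, 15, size=(8, 2))
        for r, c in specks:
            noisy[r, c] = True
        det = _det("skin_fat", 0, 60, 0.9)
        det.match = dataclasses.replace(det.match, bbox=ROIBox(0, 60, 0, 60))
        out_noisy = refine_contour(noisy, det, kernel_radius=2)
        out_clean = refine_contour(clean, det, kernel_radius=2)
        np.testing.assert_allclose(out_noisy.contour, out_clean.contour)
        assert out_noisy.interface_row == out_clean.interface_row

    def test_empty_mask_falls_back_to_bbox_outline(self):
        det = _det("skin_fat", 5, 10, 0.9)
        out = refine_contour(np.zeros((40, 40), dtype=bool), det, kernel_radius=2)
        assert "refine_fallback" in out.flags
        assert out.contour.shape[0] == 5  # closed rectangle outline


class TestBinarizeBbox:
    def test_otsu_level_computed_inside_bbox(self):
        img = np.zeros((50, 50), dtype=np.uint8)
        img[10:20, 10:40] = 200
        mask = binarize_bbox(img, ROIBox(5, 45, 5, 25))
        assert mask[12, 20] and not mask[22, 20]
        assert not mask[:5].any()  # nothing outside the bbox

    def test_constant_window_yields_empty_mask(self):
        img = np.full((30, 30), 9, dtype=np.uint8)
        assert not binarize_bbox(img, ROIBox(0, 30, 0, 30)).any()
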