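"""Color conversion, chart correction and sector statistics."""

import numpy as np
import pytest

from sasang_shi import complexion as cx
from sasang_shi import signals


class TestYCrCb:
    def test_black_is_dark_neutral(self):
        assert np.allclose(cx.rgb_to_ycrcb([0, 0, 0]), [0, 128, 128])

    def test_gray_is_achromatic(self):
        assert np.allclose(
            cx.rgb_to_ycrcb([128, 128, 128]), [128, 128, 128])

    def test_matches_matrix_oracle(self, rng):
        pix = rng.uniform(0, 255, size=(20, 3))
        got = cx.rgb_to_ycrcb(pix)
        # Direct per-pixel evaluation of the BT.601 equations.
        for p, g in zip(pix, got):
            r, gr, b = p
            y = 0.299 * r + 0.587 * gr + 0.114 * b
            assert g[0] == pytest.approx(y, abs=1e-9)
            assert g[1] == pytest.approx(
                0.5 * r - 0.418688 * gr - 0.081312 * b + 128, abs=1e-9)
            assert g[2] == pytest.approx(
                -0.168736 * r - 0.331264 * gr + 0.5 * b + 128, abs=1e-9)

    def test_roundtrip_within_one_unit(self, rng):
        pix = rng.integers(0, 256, size=(500, 3)).astype(float)
        back = cx.ycrcb_to_rgb(cx.rgb_to_ycrcb(pix))
        assert np.max(np.abs(back - pix)) <= 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cx.rgb_to_ycrcb([0, 0, 300])


class TestColorCorrection:
    def test_identity_when_observed_equals_reference(self, rng):
        patches = rng.uniform(10, 245, size=(8, 3))
        img = rng.uniform(0, 255, size=(16, 16, 3))
        corrected, rms = cx.correct_color(img, patches, patches)
        assert rms == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(corrected, img, atol=1e-8)

    def test_known_linear_distortion_inverted(self, rng):
        reference = rng.uniform(20, 235, size=(12, 3))
        M = np.array([[0.9, 0.08, 0.0],
                      [0.03, 1.1, 0.02],
                      [0.0, 0.05, 0.85]])
        offset = np.array([6.0, -4.0, 2.5])
        observed = reference @ M.T + offset
        img = rng.uniform(30, 220, size=(10, 10, 3))
        distorted = img @ M.T + offset
        corrected, rms = cx.correct_color(distorted, observed, reference)
        assert rms < 1e-6
        assert np.max(np.abs(corrected - img)) < 1.0

    def test_collinear_patches_rejected(self):
        t = np.linspace(0, 1, 5)[:, None]
        obs = t * np.array([[200.0, 100.0, 50.0]])  # all on one line
        with pytest.raises(cx.DegenerateChartError):
            cx.fit_color_correction(obs, obs)

    def test_too_few_patches_rejected(self, rng):
        p = rng.uniform(0, 255, size=(3, 3))
        with pytest.raises(cx.DegenerateChartError):
            cx.fit_color_correction(p, p)

    def test_idempotent_on_corrected_image(self, rng):
        ref = rng.uniform(20, 235, size=(10, 3))
        obs = ref @ np.diag([0.9, 1.05, 0.97]) + 3.0
        img = rng.uniform(0, 255, size=(8, 8, 3))
        coef, _ = cx.fit_color_correction(obs, ref)
        corrected_obs = cx.apply_color_correction(obs, coef)
        coef2, rms2 = cx.fit_color_correction(corrected_obs, ref)
        again = cx.apply_color_correction(
            cx.apply_color_correction(img, coef), coef2)
        assert np.max(np.abs(
            again - cx.apply_color_correction(img, coef))) < 1e-6


def _two_tone_image_and_sectors(a, b):
    """Nose sector split half value a, half value b; others uniform."""
    labels = np.zeros((20, 40), dtype=np.uint8)
    for lab in range(1, 7):
        labels[2 * (lab - 1), :5] = lab
    labels[14:18, :] = 7
    img = np.full((20, 40, 3), 128.0)
    img[14:16, :, :] = a
    img[16:18, :, :] = b
    return img, cx.SectorSet.from_label_image(labels)


class TestExtraction:
    def test_sixty_variables_and_uniform_sector(self):
        img, sectors = _two_tone_image_and_sectors(128.0, 128.0)
        rec = cx.extract_complexion(img, sectors)
        assert len(rec) == 60
        assert set(rec) == set(cx.COMPLEXION_VARIABLES)
        assert rec["Nose_Y_std"] == pytest.approx(0.0, abs=1e-12)
        assert rec["Nose_Y_avg"] == pytest.approx(128.0)

    def test_two_point_sector_statistics(self):
        # Half the pixels gray value 100, half 180: avg 140, population
        # std |180-100|/2 = 40 in Y (equal RGB means Y equals the gray).
        img, sectors = _two_tone_image_and_sectors(100.0, 180.0)
        rec = cx.extract_complexion(img, sectors)
        assert rec["Nose_Y_avg"] == pytest.approx(140.0)
        assert rec["Nose_Y_std"] == pytest.approx(40.0)

    def test_pixel_permutation_invariance(self, rng):
        face = signals.generate_face_image(seed=2)
        rec = cx.extract_complexion(face.image, face.sectors)
        # Shuffle pixels inside the FhL mask.
        img = face.image.astype(float).copy()
        mask = face.sectors.masks["FhL"]
        vals = img[mask]
        img[mask] = vals[rng.permutation(len(vals))]
        rec2 = cx.extract_complexion(img, face.sectors)
        assert rec2["FhL_Y_avg"] == pytest.approx(rec["FhL_Y_avg"])
        assert rec2["FhL_Cr_std"] == pytest.approx(rec["FhL_Cr_std"])

    def test_whole_sector_mean_bounded_by_parts(self):
        face = signals.generate_face_image(seed=3)
        rec = cx.extract_complexion(face.image, face.sectors)
        for whole, a, b in (("FhW", "FhL", "FhR"),
                            ("ChLW", "ChLU", "ChLD"),
                            ("ChRW", "ChRU", "ChRD")):
            for ch in ("Y", "Cr", "Cb"):
                lo = min(rec[f"{a}_{ch}_avg"], rec[f"{b}_{ch}_avg"])
                hi = max(rec[f"{a}_{ch}_avg"], rec[f"{b}_{ch}_avg"])
                assert lo - 1e-9 <= rec[f"{whole}_{ch}_avg"] <= hi + 1e-9

    def test_empty_mask_error_names_sector(self):
        img = np.zeros((4, 4, 3))
        masks = {s: np.ones((4, 4), dtype=bool) for s in cx.SECTORS}
        sectors = cx.SectorSet(masks)
        sectors.masks["Nose"] = np.zeros((4, 4), dtype=bool)
        with pytest.raises(ValueError, match="Nose"):
            cx.extract_complexion(img, sectors)

    def test_synthetic_face_means_within_sampling_error(self):
        spec = signals.FaceSpec(sector_sd=4.0)
        face = signals.generate_face_image(spec, seed=4)
        rec = cx.extract_complexion(face.image, face.sectors)
        for sector, (y, cr, cb) in face.true_means.items():
            n = int(face.sectors.masks[sector].sum())
            # 3 sigma / sqrt(n) sampling bound, plus 1 unit for 8-bit
            # quantization through the RGB round trip.
            tol = 3 * 4.0 / np.sqrt(n) + 1.0
            assert rec[f"{sector}_Y_avg"] == pytest.approx(y, abs=tol)
            assert rec[f"{sector}_Cr_avg"] == pytest.approx(cr, abs=tol)
            assert rec[f"{sector}_Cb_avg"] == pytest.approx(cb, abs=tol)

    def test_chart_correction_recovers_reference(self):
        M = np.array([[0.92, 0.05, 0.0],
                      [0.02, 1.08, 0.03],
                      [0.0, 0.04, 0.88]])
        spec = signals.FaceSpec(
            sector_sd=0.0, distortion=M,
            distortion_offset=np.array([5.0, -6.0, 4.0]))
        face = signals.generate_face_image(spec, seed=5)
        corrected, rms = cx.correct_color(
            face.image, face.observed_patches(), face.reference_patches)
        assert rms < 1.0  # within one intensity unit per patch

    def test_label_image_png_roundtrip(self, tmp_path):
        face = signals.generate_face_image(seed=6)
        img_path = tmp_path / "face.png"
        lab_path = tmp_path / "labels.png"
        signals.write_png(img_path, face.image)
        labels = np.zeros(face.image.shape[:2], dtype=np.uint8)
        atomic = ("FhL", "FhR", "ChLU", "ChLD", "ChRU", "ChRD", "Nose")
        for i, name in enumerate(atomic, start=1):
            labels[face.sectors.masks[name]] = i
        signals.write_png(lab_path, labels)
        img2 = signals.read_png(img_path)
        sectors2 = cx.SectorSet.from_label_image(
            signals.read_png(lab_path))
        rec = cx.extract_complexion(img2, sectors2)
        ref = cx.extract_complexion(face.image, face.sectors)
        assert rec == ref

    def test_invariant_violation_rejected(self):
        masks = {s: np.ones((4, 4), dtype=bool) for s in cx.SECTORS}
        masks["FhW"] = np.zeros((4, 4), dtype=bool)
        masks["FhW"][0, 0] = True  # no longer contains FhL | FhR
        with pytest.raises(ValueError, match="FhW"):
            cx.SectorSet(masks)
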