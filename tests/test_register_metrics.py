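"""Similarity metrics and transform plumbing against brute-force oracles."""

import numpy as np
import pytest

from coronalign.register import (
    AffineTransform,
    BSplineTransform,
    CompositeTransform,
    apply_transform,
    init_centered_affine,
    mattes_mi,
    neighborhood_correlation,
)


def entropy_mi_oracle(fixed, moving, bins):
    """Exhaustive joint-histogram MI: loop over pixels, count pairs, sum entropies."""
    f, m = fixed.ravel(), moving.ravel()
    fe = np.linspace(f.min(), f.max(), bins + 1)
    me = np.linspace(m.min(), m.max(), bins + 1)
    counts = {}
    for a, b in zip(f, m):
        i = min(np.searchsorted(fe, a, "right") - 1, bins - 1)
        j = min(np.searchsorted(me, b, "right") - 1, bins - 1)
        counts[(i, j)] = counts.get((i, j), 0) + 1
    n = len(f)
    px, py = {}, {}
    for (i, j), c in counts.items():
        px[i] = px.get(i, 0) + c
        py[j] = py.get(j, 0) + c
    mi = 0.0
    for (i, j), c in counts.items():
        p = c / n
        mi += p * np.log(p / (px[i] / n * py[j] / n))
    return mi


class TestMattesMI:
    def test_self_mi_equals_marginal_entropy_on_two_value_pattern(self):
        x = np.zeros((8, 8))
        x[::2] = 1.0  # 50/50 two-value pattern
        h = -(0.5 * np.log(0.5) + 0.5 * np.log(0.5))
        assert mattes_mi(x, x, bins=32) == pytest.approx(-h, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_oracle_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.random((16, 16))
        m = rng.random((16, 16))
        assert mattes_mi(f, m, bins=8) == pytest.approx(
            -entropy_mi_oracle(f, m, 8), abs=1e-6
        )

    def test_shuffled_image_carries_less_information(self):
        rng = np.random.default_rng(7)
        x = rng.random((16, 16))
        self_mi = mattes_mi(x, x)
        shuffled = []
        for _ in range(20):
            s = x.ravel().copy()
            rng.shuffle(s)
            shuffled.append(mattes_mi(x, s.reshape(16, 16)))
        assert self_mi <= np.mean(shuffled)  # negated: lower is more informative

    def test_full_mask_equals_no_mask(self):
        rng = np.random.default_rng(8)
        f, m = rng.random((12, 12)), rng.random((12, 12))
        assert mattes_mi(f, m, fixed_mask=np.ones((12, 12), bool)) == mattes_mi(f, m)

    def test_constant_pair_returns_zero(self):
        assert mattes_mi(np.ones((8, 8)), np.ones((8, 8))) == 0.0


class TestNeighborhoodCorrelation:
    def test_self_correlation_is_perfect(self):
        rng = np.random.default_rng(0)
        x = rng.random((16, 16))
        assert neighborhood_correlation(x, x, radius=3) == pytest.approx(-1.0, abs=1e-9)

    def test_invariant_to_positive_affine_intensity_map(self):
        rng = np.random.default_rng(1)
        x = rng.random((16, 16))
        assert neighborhood_correlation(x, 2.5 * x + 7.0, radius=2) == pytest.approx(
            -1.0, abs=1e-9
        )

    @pytest.mark.parametrize("radius", [1, 2, 3])
    def test_matches_per_window_pearson_oracle(self, radius):
        rng = np.random.default_rng(2)
        f, m = rng.random((16, 16)), rng.random((16, 16))
        got = neighborhood_correlation(f, m, radius=radius)
        vals = []
        for i in range(radius, 16 - radius):
            for j in range(radius, 16 - radius):
                wf = f[i - radius:i + radius + 1, j - radius:j + radius + 1].ravel()
                wm = m[i - radius:i + radius + 1, j - radius:j + radius + 1].ravel()
                if wf.std() > 0 and wm.std() > 0:
                    vals.append(np.corrcoef(wf, wm)[0, 1])
        assert got == pytest.approx(-np.mean(vals), abs=1e-6)

    def test_rejects_image_smaller_than_window(self):
        with pytest.raises(ValueError):
            neighborhood_correlation(np.ones((4, 4)), np.ones((4, 4)), radius=3)


class TestInitCenteredAffine:
    def test_identical_images_give_zero_translation(self):
        rng = np.random.default_rng(3)
        img = rng.random((32, 32))
        t = init_centered_affine(img, img)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-9)
        np.testing.assert_array_equal(t.matrix, np.eye(2))

    def test_pure_shift_recovered_in_resampling_sense(self):
        # moving = fixed content displaced by +10 columns -> the resampling
        # map (fixed frame -> moving frame) carries translation +10 in x.
        fixed = np.zeros((32, 32))
        fixed[10:20, 5:15] = 1.0
        moving = np.roll(fixed, 10, axis=1)
        t = init_centered_affine(fixed, moving)
        np.testing.assert_allclose(t.translation, (10.0, 0.0), atol=1e-9)

    def test_empty_moving_falls_back_to_geometric_centre(self, caplog):
        fixed = np.zeros((20, 20))
        fixed[5:9, 5:9] = 1.0
        with caplog.at_level("WARNING"):
            t = init_centered_affine(fixed, np.zeros((20, 20)))
        assert "geometric" in caplog.text
        np.testing.assert_allclose(t.translation, np.array([9.5, 9.5]) - [6.5, 6.5])


class TestApplyTransform:
    def test_identity_composite_preserves_image(self):
        rng = np.random.default_rng(4)
        img = rng.random((40, 40)).astype(np.float32)
        t = CompositeTransform(AffineTransform(), None, 40, 0)
        np.testing.assert_allclose(apply_transform(img, t), img, atol=1e-5)

    def test_nearest_on_labels_invents_no_ids(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 5, (40, 40)).astype(np.int32)
        t = CompositeTransform(
            AffineTransform(matrix=[[1.1, 0.05], [-0.03, 0.95]],
                            translation=[2.0, -1.0], center=[19.5, 19.5]),
            None, 40, 0,
        )
        warped = apply_transform(labels, t, "nearest")
        assert warped.dtype == labels.dtype
        assert set(np.unique(warped)) <= set(np.unique(labels)) | {0}

    def test_translation_moves_impulse_exactly(self):
        img = np.zeros((21, 21), dtype=np.float32)
        img[10, 10] = 1.0
        # Resampling map x -> x+3: output pixel p reads input at p+3, so the
        # impulse appears at column 7.
        t = AffineTransform(translation=[3.0, 0.0])
        out = apply_transform(img, t)
        assert out[10, 7] == pytest.approx(1.0, abs=1e-6)
        assert out[10, 10] == pytest.approx(0.0, abs=1e-6)

    def test_rejects_unknown_interpolation(self):
        with pytest.raises(ValueError):
            apply_transform(np.ones((8, 8)), AffineTransform(), "cubic")


class TestSerialization:
    def test_composite_roundtrip_is_exact(self, tmp_path):
        rng = np.random.default_rng(6)
        affine = AffineTransform(matrix=[[1.02, 0.03], [-0.01, 0.98]],
                                 translation=[4.2, -1.7], center=[229.5, 229.5])
        import SimpleITK as sitk
        init = sitk.BSplineTransformInitializer(
            sitk.Image(100, 100, sitk.sitkFloat32), [4, 4]
        )
        bspline = BSplineTransform(
            mesh_size=(4, 4),
            fixed_parameters=tuple(init.GetFixedParameters()),
            parameters=rng.normal(size=len(init.GetParameters())),
        )
        t = CompositeTransform(affine, bspline, 360, 50)
        path = tmp_path / "t.json"
        t.to_json(path)
        back = CompositeTransform.from_json(path)
        np.testing.assert_array_equal(back.affine.matrix, t.affine.matrix)
        np.testing.assert_array_equal(back.affine.translation, t.affine.translation)
        np.testing.assert_array_equal(back.bspline.parameters, t.bspline.parameters)
        assert back.bspline.fixed_parameters == t.bspline.fixed_parameters
        assert (back.working_size, back.pad_px) == (360, 50)
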