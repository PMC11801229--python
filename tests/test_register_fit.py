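"""Registration fitting: identity/rotation/scale recovery, B-spline refinement.

These tests run the full fitting machinery at a reduced working size so they
stay fast; the default-resolution behaviour is exercised by the acceptance
suite.
"""

import numpy as np
import pytest
import SimpleITK as sitk

from coronalign.evaluate import dice
from coronalign.preprocess import match_histogram, pad_pair, to_gradient, resize_working
from coronalign.register import (
    AffineTransform,
    CompositeTransform,
    OptimizerConfig,
    apply_transform,
    fit_affine,
    fit_bspline,
    register_composite,
)
from coronalign.synthetic import DeformationSpec, make_deformed_section


def prepped_pair(fixed_img, moving_img, cfg):
    fx = to_gradient(resize_working(fixed_img, cfg.working_size))
    mv = to_gradient(resize_working(moving_img, cfg.working_size))
    fx, mv = pad_pair(fx, mv, cfg.pad_px)
    return fx, match_histogram(mv, fx, cfg)


def native_matrix(working_A, native_shape, working_size):
    """Undo the anisotropic working-frame resize: A_native = S^-1 A S."""
    h, w = native_shape
    s = np.diag([working_size / w, working_size / h])
    return np.linalg.inv(s) @ working_A @ s


class TestAffineRecovery:
    def test_identity_pair_recovers_identity(self, mid_section, fast_cfgs):
        pre, opt = fast_cfgs
        fx, mv = prepped_pair(mid_section.image, mid_section.image, pre)
        t = fit_affine(fx, mv, opt)
        assert np.abs(t.matrix - np.eye(2)).max() < 1e-2
        assert np.linalg.norm(t.translation) < 0.5

    def test_five_degree_rotation_recovered(self, phantom, mid_pose, mid_section, fast_cfgs):
        pre, opt = fast_cfgs
        sec, _ = make_deformed_section(phantom, mid_pose, DeformationSpec(rotation_deg=5.0))
        fx, mv = prepped_pair(sec.image, mid_section.image, pre)
        t = fit_affine(fx, mv, opt)
        a = native_matrix(t.matrix, sec.image.shape, pre.working_size)
        angle = np.rad2deg(np.arctan2(a[1, 0], a[0, 0]))
        assert abs(angle - 5.0) < 0.5

    def test_ten_percent_scale_recovered(self, phantom, mid_pose, mid_section, fast_cfgs):
        pre, opt = fast_cfgs
        sec, _ = make_deformed_section(phantom, mid_pose, DeformationSpec(scale=1.1))
        fx, mv = prepped_pair(sec.image, mid_section.image, pre)
        t = fit_affine(fx, mv, opt)
        a = native_matrix(t.matrix, sec.image.shape, pre.working_size)
        scale = np.sqrt(abs(np.linalg.det(a)))
        assert 1.08 <= scale <= 1.12

    def test_objective_does_not_increase_overall(self, phantom, mid_pose, mid_section, fast_cfgs):
        pre, opt = fast_cfgs
        sec, _ = make_deformed_section(
            phantom, mid_pose, DeformationSpec(rotation_deg=3.0, translation_px=(4, 2))
        )
        fx, mv = prepped_pair(sec.image, mid_section.image, pre)
        log = []
        fit_affine(fx, mv, opt, log=log)
        # final level: descent must not end worse than it started
        last_level = log[-1][0]
        level_vals = [m for lvl, _, m in log if lvl == last_level]
        assert level_vals[-1] <= level_vals[0] + 1e-9


class TestBsplineRecovery:
    def test_identity_pair_gives_subpixel_control_points(self, mid_section, fast_cfgs):
        pre, opt = fast_cfgs
        fx, mv = prepped_pair(mid_section.image, mid_section.image, pre)
        b = fit_bspline(fx, mv, opt)
        assert np.abs(b.parameters).max() < 0.5

    def test_known_bulge_recovered_within_one_px_rms(self, mid_section, fast_cfgs):
        pre, opt = fast_cfgs
        base = prepped_pair(mid_section.image, mid_section.image, pre)[0]
        n = base.shape[0]
        init = sitk.BSplineTransformInitializer(
            sitk.Image(n, n, sitk.sitkFloat32), list(opt.bspline_mesh)
        )
        rng = np.random.default_rng(12)
        true_params = rng.uniform(-4.0, 4.0, len(init.GetParameters()))
        true_tx = sitk.BSplineTransform(2, 3)
        true_tx.SetFixedParameters(init.GetFixedParameters())
        true_tx.SetParameters(true_params.tolist())
        ref = sitk.GetImageFromArray(base)
        deformed = sitk.GetArrayFromImage(
            sitk.Resample(ref, ref, true_tx, sitk.sitkLinear, 0.0)
        )
        fitted = fit_bspline(deformed, base, opt)
        # Compare displacement fields (parameterizations may differ slightly).
        pts = [(float(x), float(y)) for y in range(10, n - 10, 25)
               for x in range(10, n - 10, 25)]
        ft = fitted.to_sitk()
        errs = []
        for p in pts:
            dt = np.subtract(true_tx.TransformPoint(p), p)
            df = np.subtract(ft.TransformPoint(p), p)
            errs.append(np.linalg.norm(dt - df))
        assert np.sqrt(np.mean(np.square(errs))) < 1.0


class TestCompositeApplication:
    def test_single_resample_matches_sequential(self, mid_section, fast_cfgs):
        pre, opt = fast_cfgs
        from scipy import ndimage

        rng = np.random.default_rng(3)
        n = pre.working_size + 2 * pre.pad_px
        img = np.zeros((n, n), dtype=np.float32)
        img[40:190, 60:170] = rng.random((150, 110)).astype(np.float32)
        # smooth so the double-interpolation error of the sequential path is
        # negligible and only the composition order is being compared
        img = ndimage.gaussian_filter(img, 6.0).astype(np.float32)
        affine = AffineTransform(matrix=[[1.03, 0.02], [-0.02, 0.97]],
                                 translation=[3.0, -2.0],
                                 center=[(n - 1) / 2] * 2)
        init = sitk.BSplineTransformInitializer(
            sitk.Image(n, n, sitk.sitkFloat32), [4, 4]
        )
        from coronalign.register import BSplineTransform
        bspline = BSplineTransform(
            (4, 4), tuple(init.GetFixedParameters()),
            rng.uniform(-3, 3, len(init.GetParameters())),
        )
        composite = CompositeTransform(affine, bspline, pre.working_size, pre.pad_px)
        oneshot = apply_transform(img, composite)
        sequential = apply_transform(apply_transform(img, affine), bspline)
        assert np.abs(oneshot - sequential).mean() < 1e-4


class TestRegisterComposite:
    def test_self_registration_recovers_labels(self, mid_section, fast_cfgs):
        pre, opt = fast_cfgs
        res = register_composite(mid_section, mid_section, pre_cfg=pre, opt_cfg=opt)
        assert dice(res.warped_labels > 0, mid_section.labels > 0) >= 0.99
        assert np.abs(res.transform.affine.matrix - np.eye(2)).max() < 1e-2

    def test_warped_labels_subset_of_atlas_ids(self, phantom, mid_pose, mid_section, fast_cfgs):
        pre, opt = fast_cfgs
        sec, _ = make_deformed_section(
            phantom, mid_pose,
            DeformationSpec(rotation_deg=3, translation_px=(5, -3),
                            bspline_amplitude_px=4, noise_sigma=5, seed=2),
        )
        res = register_composite(sec, mid_section, pre_cfg=pre, opt_cfg=opt)
        assert set(np.unique(res.warped_labels)) <= set(np.unique(mid_section.labels)) | {0}

    def test_mask_shape_mismatch_raises(self, mid_section, fast_cfgs):
        pre, opt = fast_cfgs
        with pytest.raises(ValueError, match="mask"):
            register_composite(mid_section, mid_section,
                               mask=np.zeros((5, 5), bool), pre_cfg=pre, opt_cfg=opt)

    def test_deterministic_transforms(self, phantom, mid_pose, mid_section, fast_cfgs):
        pre, opt = fast_cfgs
        sec, _ = make_deformed_section(
            phantom, mid_pose, DeformationSpec(rotation_deg=2, seed=1)
        )
        a = register_composite(sec, mid_section, pre_cfg=pre, opt_cfg=opt)
        b = register_composite(sec, mid_section, pre_cfg=pre, opt_cfg=opt)
        np.testing.assert_array_equal(a.transform.affine.matrix, b.transform.affine.matrix)
        np.testing.assert_array_equal(a.transform.bspline.parameters,
                                      b.transform.bspline.parameters)
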