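"""Background phase-offset correction, mask resampling and LV volumetrics."""

import numpy as np
import pytest

from lv4dflow import (
    VelocityField4D,
    apply_phase_correction,
    compute_volumetric_indices,
    fit_background_polynomial,
    identify_static_tissue,
    resample_ed_mask,
)
from lv4dflow.flow_io import LVSegmentation
from lv4dflow.phantom import PhantomSpec, ellipsoid_mask, generate_phantom
from lv4dflow.preprocess import polynomial_basis, polynomial_exponents


def zero_field(shape=(12, 12, 12), nt=4, spacing=3.0):
    return VelocityField4D(np.zeros((*shape, nt, 3)), spacing, 52.0)


def field_with_offset(coef, shape=(12, 12, 12), nt=4):
    """Static field carrying a polynomial offset defined in the scaled basis."""
    fld = zero_field(shape, nt)
    half = (np.asarray(shape) - 1) / 2.0 * fld.voxel_spacing
    X = polynomial_basis(fld.voxel_centers(), fld.origin + half, half)
    offset = (X @ np.asarray(coef).T).reshape(*shape, 3)
    data = np.repeat(offset[:, :, :, None, :], nt, axis=3)
    return fld.copy_with(data=data)


class TestStaticTissue:
    def test_phantom_background_identified(self, reference_dataset):
        ds = reference_dataset
        mask = identify_static_tissue(ds.field, 2.0)
        truth_bg = ds.truth.static_mask
        # all of the true rest region is picked up; the bulk of the moving
        # chamber is excluded (slow near-stagnation voxels legitimately
        # qualify under a pure variance threshold)
        assert np.all(mask[truth_bg])
        assert mask[ds.segmentation.ed_mask_cine].mean() < 0.25

    def test_zero_threshold_raises(self):
        rng = np.random.default_rng(0)
        fld = VelocityField4D(rng.normal(0, 5, (8, 8, 8, 3, 3)), 3.0, 52.0)
        with pytest.raises(ValueError, match="increase threshold"):
            identify_static_tissue(fld, 0.0)

    def test_gaussian_noise_background_selected(self):
        # sigma = 1 cm/s, threshold 3 cm/s: nearly all rest voxels qualify
        rng = np.random.default_rng(42)
        fld = VelocityField4D(rng.normal(0, 1.0, (16, 16, 16, 8, 3)), 3.0, 52.0)
        mask = identify_static_tissue(fld, 3.0)
        assert mask.mean() >= 0.99


class TestPolynomialFit:
    def test_constant_plus_linear_recovered(self):
        coef = np.zeros((3, 20))
        coef[0, 0] = 0.8    # constant term, x-direction
        coef[0, 1] = 0.002  # leading linear term
        fld = field_with_offset(coef)
        model = fit_background_polynomial(fld, np.ones(fld.grid_shape, bool))
        np.testing.assert_allclose(model.coefficients, coef, atol=1e-9)

    def test_zero_field_gives_null_model(self):
        model = fit_background_polynomial(
            zero_field(), np.ones((12, 12, 12), bool)
        )
        assert np.abs(model.coefficients).max() < 1e-9

    def test_full_cubic_recovered_exactly(self):
        rng = np.random.default_rng(7)
        coef = rng.normal(0, 0.5, (3, 20))
        fld = field_with_offset(coef)
        model = fit_background_polynomial(fld, np.ones(fld.grid_shape, bool))
        np.testing.assert_allclose(model.coefficients, coef, rtol=1e-6, atol=1e-9)

    def test_injected_offset_recovered_on_phantom(self):
        rng = np.random.default_rng(7)
        coef = rng.normal(0, 0.3, (3, 20))
        fld, seg, truth = generate_phantom(PhantomSpec(background_poly=coef))
        model = fit_background_polynomial(fld, truth.static_mask)
        np.testing.assert_allclose(model.coefficients, coef, rtol=1e-6, atol=1e-8)

    def test_too_few_static_voxels(self):
        fld = zero_field()
        mask = np.zeros(fld.grid_shape, bool)
        mask[0, 0, :10] = True
        with pytest.raises(ValueError, match="at least 200"):
            fit_background_polynomial(fld, mask)

    def test_coplanar_static_voxels_rank_deficient(self):
        fld = zero_field(shape=(24, 24, 24))
        mask = np.zeros(fld.grid_shape, bool)
        mask[:, :, 5] = True  # a single plane cannot pin z-dependence
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_background_polynomial(fld, mask)

    def test_basis_has_twenty_cubic_terms(self):
        expo = polynomial_exponents(3)
        assert len(expo) == 20
        assert expo.sum(axis=1).max() == 3


class TestCorrection:
    def test_correction_is_projection(self):
        rng = np.random.default_rng(11)
        coef = rng.normal(0, 0.4, (3, 20))
        fld = field_with_offset(coef)
        mask = np.ones(fld.grid_shape, bool)
        corrected = apply_phase_correction(fld, fit_background_polynomial(fld, mask))
        refit = fit_background_polynomial(corrected, mask)
        assert np.abs(refit.coefficients).max() < 1e-9

    def test_zero_model_leaves_field_bitwise(self, reference_dataset):
        from lv4dflow.preprocess import PolynomialOffsetModel

        fld = reference_dataset.field
        model = PolynomialOffsetModel(
            np.zeros((3, 20)), np.zeros(3), np.ones(3)
        )
        out = apply_phase_correction(fld, model)
        np.testing.assert_array_equal(out.data, fld.data)

    def test_temporal_differences_preserved_exactly(self):
        rng = np.random.default_rng(13)
        coef = rng.normal(0, 0.4, (3, 20))
        base = VelocityField4D(rng.normal(0, 5, (10, 10, 10, 4, 3)), 3.0, 52.0)
        model_fld = field_with_offset(coef, shape=(10, 10, 10))
        fld = base.copy_with(data=base.data + model_fld.data)
        model = fit_background_polynomial(
            field_with_offset(coef, (10, 10, 10)), np.ones((10, 10, 10), bool)
        )
        corrected = apply_phase_correction(fld, model)
        d_before = fld.data[..., 1, :] - fld.data[..., 3, :]
        d_after = corrected.data[..., 1, :] - corrected.data[..., 3, :]
        np.testing.assert_allclose(d_before, d_after, atol=1e-12)

    def test_corrected_phantom_background_below_noise_floor(self):
        rng = np.random.default_rng(19)
        coef = rng.normal(0, 0.3, (3, 20))
        spec = PhantomSpec(background_poly=coef, noise_sigma=1.0, seed=19)
        fld, seg, truth = generate_phantom(spec)
        model = fit_background_polynomial(fld, truth.static_mask)
        corrected = apply_phase_correction(fld, model)
        bg_mean_speed = np.linalg.norm(
            corrected.data[truth.static_mask].mean(axis=1), axis=-1
        ).mean()
        assert bg_mean_speed <= 1.0  # at or below the injected noise sd


class TestResampling:
    def test_identity_on_matching_grids(self, reference_dataset):
        ds = reference_dataset
        out = resample_ed_mask(ds.segmentation, ds.field)
        np.testing.assert_array_equal(out, ds.segmentation.ed_mask_cine)

    def test_anisotropic_cine_ellipsoid_volume(self):
        # 1.5 x 1.5 x 8 mm cine mask of an ellipsoid resampled at 3 mm
        semi = (40.0, 35.0, 30.0)
        analytic_ml = 4.0 / 3.0 * np.pi * np.prod(semi) / 1000.0
        cine_sp = (1.5, 1.5, 8.0)
        cine_shape = (80, 80, 16)
        center = tuple((np.array(cine_shape) - 1) / 2 * cine_sp)
        cine = ellipsoid_mask(cine_shape, cine_sp, center, semi)
        es = np.zeros((40, 40, 40), dtype=bool)
        es[18:22, 18:22, 18:22] = True
        seg = LVSegmentation(cine, es, 0, 8, cine_spacing=cine_sp)
        fld = zero_field(shape=(40, 40, 40))
        out = resample_ed_mask(seg, fld)
        resampled_ml = out.sum() * fld.voxel_volume_ml
        assert resampled_ml == pytest.approx(analytic_ml, rel=0.05)

    def test_resampled_volume_converges_with_cine_resolution(self):
        semi = (40.0, 35.0, 30.0)
        analytic_ml = 4.0 / 3.0 * np.pi * np.prod(semi) / 1000.0
        shift = np.array([0.7, 1.1, 2.3])  # break lattice-symmetry luck
        errs = []
        for cine_sp, cine_shape in (((6.0, 6.0, 12.0), (22, 22, 12)),
                                    ((1.0, 1.0, 2.0), (124, 124, 66))):
            center = (np.array(cine_shape) - 1) / 2 * np.array(cine_sp) + shift
            cine = ellipsoid_mask(cine_shape, cine_sp, tuple(center), semi)
            es = np.zeros((44, 44, 44), dtype=bool)
            es[18:22, 18:22, 18:22] = True
            seg = LVSegmentation(cine, es, 0, 8, cine_spacing=cine_sp)
            out = resample_ed_mask(seg, zero_field(shape=(44, 44, 44)))
            errs.append(abs(out.sum() * 0.027 - analytic_ml) / analytic_ml)
        assert errs[1] < errs[0]
        assert errs[1] < 0.01

    def test_disjoint_grids_raise(self):
        cine = np.ones((4, 4, 4), dtype=bool)
        es = np.ones((4, 4, 4), dtype=bool)
        es[0] = False
        seg = LVSegmentation(
            cine, es, 0, 8, cine_spacing=3.0, cine_origin=(1000.0, 0.0, 0.0)
        )
        with pytest.raises(ValueError, match="do not overlap"):
            resample_ed_mask(seg, zero_field(shape=(8, 8, 8)))


class TestVolumetrics:
    def test_printed_cohort_worked_example(self):
        # EDV 155 ml / ESV 52 ml at 3 mm voxels
        n_ed = round(155.0 / 0.027)
        n_es = round(52.0 / 0.027)
        ed = np.zeros(8000, bool)
        ed[:n_ed] = True
        es = np.zeros(8000, bool)
        es[:n_es] = True
        idx = compute_volumetric_indices(
            ed.reshape(20, 20, 20), es.reshape(20, 20, 20), 0.027, heart_rate=65.0
        )
        assert idx.sv == pytest.approx(103.0, abs=0.1)
        assert idx.ef == pytest.approx(66.5, abs=0.2)
        assert idx.cardiac_output == pytest.approx(6.70, abs=0.02)

    def test_swapped_masks_raise(self):
        ed = np.zeros((4, 4, 4), bool)
        ed[:2] = True
        with pytest.raises(ValueError, match="swapped"):
            compute_volumetric_indices(ed, ed, 0.027, 60.0)

    def test_identities_hold(self, reference_analysis):
        idx = reference_analysis.indices
        assert idx.sv + idx.esv == pytest.approx(idx.edv, abs=1e-9)
        assert 0.0 < idx.ef < 100.0
        assert idx.cardiac_output == pytest.approx(
            idx.sv * reference_analysis.subject.heart_rate / 1000.0
        )
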