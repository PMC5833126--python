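"""Container invariants, IO round-trips, and the spatiotemporal sampler."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lv4dflow import (
    LVSegmentation,
    SubjectRecord,
    VelocityField4D,
    load_velocity_field,
    read_component_table,
    sample_velocity,
    save_velocity_field,
    write_component_table,
)
from lv4dflow.flow_io import (
    containing_voxel,
    mask_lookup,
    save_velocity_field_nifti,
)


def random_field(seed=0, shape=(6, 5, 4), nt=5):
    rng = np.random.default_rng(seed)
    data = rng.normal(0, 10, (*shape, nt, 3))
    return VelocityField4D(data, (3.0, 3.0, 3.0), 52.0, venc=100.0)


class TestVelocityField4D:
    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match="n_frames must be >= 2"):
            VelocityField4D(np.zeros((4, 4, 4, 1, 3)), 3.0, 52.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(voxel_spacing=-1.0, frame_interval=52.0),
            dict(voxel_spacing=3.0, frame_interval=0.0),
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VelocityField4D(np.zeros((4, 4, 4, 2, 3)), **kwargs)

    def test_venc_violation_warns_not_raises(self):
        data = np.zeros((4, 4, 4, 2, 3))
        data[0, 0, 0, 0, 0] = 150.0
        with pytest.warns(UserWarning, match="exceed venc"):
            fld = VelocityField4D(data, 3.0, 52.0, venc=100.0)
        assert fld.n_frames == 2

    def test_cycle_length_and_voxel_volume(self):
        fld = random_field()
        assert fld.cycle_length == 5 * 52.0
        assert fld.voxel_volume_ml == pytest.approx(0.027)


class TestRoundTrips:
    def test_npz_round_trip(self, tmp_path):
        fld = random_field()
        path = save_velocity_field(fld, tmp_path / "vel.npz")
        back = load_velocity_field(path)
        np.testing.assert_array_equal(back.data, fld.data)
        assert back.frame_interval == fld.frame_interval
        assert back.venc == fld.venc

    def test_nifti_matches_npz_route(self, tmp_path):
        fld = random_field()
        npz = load_velocity_field(save_velocity_field(fld, tmp_path / "vel.npz"))
        paths = save_velocity_field_nifti(fld, tmp_path / "vel")
        nii = load_velocity_field([p for p in paths if p.suffix == ".gz"])
        np.testing.assert_allclose(nii.data, npz.data, rtol=1e-6)
        assert nii.frame_interval == npz.frame_interval
        assert nii.venc == npz.venc

    def test_missing_npz_keys(self, tmp_path):
        np.savez(tmp_path / "bad.npz", data=np.zeros((4, 4, 4, 2, 3)))
        with pytest.raises(ValueError, match="missing keys"):
            load_velocity_field(tmp_path / "bad.npz")

    def test_nifti_without_timing_metadata(self, tmp_path):
        import nibabel as nib

        arr = np.zeros((4, 4, 4, 2))
        for d in "xyz":
            img = nib.Nifti1Image(arr, np.eye(4))
            img.header.set_zooms((1.0, 1.0, 1.0, 0.0))  # no frame timing
            nib.save(img, tmp_path / f"v{d}.nii.gz")
        with pytest.raises(ValueError, match="frame_interval"):
            load_velocity_field(
                [tmp_path / f"v{d}.nii.gz" for d in "xyz"], format="nifti4d",
                sidecar={},
            )


class TestSampler:
    def test_voxel_centre_identity(self, small_uniform_field):
        fld = small_uniform_field
        v, oob = sample_velocity(fld, np.array([9.0, 9.0, 9.0]), 52.0)
        np.testing.assert_allclose(v, [10.0, 0.0, 0.0])
        assert not oob

    def test_periodicity_exact(self):
        fld = random_field(3)
        p = np.array([[7.3, 6.1, 5.2], [1.0, 2.0, 3.0]])
        for k in (-2, 1, 5):
            v0, _ = sample_velocity(fld, p, 37.0)
            vk, _ = sample_velocity(fld, p, 37.0 + k * fld.cycle_length)
            np.testing.assert_allclose(v0, vk, atol=1e-12)

    def test_midpoint_is_mean_of_neighbours(self):
        fld = random_field(4)
        p_mid = np.array([4.5, 6.0, 6.0])  # halfway between x-neighbours
        v_mid, _ = sample_velocity(fld, p_mid, 0.0)
        v_a, _ = sample_velocity(fld, np.array([3.0, 6.0, 6.0]), 0.0)
        v_b, _ = sample_velocity(fld, np.array([6.0, 6.0, 6.0]), 0.0)
        np.testing.assert_allclose(v_mid, (v_a + v_b) / 2, atol=1e-12)

    def test_outside_grid_zero_with_flag(self):
        fld = random_field(5)
        v, oob = sample_velocity(fld, np.array([-50.0, 0.0, 0.0]), 0.0)
        assert oob
        np.testing.assert_array_equal(v, 0.0)

    @settings(max_examples=30, deadline=None)
    @given(
        x=st.floats(0, 15), y=st.floats(0, 12), z=st.floats(0, 9),
        t=st.floats(0, 260),
    )
    def test_convex_combination_of_stored_values(self, x, y, z, t):
        fld = random_field(6)
        v, oob = sample_velocity(fld, np.array([x, y, z]), t)
        assert not oob
        for d in range(3):
            lo, hi = fld.data[..., d].min(), fld.data[..., d].max()
            assert lo - 1e-9 <= v[d] <= hi + 1e-9


class TestMaskLookup:
    def test_face_point_belongs_to_lower_voxel(self):
        # boundary at 1.5 mm between voxels 0 and 1 (3 mm spacing)
        idx = containing_voxel(np.array([[1.5, 0.0, 0.0]]), np.zeros(3), np.full(3, 3.0))
        assert idx[0, 0] == 0
        idx = containing_voxel(np.array([[1.5001, 0.0, 0.0]]), np.zeros(3), np.full(3, 3.0))
        assert idx[0, 0] == 1

    def test_outside_positions_are_outside_mask(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        inside = mask_lookup(np.array([[100.0, 0, 0], [3.0, 3.0, 3.0]]),
                             mask, np.zeros(3), np.full(3, 3.0))
        assert list(inside) == [False, True]


class TestSegmentation:
    def test_same_frames_rejected(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[1:3, 1:3, 1:3] = True
        with pytest.raises(ValueError, match="must differ"):
            LVSegmentation(m, m, 3, 3)

    def test_disconnected_mask_warns(self):
        m = np.zeros((6, 6, 6), dtype=bool)
        m[0, 0, 0] = True
        m[5, 5, 5] = True
        es = np.zeros_like(m)
        es[2, 2, 2] = True
        with pytest.warns(UserWarning, match="connected components"):
            LVSegmentation(m, es, 0, 8)

    def test_heart_rate_must_be_positive(self):
        with pytest.raises(ValueError):
            SubjectRecord("s1", heart_rate=0.0)


class TestComponentTable:
    def test_round_trip_and_multi_visit(self, tmp_path, reference_analysis):
        row1 = reference_analysis.table_row()
        row2 = dict(row1, visit="scan2")
        path = tmp_path / "components.csv"
        write_component_table([row1, row2], path)
        back = read_component_table(path)
        assert len(back) == 2
        assert set(back["subject_id"]) == {row1["subject_id"]}
        for col, val in row1.items():
            if isinstance(val, float) and np.isfinite(val):
                assert back[col][0] == pytest.approx(val, rel=1e-6)

    def test_empty_results_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="no results"):
            write_component_table([], tmp_path / "x.csv")
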