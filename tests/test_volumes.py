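"""Grid geometry, interpolation, resampling and warping primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atlasseg.metrics import dice
from atlasseg.volumes import (
    BinaryMask,
    DisplacementField,
    ImageVolume,
    RigidTransform3D,
    apply_displacement,
    apply_rigid,
    compose_rigid_and_field,
    project_mean,
    read_field,
    read_mask,
    read_volume,
    trilinear_sample,
    voxel_to_world,
    world_to_voxel,
    write_field,
    write_mask,
    write_volume,
)


def vol(data, spacing=(1, 1, 1), origin=(0, 0, 0)):
    return ImageVolume(np.asarray(data, dtype=float), spacing, origin)


class TestCoordinates:
    @pytest.mark.parametrize(
        "origin,spacing,index,expected",
        [
            ((0, 0, 0), (2, 2, 2), (0, 0, 0), (0, 0, 0)),
            ((10, 0, 0), (2, 2, 2), (1, 2, 3), (12, 4, 6)),
            ((0, 0, -30), (1, 1, 3), (5, 5, 10), (5, 5, 0)),
        ],
    )
    def test_voxel_to_world_linear_map(self, origin, spacing, index, expected):
        v = ImageVolume(np.zeros((8, 8, 12)), spacing, origin)
        assert np.allclose(voxel_to_world(index, v), expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        spacing=st.tuples(*[st.floats(0.25, 10.0) for _ in range(3)]),
        origin=st.tuples(*[st.floats(-500.0, 500.0) for _ in range(3)]),
        index=st.tuples(*[st.integers(0, 7) for _ in range(3)]),
    )
    def test_round_trip_property(self, spacing, origin, index):
        v = ImageVolume(np.zeros((8, 8, 8)), spacing, origin)
        w = voxel_to_world(index, v)
        assert np.allclose(world_to_voxel(w, v), index, atol=1e-6)

    def test_round_trip_exact(self, rng):
        v = ImageVolume(np.zeros((5, 6, 7)), (1.5, 2.0, 3.25), (-12.0, 4.0, 9.5))
        for _ in range(50):
            idx = tuple(rng.integers(0, s) for s in v.shape)
            w = voxel_to_world(idx, v)
            assert np.allclose(world_to_voxel(w, v), idx, atol=1e-9)

    def test_out_of_extent_index_rejected(self):
        v = vol(np.zeros((4, 4, 4)))
        with pytest.raises(IndexError):
            voxel_to_world((4, 0, 0), v)

    def test_invariants_rejected(self):
        with pytest.raises(ValueError):
            ImageVolume(np.zeros((4, 4)), (1, 1, 1), (0, 0, 0))
        with pytest.raises(ValueError):
            ImageVolume(np.zeros((4, 4, 4)), (1, 0, 1), (0, 0, 0))


class TestTrilinear:
    def test_voxel_center_identity(self, rng):
        data = rng.normal(size=(5, 5, 5))
        v = vol(data, spacing=(2, 2, 2))
        assert trilinear_sample(v, (4.0, 2.0, 6.0)) == pytest.approx(data[2, 1, 3])

    def test_midpoint_is_average(self):
        data = np.zeros((3, 3, 3))
        data[1, 1, 1] = 0.0
        data[2, 1, 1] = 10.0
        v = vol(data)
        assert trilinear_sample(v, (1.5, 1.0, 1.0)) == pytest.approx(5.0)

    def test_outside_returns_fill(self):
        v = vol(np.ones((4, 4, 4)))
        assert trilinear_sample(v, (-1.0, 0.0, 0.0), fill=-1000) == -1000.0


class TestProjections:
    def test_constant_volume(self):
        v = vol(np.full((6, 5, 4), 7.0))
        img, sp = project_mean(v, "sagittal")
        assert img.shape == (5, 4) and np.allclose(img, 7.0)

    def test_single_voxel_mean(self):
        data = np.zeros((4, 3, 3))
        data[2, 1, 1] = 4.0
        img, _ = project_mean(vol(data), "sagittal")
        assert img[1, 1] == pytest.approx(1.0)  # mean of (0, 0, 4, 0)

    def test_matches_loop_oracle(self, rng):
        data = rng.normal(size=(8, 8, 8))
        v = vol(data, spacing=(1, 2, 3))
        for axis, a in (("sagittal", 0), ("coronal", 1)):
            img, sp = project_mean(v, axis)
            oracle = np.zeros(img.shape)
            for idx in np.ndindex(*img.shape):
                line = [data[(k,) + idx if a == 0 else (idx[0], k, idx[1])] for k in range(data.shape[a])]
                oracle[idx] = sum(line) / len(line)
            assert np.allclose(img, oracle, atol=1e-12)
            assert np.allclose(sp, np.delete(v.spacing, a))

    def test_invalid_axis(self):
        with pytest.raises(ValueError):
            project_mean(vol(np.zeros((2, 2, 2))), "axial")


class TestApplyDisplacement:
    def test_zero_field_identity(self, rng):
        mask = BinaryMask(rng.random((6, 6, 6)) > 0.6, (2, 2, 2), (0, 0, 0))
        fld = DisplacementField.zeros_like(mask)
        out = apply_displacement(mask, fld)
        assert np.array_equal(out.data, mask.data)

    def test_integer_voxel_shift(self, rng):
        mask = BinaryMask(rng.random((8, 8, 8)) > 0.5, (2, 2, 2), (0, 0, 0))
        vec = np.zeros((8, 8, 8, 3))
        vec[..., 0] = 2.0  # exactly one voxel in x
        out = apply_displacement(mask, DisplacementField(vec, (2, 2, 2), (0, 0, 0)))
        # output voxel i samples source at i+1
        assert np.array_equal(out.data[:-1], mask.data[1:])
        assert not out.data[-1].any()  # outside -> background

    def test_matches_brute_force_resample(self, rng):
        from scipy.ndimage import gaussian_filter

        data = rng.normal(size=(8, 8, 8))
        v = vol(data, spacing=(2, 2, 2))
        vec = gaussian_filter(rng.normal(size=(8, 8, 8, 3)), sigma=(2, 2, 2, 0)) * 3
        fld = DisplacementField(vec, (2, 2, 2), (0, 0, 0))
        out = apply_displacement(v, fld)
        for idx in [(0, 0, 0), (3, 4, 5), (7, 7, 7), (2, 6, 1)]:
            p = np.asarray(idx) * 2.0 + vec[idx]
            assert out.data[idx] == pytest.approx(trilinear_sample(v, p, fill=-1000), abs=1e-9)

    def test_geometry_mismatch_rejected(self):
        mask = BinaryMask(np.ones((4, 4, 4), bool), (1, 1, 1), (0, 0, 0))
        fld = DisplacementField(np.zeros((4, 4, 4, 3)), (2, 2, 2), (0, 0, 0))
        out = apply_displacement(mask, fld)   # field grid wins: resample onto it
        assert out.spacing[0] == 2.0


class TestApplyRigid:
    def test_identity_noop_nearest(self, rng):
        mask = BinaryMask(rng.random((6, 6, 6)) > 0.5, (2, 2, 2), (1, 2, 3))
        out = apply_rigid(mask, RigidTransform3D.identity(), interpolation="nearest")
        assert np.array_equal(out.data, mask.data)

    def test_integer_translation_exact_shift(self, rng):
        data = rng.normal(size=(8, 8, 8))
        v = vol(data, spacing=(2, 2, 2))
        t = RigidTransform3D(translation_mm=(2, 0, 0))  # +1 voxel in x
        out = apply_rigid(v, t)
        # t maps moving into fixed: content moves +1 voxel; output[i] = moving[i-1]
        assert np.allclose(out.data[1:], data[:-1], atol=1e-9)

    def test_rigid_round_trip_dsc(self):
        """t then t^-1 keeps a smooth 2 mm-resolution mask at DSC >= 0.99."""
        ii, jj, kk = np.indices((64, 64, 48))
        sphere = ((ii - 32) ** 2 + (jj - 32) ** 2 + ((kk - 24) * 1.0) ** 2) <= 15 ** 2
        mask = BinaryMask(sphere, (2, 2, 2), (0, 0, 0))
        t = RigidTransform3D((4, -3, 2), (8, -6, 9), (63, 63, 47))
        back = apply_rigid(apply_rigid(mask, t), t.inverse())
        assert dice(back, mask) >= 0.99


class TestRigidTransform:
    def test_compose_with_inverse_is_identity(self, rng):
        t = RigidTransform3D(rng.uniform(-30, 30, 3), rng.uniform(-40, 40, 3), (5, -3, 8))
        ident = t.compose(t.inverse())
        assert np.allclose(ident.rotation_deg, 0, atol=1e-9)
        assert np.allclose(ident.translation_mm, 0, atol=1e-9)
        pts = rng.normal(scale=50, size=(20, 3))
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)

    def test_compose_matches_sequential_application(self, rng):
        a = RigidTransform3D((10, -5, 3), (4, 2, -7), (1, 2, 3))
        b = RigidTransform3D((-3, 8, 12), (-6, 1, 5), (1, 2, 3))
        pts = rng.normal(scale=30, size=(10, 3))
        assert np.allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)), atol=1e-9)

    def test_json_round_trip(self):
        t = RigidTransform3D((1.5, -2.25, 3.0), (4.5, 5.0, -6.75), (0, 10, 20))
        t2 = RigidTransform3D.from_json(t.to_json())
        assert np.allclose(t2.rotation_deg, t.rotation_deg)
        assert np.allclose(t2.translation_mm, t.translation_mm)
        assert np.allclose(t2.center_mm, t.center_mm)


class TestComposedWarp:
    def test_single_pass_equals_two_pass_on_large_structure(self, phantom48):
        """Composing rigid+field in one resample agrees with sequential
        resampling up to interpolation (checked via high DSC on the brain)."""
        img, masks = phantom48
        brain = masks["brain"]
        t = RigidTransform3D((2, -1, 0), (4, -3, 5), (94, 94, 62))
        vec = np.zeros(img.shape + (3,))
        vec[..., 2] = 3.0
        fld = DisplacementField(vec, img.spacing, img.origin)
        one = compose_rigid_and_field(brain, t, fld)
        two = apply_displacement(apply_rigid(brain, t, target=img), fld)
        # not identical: the single pass interpolates once, which is the point
        assert dice(one, two) >= 0.95


class TestIO:
    def test_nifti_round_trip(self, tmp_path, rng):
        img = ImageVolume(rng.integers(-1000, 1500, (6, 5, 4)).astype(np.int16),
                          (2.0, 2.0, 3.0), (-10.0, 5.0, 0.0))
        write_volume(img, tmp_path / "img.nii")
        back = read_volume(tmp_path / "img.nii")
        assert np.array_equal(back.data, img.data)
        assert np.allclose(back.spacing, img.spacing)
        assert np.allclose(back.origin, img.origin)

        mask = BinaryMask(rng.random((6, 5, 4)) > 0.5, (2.0, 2.0, 3.0), (-10.0, 5.0, 0.0), "brain")
        write_mask(mask, tmp_path / "m.nii")
        mback = read_mask(tmp_path / "m.nii", "brain")
        assert np.array_equal(mback.data, mask.data)
        assert mback.structure_name == "brain"

        fld = DisplacementField(rng.normal(size=(6, 5, 4, 3)).astype(np.float32),
                                (2.0, 2.0, 3.0), (-10.0, 5.0, 0.0))
        write_field(fld, tmp_path / "f.nii")
        fback = read_field(tmp_path / "f.nii")
        assert np.allclose(fback.vectors, fld.vectors, atol=1e-6)
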