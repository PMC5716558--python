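"""Output-grid construction, trilinear interpolation and per-leg resampling."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from petstitch.dicom_io import VolumeGrid
from petstitch.geometry import StitchTransform
from petstitch.resample import (
    InsufficientOverlapError,
    build_stitched_grid,
    embed_on_grid,
    resample_segment,
    stitch_volumes,
    trilinear_sample,
)
from petstitch.segmentation import split_legs


def naive_trilinear(values, idx):
    """Independent 8-corner weighted-sum oracle (in-hull points only)."""
    i0 = np.floor(idx).astype(int)
    i0 = np.minimum(i0, np.array(values.shape) - 2)
    f = idx - i0
    out = 0.0
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                w = (
                    (f[0] if di else 1 - f[0])
                    * (f[1] if dj else 1 - f[1])
                    * (f[2] if dk else 1 - f[2])
                )
                out += w * values[i0[0] + di, i0[1] + dj, i0[2] + dk]
    return out


def volume_from(values, spacing=(2.0, 2.0, 3.0), origin=None, modality="CT", slope=1.0):
    values = np.asarray(values)
    if origin is None:
        ni, nj, _ = values.shape
        origin = (-(ni - 1) * spacing[0] / 2, -(nj - 1) * spacing[1] / 2, 0.0)
    return VolumeGrid(
        values=values, spacing=spacing, origin=origin,
        orientation=np.eye(3), modality=modality, slope=slope,
    )


def translation_transform(t):
    """Transform with X = Y + t."""
    return StitchTransform(np.eye(3), np.zeros(3), np.asarray(t, float))


class TestTrilinearSample:
    def test_voxel_center_is_exact(self, rng):
        vol = volume_from(rng.integers(0, 1000, (8, 7, 6)).astype(np.int16))
        p = vol.voxel_to_patient([3, 2, 4])
        assert trilinear_sample(vol, p) == vol.values[3, 2, 4]

    def test_axial_midpoint_is_mean(self, rng):
        vol = volume_from(rng.integers(0, 1000, (8, 7, 6)).astype(np.int16))
        p = vol.voxel_to_patient([3, 2, 3.5])
        assert trilinear_sample(vol, p) == pytest.approx(
            (vol.values[3, 2, 3] + vol.values[3, 2, 4]) / 2.0
        )

    def test_thousand_random_points_match_naive_oracle(self, rng):
        vals = rng.random((9, 8, 7))
        vol = volume_from(vals)
        idx = rng.uniform(0, np.array(vals.shape) - 1.0, size=(1000, 3))
        pts = vol.voxel_to_patient(idx)
        got = trilinear_sample(vol, pts)
        expected = np.array([naive_trilinear(vals, x) for x in idx])
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_outside_hull_returns_fill(self, rng):
        vol = volume_from(rng.integers(1, 9, (5, 5, 5)).astype(np.int16))
        p = vol.voxel_to_patient([-0.6, 2, 2])
        assert trilinear_sample(vol, p, fill_value=-123.0) == -123.0


@pytest.fixture(scope="module")
def lower_segment(small_spec=None):
    """A two-cylinder lower-segment CT with its leg partition."""
    ni, nj, nk = 48, 40, 14
    spacing = (2.5, 2.5, 3.0)
    hu = np.full((ni, nj, nk), -1000.0)
    x = (np.arange(ni) - (ni - 1) / 2) * spacing[0]
    y = (np.arange(nj) - (nj - 1) / 2) * spacing[1]
    xx, yy = np.meshgrid(x, y, indexing="ij")
    rng = np.random.default_rng(5)
    for cx in (-30.0, 30.0):
        inside = (xx - cx) ** 2 + yy**2 <= 16.0**2
        hu[inside, :] = 40.0 + np.round(rng.normal(0, 5, size=(int(inside.sum()), nk)))
    vol = volume_from(np.rint(hu).astype(np.int16), spacing)
    return vol, split_legs(vol)


class TestResampleSegment:
    def test_identity_transform_reproduces_input(self, lower_segment):
        vol, part = lower_segment
        tr = {"left": StitchTransform.identity(), "right": StitchTransform.identity()}
        out, claimed = resample_segment(vol, part, tr, vol)
        np.testing.assert_array_equal(out.values, vol.values)

    def test_integer_slice_translation_is_exact(self, lower_segment):
        vol, part = lower_segment
        shift = np.array([0.0, 0.0, 2 * vol.spacing[2]])  # two whole slices up
        tr = {"left": translation_transform(shift), "right": translation_transform(shift)}
        out, _ = resample_segment(vol, part, tr, vol)
        # output slice k holds input slice k-2, exactly (no interpolation blur)
        np.testing.assert_array_equal(out.values[:, :, 2:], vol.values[:, :, :-2])
        assert np.all(out.values[:, :, :2] == -1000)

    def test_mean_preserved_under_small_rotation(self, lower_segment):
        noisy, part = lower_segment
        # noiseless uniform legs: exactly 40 HU inside, air outside
        vol = volume_from(
            np.where(noisy.values > -500, 40, -1000).astype(np.int16),
            spacing=tuple(noisy.spacing),
        )
        rot = Rotation.from_euler("z", 3.0, degrees=True).as_matrix()
        anchor = np.array([0.0, 0.0, 20.0])
        tr = {s: StitchTransform(rot, anchor, anchor) for s in ("left", "right")}
        out, claimed = resample_segment(vol, part, tr, vol)
        phys_out = out.physical()
        # geometric interior of each moved leg, clear of partial-volume edges
        ni, nj, nk = out.shape
        ii, jj, kk = np.meshgrid(*(np.arange(n) for n in out.shape), indexing="ij")
        pts = out.voxel_to_patient(np.stack([ii, jj, kk], -1).reshape(-1, 3))
        interior = np.zeros(len(pts), bool)
        for cx in (-30.0, 30.0):
            moved = anchor + rot @ (np.array([cx, 0.0, 20.0]) - anchor)
            interior |= (pts[:, 0] - moved[0]) ** 2 + (pts[:, 1] - moved[1]) ** 2 < 11.0**2
        interior = interior.reshape(out.shape)
        interior[:, :, :2] = interior[:, :, -2:] = False
        # noisy uniform legs (mean 40 HU): interpolation must not bias the mean
        assert abs(phys_out[interior].mean() - 40.0) < 0.5 * 0.01 * 40

    def test_cross_leg_samples_are_fill(self, lower_segment):
        # move the left leg onto the right leg's territory: samples that land
        # on the other side of the boundary must come back as air
        vol, part = lower_segment
        tr = {
            "left": translation_transform([60.0, 0.0, 0.0]),
            "right": translation_transform([0.0, 0.0, 0.0]),
        }
        out, _ = resample_segment(vol, part, tr, vol)
        phys = out.physical()
        # where the left leg would now sit (over the right leg), the right
        # leg's own identity transform wins or fill applies; no doubled legs
        assert phys.max() <= vol.physical().max()


class TestBuildStitchedGrid:
    def _upper_lower(self):
        upper = volume_from(np.zeros((20, 20, 10), np.int16), origin=(-19, -19, 30.0))
        lower = volume_from(np.zeros((20, 20, 14), np.int16), origin=(-19, -19, 0.0))
        return upper, lower

    def test_identity_union_extent(self):
        upper, lower = self._upper_lower()
        tr = {"left": StitchTransform.identity()}
        out = build_stitched_grid(upper, lower, tr, plane_z=31.0)
        assert out.shape[2] == 20  # slices at z = 0..57 step 3
        assert out.origin[2] == pytest.approx(0.0)

    def test_axial_translation_grows_extent(self):
        upper, lower = self._upper_lower()
        t = -6.0  # lower segment moves 2 slices further down
        tr = {"left": translation_transform([0, 0, t])}
        out = build_stitched_grid(upper, lower, tr, plane_z=31.0)
        assert out.shape[2] == 22
        assert out.origin[2] == pytest.approx(-6.0)

    def test_transformed_corners_below_plane_covered(self, rng):
        upper, lower = self._upper_lower()
        for _ in range(10):
            rot = Rotation.from_euler(
                "xyz", rng.uniform(-5, 5, 3), degrees=True
            ).as_matrix()
            anchor = rng.uniform(-10, 10, 3) + [0, 0, 15.0]
            tr = {"left": StitchTransform(rot, anchor, anchor + rng.uniform(-5, 5, 3))}
            plane_z = 31.0
            out = build_stitched_grid(upper, lower, tr, plane_z)
            n = np.array(lower.shape) - 1
            corners = lower.voxel_to_patient(
                [[i, j, k] for i in (0, n[0]) for j in (0, n[1]) for k in (0, n[2])]
            )
            moved = tr["left"].apply(corners)
            zs = out.slice_positions()
            low = moved[moved[:, 2] < plane_z]
            assert np.all(low[:, 2] >= zs[0] - out.spacing[2])
            assert np.all(low[:, 2] <= zs[-1] + out.spacing[2])

    def test_insufficient_overlap_raises(self):
        upper, lower = self._upper_lower()
        tr = {"left": translation_transform([0, 0, -100.0])}
        with pytest.raises(InsufficientOverlapError):
            build_stitched_grid(upper, lower, tr, plane_z=31.0)


class TestStitchVolumes:
    def _pair(self, rng, nk=10):
        a = volume_from(rng.integers(0, 100, (6, 6, nk)).astype(np.int16))
        b = volume_from(rng.integers(0, 100, (6, 6, nk)).astype(np.int16))
        return a, b

    def test_equal_inputs_equal_output(self, rng):
        a, _ = self._pair(rng)
        out = stitch_volumes(a, a, plane_z=10.0)
        np.testing.assert_array_equal(out.values, a.values)

    def test_plane_above_everything_takes_lower(self, rng):
        a, b = self._pair(rng)
        out = stitch_volumes(a, b, plane_z=1e6)
        np.testing.assert_array_equal(out.values, b.values)

    def test_slice_counting_at_plane(self, rng):
        a, b = self._pair(rng)
        # slices at z = 0, 3, ..., 27; plane between slices 4 and 5
        out = stitch_volumes(a, b, plane_z=13.5)
        np.testing.assert_array_equal(out.values[:, :, 5:], a.values[:, :, 5:])
        np.testing.assert_array_equal(out.values[:, :, :5], b.values[:, :, :5])

    def test_upper_slices_bit_identical(self, rng):
        a, b = self._pair(rng)
        out = stitch_volumes(a, b, plane_z=13.5)
        above = a.slice_positions() > 13.5
        np.testing.assert_array_equal(out.values[:, :, above], a.values[:, :, above])

    def test_mismatched_grids_rejected(self, rng):
        a, b = self._pair(rng)
        b.origin = b.origin + 1.0
        with pytest.raises(ValueError, match="origin"):
            stitch_volumes(a, b, plane_z=10.0)

    def test_per_slice_slope_follows_source(self, rng):
        a, b = self._pair(rng)
        a.modality = b.modality = "PT"
        a.slope, b.slope = 0.2, 0.25
        out = stitch_volumes(a, b, plane_z=13.5)
        slopes = out.slope_per_slice()
        np.testing.assert_allclose(slopes[:5], 0.25)
        np.testing.assert_allclose(slopes[5:], 0.2)


class TestEmbedOnGrid:
    def test_bit_copy_into_extended_grid(self, rng):
        vol = volume_from(rng.integers(0, 100, (6, 6, 8)).astype(np.int16),
                          origin=(-5, -5, 12.0))
        out_grid = volume_from(np.zeros((6, 6, 12), np.int16), origin=(-5, -5, 0.0))
        emb = embed_on_grid(vol, out_grid)
        np.testing.assert_array_equal(emb.values[:, :, 4:], vol.values)
        assert np.all(emb.values[:, :, :4] == -1000)
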