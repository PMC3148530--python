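"""Binary-mask morphometrics: volumes, surfaces, inertia, distances."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from phaseopt.core import (
    PhaseSeries,
    PhaseVolume,
    RoiMaskSet,
    mask_centroid,
    mask_volume,
    min_distance,
    roi_metrics,
)
from phaseopt.errors import EmptyRoiError, GeometryError


def _volume(values, spacing=(1.0, 1.0, 1.0), phase=0, origin=None):
    return PhaseVolume(phase_index=phase, values=np.asarray(values), spacing=spacing, origin=origin)


class TestMaskVolume:
    @pytest.mark.parametrize(
        "mask, spacing, expected",
        [
            (np.zeros((4, 4, 4), bool), (1, 1, 1), 0.0),
            (np.ones((10, 10, 10), bool), (1, 1, 1), 1000.0),
            (np.ones((2, 3, 4), bool), (0.5, 2.0, 1.5), 24 * 1.5),
        ],
    )
    def test_counting_times_voxel_volume(self, mask, spacing, expected):
        assert mask_volume(mask, spacing) == pytest.approx(expected)

    def test_voxelized_sphere_approaches_analytic_volume(self):
        # voxel-center-inside-sphere counting vs 4/3*pi*r^3 at 0.5 mm spacing
        r, sp = 5.0, 0.5
        ax = np.arange(24) * sp
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
        c = 11.5 * sp
        sphere = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= r**2
        analytic = 4 / 3 * np.pi * r**3
        assert mask_volume(sphere, (sp, sp, sp)) == pytest.approx(analytic, rel=0.02)

    def test_invalid_spacing_rejected(self):
        with pytest.raises(GeometryError):
            mask_volume(np.ones((2, 2, 2), bool), (1.0, 0.0, 1.0))

    def test_additive_over_disjoint_masks(self, rng):
        shape = (12, 12, 12)
        a = rng.random(shape) > 0.7
        b = (rng.random(shape) > 0.7) & ~a
        sp = (1.0, 2.0, 0.5)
        assert mask_volume(a | b, sp) == pytest.approx(mask_volume(a, sp) + mask_volume(b, sp))


class TestRoiMetrics:
    def test_single_voxel_cube_faces(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        m = roi_metrics(_volume(np.zeros((3, 3, 3))), mask)
        assert m.surface_area_mm2 == pytest.approx(6.0)
        assert m.volume_mm3 == pytest.approx(1.0)

    def test_grid_boundary_faces_count_as_exposed(self):
        mask = np.ones((2, 2, 2), bool)
        m = roi_metrics(_volume(np.zeros((2, 2, 2))), mask)
        assert m.surface_area_mm2 == pytest.approx(24.0)  # a 2x2x2 mm cube

    def test_elongated_box_principal_axis(self):
        mask = np.zeros((24, 8, 8), bool)
        mask[2:22, 2:6, 2:6] = True
        m = roi_metrics(_volume(np.zeros((24, 8, 8))), mask)
        principal = m.inertia_axes[:, 0]
        assert abs(principal @ np.array([1.0, 0.0, 0.0])) == pytest.approx(1.0)
        assert np.all(np.diff(m.inertia_eigenvalues) <= 1e-12)  # sorted descending

    def test_histogram_counts_sum_to_voxel_count(self, rng):
        shape = (10, 11, 12)
        mask = rng.random(shape) > 0.6
        image = _volume(rng.normal(size=shape))
        m = roi_metrics(image, mask)
        assert m.histogram_counts.sum() == np.count_nonzero(mask)
        assert m.mean_density == pytest.approx(image.values[mask].mean())

    def test_empty_mask_yields_explicit_sentinel(self):
        m = roi_metrics(_volume(np.zeros((4, 4, 4))), np.zeros((4, 4, 4), bool))
        assert not m.defined
        assert m.volume_mm3 == 0.0
        assert m.centroid_mm is None and m.inertia_axes is None

    def test_volume_invariant_under_origin_change(self, rng):
        shape = (9, 9, 9)
        mask = rng.random(shape) > 0.5
        vals = rng.normal(size=shape)
        a = roi_metrics(_volume(vals), mask)
        b = roi_metrics(_volume(vals, origin=(10.0, -4.0, 2.5)), mask)
        assert a.volume_mm3 == b.volume_mm3
        assert np.allclose(b.centroid_mm - a.centroid_mm, (10.0, -4.0, 2.5))

    def test_inertia_axes_equivariant_under_axis_permutation(self, rng):
        shape = (14, 14, 14)
        mask = rng.random(shape) > 0.8
        mask[0, 0, 0] = True
        perm = (2, 0, 1)
        a = roi_metrics(_volume(np.zeros(shape)), mask)
        b = roi_metrics(_volume(np.zeros(shape)), np.transpose(mask, perm))
        assert np.allclose(np.sort(a.inertia_eigenvalues), np.sort(b.inertia_eigenvalues))


class TestMinDistance:
    def test_overlapping_masks_have_zero_distance(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[1:4, 1:4, 1:4] = True
        b[3:5, 3:5, 3:5] = True
        assert min_distance(a, b, (1, 1, 1)) == 0.0

    def test_three_four_five_triangle(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[0, 0, 0] = True
        b[3, 4, 0] = True
        assert min_distance(a, b, (1, 1, 1)) == pytest.approx(5.0)

    def test_empty_mask_error_names_the_roi(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.ones((4, 4, 4), bool)
        with pytest.raises(EmptyRoiError, match="gtv"):
            min_distance(a, b, (1, 1, 1), name_a="gtv", name_b="cord")

    @given(seed=st.integers(0, 500))
    def test_matches_brute_force_all_pairs(self, seed):
        rng = np.random.default_rng(seed)
        shape = (10, 12, 9)
        spacing = np.array([1.0, 1.7, 0.6])
        a = rng.random(shape) > 0.95
        b = rng.random(shape) > 0.95
        a.flat[rng.integers(a.size)] = True  # guarantee non-empty
        b.flat[rng.integers(b.size)] = True
        got = min_distance(a, b, spacing)
        brute = cdist(np.argwhere(a) * spacing, np.argwhere(b) * spacing).min()
        assert got == pytest.approx(brute, abs=1e-9)
        assert min_distance(b, a, spacing) == pytest.approx(got)  # symmetry
        assert min_distance(a, a, spacing) == 0.0

    def test_centroid_modes(self):
        a = np.zeros((9, 9, 9), bool)
        b = np.zeros((9, 9, 9), bool)
        a[1, 1, 1] = True
        b[1, 7, 1] = True
        sp = (1, 1, 1)
        assert min_distance(a, b, sp, mode="centroid_to_centroid") == pytest.approx(6.0)
        assert min_distance(a, b, sp, mode="centroid_to_surface") == pytest.approx(6.0)
        assert min_distance(a, b, sp, mode="min_surface") == pytest.approx(6.0)

    def test_min_surface_equals_min_for_solid_masks(self, rng):
        a = np.zeros((16, 16, 16), bool)
        b = np.zeros((16, 16, 16), bool)
        a[2:7, 2:7, 2:7] = True
        b[10:14, 9:15, 3:8] = True
        sp = (1.0, 0.8, 1.2)
        assert min_distance(a, b, sp, mode="min_surface") == pytest.approx(
            min_distance(a, b, sp, mode="min")
        )


class TestDomainTypes:
    def test_phase_series_requires_ten_consistent_phases(self):
        def phase(k, shape=(4, 4, 4)):
            vol = _volume(np.zeros(shape), phase=k)
            m = np.zeros(shape, bool)
            m[1, 1, 1] = True
            return vol, RoiMaskSet(gtv=m, lung_left=m, lung_right=m, cord=m)

        with pytest.raises(GeometryError, match="10 phases"):
            PhaseSeries(tuple(phase(k) for k in range(9)))
        with pytest.raises(GeometryError, match="0..9"):
            PhaseSeries(tuple(phase(0) for _ in range(10)))
        series = PhaseSeries(tuple(phase(k) for k in range(10)))
        assert [vol.phase_index for vol, _ in series] == list(range(10))

    def test_mask_set_rejects_mismatched_shapes(self):
        good = np.zeros((4, 4, 4), bool)
        bad = np.zeros((4, 4, 5), bool)
        with pytest.raises(GeometryError, match="cord"):
            RoiMaskSet(gtv=good, lung_left=good, lung_right=good, cord=bad)

    def test_masks_thresholded_to_binary(self):
        m = np.zeros((3, 3, 3))
        m[1, 1, 1] = 255.0
        ms = RoiMaskSet(gtv=m, lung_left=m, lung_right=m, cord=m)
        assert ms.gtv.dtype == bool and ms.gtv.sum() == 1

    def test_centroid_of_known_block(self):
        m = np.zeros((6, 6, 6), bool)
        m[2:4, 2:4, 2:4] = True
        assert np.allclose(mask_centroid(m, (2.0, 2.0, 2.0)), (5.0, 5.0, 5.0))
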