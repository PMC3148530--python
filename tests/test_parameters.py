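"""Per-phase comparison parameters: laterality, T/L ratio, reference phase."""

import numpy as np
import pandas as pd
import pytest

from conftest import small_config
from phaseopt.core import RoiMaskSet
from phaseopt.errors import GainError, LateralityError, ValidationError
from phaseopt.parameters import (
    PhaseParameterTable,
    compute_phase_table,
    detect_laterality,
    identify_reference,
    tl_ratio,
)
from phaseopt.phantom import expected_table, generate


def _mask_with_block(shape, sl):
    m = np.zeros(shape, bool)
    m[sl] = True
    return m


def _lung_pair(shape=(20, 8, 8)):
    left = _mask_with_block(shape, (slice(13, 19), slice(1, 7), slice(1, 7)))
    right = _mask_with_block(shape, (slice(1, 7), slice(1, 7), slice(1, 7)))
    return left, right


class TestLaterality:
    @pytest.mark.parametrize("gtv_slice, expected", [
        ((slice(2, 5), slice(2, 5), slice(2, 5)), "right"),
        ((slice(15, 18), slice(2, 5), slice(2, 5)), "left"),
    ])
    def test_gtv_side_detected(self, gtv_slice, expected):
        shape = (20, 8, 8)
        left, right = _lung_pair(shape)
        masks = RoiMaskSet(
            gtv=_mask_with_block(shape, gtv_slice), lung_left=left, lung_right=right,
            cord=_mask_with_block(shape, (slice(9, 11), slice(3, 5), slice(0, 8))),
        )
        assert detect_laterality(masks, (1, 1, 1)) == expected

    def test_one_voxel_off_midline_decides(self):
        # GTV centered one voxel toward the right lung
        shape = (21, 8, 8)
        left, right = _lung_pair(shape)
        gtv = _mask_with_block(shape, (slice(8, 11), slice(3, 5), slice(3, 5)))  # center 9 < 10
        masks = RoiMaskSet(gtv=gtv, lung_left=left, lung_right=right,
                           cord=_mask_with_block(shape, (slice(0, 1), slice(0, 1), slice(0, 1))))
        assert detect_laterality(masks, (1, 1, 1)) == "right"

    def test_midline_tie_requires_explicit_config(self):
        shape = (20, 8, 8)
        left, right = _lung_pair(shape)
        gtv = _mask_with_block(shape, (slice(9, 11), slice(3, 5), slice(3, 5)))  # centroid 9.5 = midline
        masks = RoiMaskSet(gtv=gtv, lung_left=left, lung_right=right, cord=gtv)
        with pytest.raises(LateralityError):
            detect_laterality(masks, (1, 1, 1))


class TestTlRatio:
    @pytest.mark.parametrize("gtv, lung, expected", [
        (100.0, 10000.0, 1.0),
        (0.0, 5000.0, 0.0),
    ])
    def test_formula(self, gtv, lung, expected):
        assert tl_ratio(gtv, lung) == pytest.approx(expected)

    def test_table_scale_consistency(self):
        # a 403 cm^3 tumor in a ~1.2 L lung sits at ratio ~33.5 (percent scale)
        assert tl_ratio(403e3, 403e3 / 0.335) == pytest.approx(33.5)

    def test_zero_lung_volume_names_phase(self):
        with pytest.raises(GainError, match="phase 3"):
            tl_ratio(10.0, 0.0, phase_index=3)


def _table_from_lung_volumes(vols):
    df = pd.DataFrame({
        "tl_ratio": np.ones(10),
        "tc_dist_mm": np.ones(10),
        "ipsi_lung_volume_mm3": vols,
    })
    return PhaseParameterTable(df)


class TestIdentifyReference:
    def test_peak_at_start(self):
        vols = 5 + np.cos(2 * np.pi * np.arange(10) / 10)
        assert identify_reference(_table_from_lung_volumes(vols)) == 0

    def test_tie_breaks_to_lowest_phase(self):
        assert identify_reference(_table_from_lung_volumes([4, 5, 5, 4, 3, 3, 3, 3, 3, 3])) == 1

    def test_late_inspiration_peak_recovered(self):
        # mirrors a patient whose maximal inspiration fell at phase 6
        cfg = small_config(inspiration_phase=6, noise_sigma=0.0)
        assert identify_reference(expected_table(cfg)) == 6
        series, _ = generate(cfg)
        assert compute_phase_table(series).reference_phase == 6

    def test_missing_lung_volumes_demand_explicit_reference(self):
        df = pd.DataFrame({"tl_ratio": np.ones(10), "tc_dist_mm": np.ones(10)})
        with pytest.raises(ValidationError, match="reference_phase"):
            identify_reference(PhaseParameterTable(df))


class TestComputePhaseTable:
    def test_static_phantom_rows_identical(self):
        cfg = small_config(amplitude_mm=0.0, ap_amplitude_mm=0.0,
                           expansion_fraction=0.0, noise_sigma=0.0)
        series, _ = generate(cfg)
        table = compute_phase_table(series)
        assert table.laterality == "right"
        assert np.ptp(table.tl_values) == 0.0
        assert np.ptp(table.tc_values) == 0.0

    def test_shrinking_lung_raises_ratio_monotonically(self):
        # inspiration peaks at phase 0, so lung volume falls 0 -> 5 and the
        # ratio of the fixed (non-moving) tumor to it rises
        cfg = small_config(amplitude_mm=0.0, ap_amplitude_mm=0.0, noise_sigma=0.0)
        series, _ = generate(cfg)
        table = compute_phase_table(series)
        assert np.all(np.diff(table.lung_volumes[:6]) < 0)
        assert np.all(np.diff(table.tl_values[:6]) > 0)

    def test_cord_approach_minimizes_distance_at_mid_cycle(self, small_phantom, small_cfg):
        series, gt = small_phantom
        table = compute_phase_table(series)
        expected = expected_table(small_cfg)
        assert int(np.argmin(expected.tc_values)) == 5
        # voxel quantization can tie the near-peak phases; the mid-cycle
        # phase must still attain the minimum measured distance
        assert table.tc_values[5] == table.tc_values.min()
        assert np.abs(table.tc_values - expected.tc_values).max() <= np.linalg.norm(small_cfg.spacing)

    def test_spacing_rescale_leaves_ratio_fixed_and_scales_distance(self, small_phantom):
        series, _ = small_phantom
        table = compute_phase_table(series)
        s = 2.5
        from phaseopt.core import PhaseSeries, PhaseVolume

        scaled = PhaseSeries(tuple(
            (PhaseVolume(phase_index=v.phase_index, values=v.values,
                         spacing=v.spacing * s, origin=v.origin), m)
            for v, m in series
        ))
        scaled_table = compute_phase_table(scaled)
        assert np.allclose(scaled_table.tl_values, table.tl_values)
        assert np.allclose(scaled_table.tc_values, s * table.tc_values)

    def test_missing_roi_reported_per_phase(self, small_phantom):
        series, _ = small_phantom
        from phaseopt.core import PhaseSeries, RoiMaskSet

        empty = np.zeros(series.shape, bool)
        broken = []
        for v, m in series:
            if v.phase_index in (3, 8):
                m = RoiMaskSet(gtv=m.gtv, lung_left=m.lung_left,
                               lung_right=m.lung_right, cord=empty)
            broken.append((v, m))
        with pytest.raises(ValidationError, match="phase 3") as err:
            compute_phase_table(PhaseSeries(tuple(broken)))
        assert "phase 8" in str(err.value)
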