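"""ROI statistics, aggregation, range derivation and overlap analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cementscan.errors import EmptyRegionError
from cementscan.reference_data import (
    PROSTHESIS_INFLUENCE,
    PROSTHESIS_INFLUENCE_EXPECTED,
    SUMMARY_ROI_STATS,
)
from cementscan.roi_ranges import (
    CORTICAL,
    PENETRATED,
    PROSTHESIS,
    TRABECULAR,
    AggregateStats,
    RoiStats,
    aggregate,
    check_overlap,
    default_material_table,
    derive_range,
    roi_statistics,
)


class TestRoiStatistics:
    def test_uniform_region_has_zero_homogeneity(self):
        stats = roi_statistics(np.full((5, 5), 1328.0))
        assert stats.mean_hu == 1328.0
        assert stats.homogeneity == 0.0

    def test_two_voxel_hand_computation(self):
        stats = roi_statistics(np.array([100.0, 300.0]))
        assert stats.mean_hu == 200.0
        assert stats.homogeneity == pytest.approx(200.0 / np.sqrt(2), abs=1e-9)

    def test_gaussian_region_recovers_trabecular_parameters(self):
        rng = np.random.default_rng(163)
        stats = roi_statistics(rng.normal(163.0, 152.0, size=10_000))
        assert stats.mean_hu == pytest.approx(163.0, abs=5.0)
        assert stats.homogeneity == pytest.approx(152.0, abs=5.0)

    def test_mask_selection_and_too_few_voxels(self):
        arr = np.arange(9.0).reshape(3, 3)
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, :2] = True
        assert roi_statistics(arr, mask).mean_hu == 0.5
        mask[0, 1] = False
        with pytest.raises(EmptyRegionError):
            roi_statistics(arr, mask)

    def test_homogeneity_shift_invariant_and_scale_linear(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 50, size=500)
        base = roi_statistics(x).homogeneity
        assert roi_statistics(x + 700.0).homogeneity == pytest.approx(base, abs=1e-9)
        assert roi_statistics(3.0 * x).homogeneity == pytest.approx(3.0 * base, rel=1e-12)


class TestAggregate:
    @pytest.mark.parametrize("arm", list(PROSTHESIS_INFLUENCE))
    def test_reference_columns_reproduce_published_aggregates(self, arm):
        """Each measurement arm's printed per-ROI values round to the
        published mean (SD) cells for both HU and homogeneity."""
        assert aggregate(PROSTHESIS_INFLUENCE[arm]).rounded() == (
            PROSTHESIS_INFLUENCE_EXPECTED[arm]
        )

    def test_identical_rois_have_zero_spread(self):
        agg = aggregate([RoiStats(1000.0, 50.0)] * 3)
        assert agg.sd_of_means == 0.0
        assert agg.sd_of_homogeneity == 0.0

    def test_single_roi_rejected(self):
        with pytest.raises(EmptyRegionError):
            aggregate([RoiStats(1000.0, 50.0)])


class TestDeriveRange:
    def test_degenerate_zero_width(self):
        rng = derive_range(AggregateStats(0.0, 0.0, 0.0, 0.0, 2))
        assert (rng.low, rng.high) == (0.0, 0.0)

    def test_trabecular_summary_statistics(self):
        """mean 163, homogeneity 152 (SD 14) -> 163 +/- 318 = [-155, 481]."""
        rng = derive_range(SUMMARY_ROI_STATS["trabecular_transversal"])
        assert (rng.low, rng.high) == (-155.0, 481.0)

    def test_beneath_tray_summary_statistics(self):
        """mean 1384, homogeneity 81 (SD 30) -> 1384 +/- 192 = [1192, 1576]."""
        rng = derive_range(SUMMARY_ROI_STATS["beneath_tray"])
        assert (rng.low, rng.high) == (1192.0, 1576.0)

    @given(
        hom=st.floats(0.1, 200), sd=st.floats(0.0, 100),
        bump=st.floats(0.1, 50), mean=st.floats(-500, 2000),
    )
    @settings(deadline=None, max_examples=50)
    def test_width_increases_with_homogeneity_and_its_sd(self, hom, sd, bump, mean):
        def width(h, s):
            r = derive_range(AggregateStats(mean, 0.0, h, s, 3))
            return r.high - r.low

        assert width(hom + bump, sd) > width(hom, sd)
        assert width(hom, sd + bump) > width(hom, sd)
        r = derive_range(AggregateStats(mean, 0.0, hom, sd, 3))
        assert (r.low + r.high) / 2 == pytest.approx(mean, rel=1e-9, abs=1e-6)

    def test_simulated_replicates_bracket_the_true_mean(self):
        rng = np.random.default_rng(99)
        rois = [
            roi_statistics(rng.normal(163.0, 152.0, size=400)) for _ in range(6)
        ]
        derived = derive_range(aggregate(rois))
        assert derived.low < 163.0 < derived.high


class TestOverlap:
    def test_default_table_has_exactly_the_known_overlap(self, table):
        overlaps = check_overlap(table)
        assert len(overlaps) == 1
        a, b, interval = overlaps[0]
        assert {a, b} == {PENETRATED, CORTICAL}
        assert interval == (1386.0, 1706.0)

    def test_measurement_materials_do_not_overlap(self, table):
        sub = table.subset({TRABECULAR, PENETRATED, PROSTHESIS})
        assert check_overlap(sub) == []

    def test_single_range_table(self):
        t = default_material_table().subset({PROSTHESIS})
        assert check_overlap(t) == []


def test_material_table_json_csv_roundtrip(tmp_path, table):
    table.to_json(tmp_path / "t.json")
    table.to_csv(tmp_path / "t.csv")
    for back in (
        type(table).from_json(tmp_path / "t.json"),
        type(table).from_csv(tmp_path / "t.csv"),
    ):
        assert [
            (r.material, r.low, r.high, r.priority) for r in back
        ] == [(r.material, r.low, r.high, r.priority) for r in table]
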