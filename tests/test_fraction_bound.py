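"""RFU calibration, affinity conversion, grouping and concentration grids."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycobind.fraction_bound import (
    AffinityRecord,
    CalibrationParams,
    ConcentrationGrid,
    affinity_to_fraction,
    build_concentration_grid,
    cfg_coarse_grid,
    dense50_grid,
    estimate_background_peak,
    group_arrays,
    resample_fractions,
    rfu_to_fraction,
    summarize_spots,
)


def spot_table(rows):
    return pd.DataFrame(rows, columns=["glycoconjugate_id", "replicate", "foreground", "background"])


class TestSummarizeSpots:
    def test_mean_net_over_replicates(self):
        table = spot_table([("g1", r, 110.0, 10.0) for r in range(1, 7)])
        assert summarize_spots(table) == {"g1": 100.0}

    def test_negative_means_preserved(self):
        table = spot_table([("g1", r, 5.0, 10.0) for r in range(1, 7)])
        assert summarize_spots(table) == {"g1": -5.0}

    def test_partial_replicates_warn(self, caplog):
        import logging

        table = spot_table([("g1", r, 110.0, 10.0) for r in range(1, 5)])
        with caplog.at_level(logging.WARNING):
            means = summarize_spots(table)
        assert means == {"g1": 100.0}
        assert any("4 of 6" in r.message for r in caplog.records)


class TestBackgroundPeak:
    def test_degenerate_all_equal(self):
        cal = estimate_background_peak([500.0] * 20)
        assert cal.background_peak == pytest.approx(500.0, rel=1e-6)

    def test_lognormal_mode_with_outliers(self):
        # mode at 100 in log space, 20 bright binder spots near 30,000
        rng = np.random.default_rng(42)
        values = list(100 * 10 ** rng.normal(0, 0.25, size=500)) + list(
            30_000 * 10 ** rng.normal(0, 0.02, size=20)
        )
        cal = estimate_background_peak(values)
        assert 80 <= cal.background_peak <= 125
        # independent KDE implementation agrees on the peak location
        from scipy.stats import gaussian_kde

        log_vals = np.log10([v for v in values if v > 0])
        kde = gaussian_kde(log_vals, bw_method=0.2 / log_vals.std(ddof=1))
        grid = np.linspace(log_vals.min(), log_vals.max(), 512)
        dens = kde(grid)
        dens[grid >= np.log10(4000)] = -np.inf
        independent_peak = 10 ** grid[np.argmax(dens)]
        assert cal.background_peak == pytest.approx(independent_peak, rel=0.10)

    def test_bimodal_upper_mode_masked_by_cutoff(self):
        rng = np.random.default_rng(7)
        values = list(1_000 * 10 ** rng.normal(0, 0.1, 100)) + list(
            20_000 * 10 ** rng.normal(0, 0.1, 300)
        )
        cal = estimate_background_peak(values)
        assert 700 <= cal.background_peak <= 1400

    def test_no_positive_values(self):
        with pytest.raises(ValueError, match="positive"):
            estimate_background_peak([-5.0] * 20, array_id="a1")

    def test_too_few_values(self):
        with pytest.raises(ValueError, match="at least 10"):
            estimate_background_peak([100.0] * 5)


class TestRfuToFraction:
    def test_peak_maps_to_zero(self):
        cal = CalibrationParams(background_peak=1000.0)
        assert rfu_to_fraction(1000.0, cal) == 0.0

    def test_global_max_maps_to_one(self):
        cal = CalibrationParams(background_peak=1000.0)
        assert rfu_to_fraction(65_536.0, cal) == 1.0

    def test_linear_midpoint(self):
        cal = CalibrationParams(background_peak=1000.0)
        assert rfu_to_fraction(33_268.0, cal) == pytest.approx(0.5)

    def test_below_peak_clamped_to_zero(self):
        cal = CalibrationParams(background_peak=1000.0)
        assert rfu_to_fraction(-50.0, cal) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(
        rfu1=st.floats(-1e4, 7e4),
        rfu2=st.floats(-1e4, 7e4),
        peak=st.floats(1.0, 3999.0),
    )
    def test_monotone_into_unit_interval(self, rfu1, rfu2, peak):
        cal = CalibrationParams(background_peak=peak)
        f1, f2 = rfu_to_fraction(rfu1, cal), rfu_to_fraction(rfu2, cal)
        assert 0.0 <= f1 <= 1.0
        if rfu1 <= rfu2:
            assert f1 <= f2


class TestGroupArrays:
    def metadata(self, rows):
        return pd.DataFrame(
            rows,
            columns=["array_id", "cbpID", "sample_description", "investigator", "concentration", "unit"],
        )

    def test_group_with_three_concentrations_retained(self):
        meta = self.metadata(
            [(f"a{i}", "cbp1", "lectin X", "inv1", c, "ug/ml") for i, c in enumerate([1.0, 10.0, 100.0])]
        )
        groups = group_arrays(meta)
        assert len(groups) == 1
        assert groups[0].concentrations == [1.0, 10.0, 100.0]

    def test_two_concentrations_dropped(self):
        meta = self.metadata([("a1", "cbp1", "x", "inv1", 1.0, "ug/ml"), ("a2", "cbp1", "x", "inv1", 10.0, "ug/ml")])
        assert group_arrays(meta) == []

    def test_different_investigator_splits_group(self):
        rows = [(f"a{i}", "cbp1", "x", inv, c, "ug/ml") for i, (inv, c) in enumerate(
            [(v, c) for v in ("inv1", "inv2") for c in (1.0, 10.0, 100.0)]
        )]
        groups = group_arrays(self.metadata(rows))
        assert len(groups) == 2
        assert {g.investigator for g in groups} == {"inv1", "inv2"}

    def test_missing_grouping_field_errors(self):
        meta = self.metadata([("a1", None, "x", "inv1", 1.0, "ug/ml")])
        with pytest.raises(ValueError, match="grouping"):
            group_arrays(meta)


class TestResample:
    def test_log_midpoint(self):
        grid = ConcentrationGrid(values=np.array([10.0]), unit="ug/ml")
        (rec,) = resample_fractions([(1.0, 0.2), (100.0, 0.8)], grid)
        assert rec.fraction_bound == pytest.approx(0.5)

    def test_constant_end_extrapolation(self):
        grid = ConcentrationGrid(values=np.array([0.01, 1000.0]), unit="ug/ml")
        low, high = resample_fractions([(1.0, 0.2), (100.0, 0.8)], grid)
        assert low.fraction_bound == pytest.approx(0.2)
        assert high.fraction_bound == pytest.approx(0.8)

    def test_single_point_expands_to_constant(self):
        grid = cfg_coarse_grid()
        records = resample_fractions([(10.0, 0.4)], grid)
        assert [r.fraction_bound for r in records] == pytest.approx([0.4] * 4)

    def test_measured_points_reproduced_exactly(self):
        grid = ConcentrationGrid(values=np.array([1.0, 10.0, 100.0]), unit="ug/ml")
        records = resample_fractions([(1.0, 0.1), (10.0, 0.5), (100.0, 0.9)], grid)
        assert [r.fraction_bound for r in records] == pytest.approx([0.1, 0.5, 0.9])

    def test_empty_points_error(self):
        with pytest.raises(ValueError):
            resample_fractions([], cfg_coarse_grid())


class TestAffinityConversion:
    def test_half_occupancy_at_kd(self):
        aff = AffinityRecord("m", "l", 2.5, "Kd", "uM")
        assert affinity_to_fraction(aff, 2.5) == pytest.approx(0.5)

    def test_vanishes_at_low_concentration(self):
        aff = AffinityRecord("m", "l", 1.0, "Kd", "uM")
        assert affinity_to_fraction(aff, 1e-12) < 1e-9

    def test_ka_reciprocal(self):
        # Ka = 1 per μM ⇒ Kd = 1 μM; at 99 μM occupancy is 0.99
        aff = AffinityRecord("m", "l", 1.0, "Ka", "uM")
        assert affinity_to_fraction(aff, 99.0) == pytest.approx(0.99)

    def test_unit_mismatch_rejected(self):
        aff = AffinityRecord("m", "l", 1.0, "Kd", "uM")
        with pytest.raises(ValueError, match="unit"):
            affinity_to_fraction(aff, 1.0, unit="ug/ml")

    @settings(max_examples=50, deadline=None)
    @given(
        kd=st.floats(1e-3, 1e3),
        c1=st.floats(1e-3, 1e3),
        c2=st.floats(1e-3, 1e3),
    )
    def test_strictly_increasing_in_concentration(self, kd, c1, c2):
        aff = AffinityRecord("m", "l", kd, "Kd", "uM")
        f1, f2 = affinity_to_fraction(aff, c1), affinity_to_fraction(aff, c2)
        assert 0 < f1 < 1
        if c1 < c2:
            assert f1 < f2


class TestConcentrationGrid:
    def test_dense_grid_has_fifty_points(self):
        grid = dense50_grid()
        assert len(grid) == 50
        assert grid.values.min() == pytest.approx(1e-5)
        assert grid.values.max() == pytest.approx(100.0)

    def test_coarse_grid(self):
        assert cfg_coarse_grid().values.tolist() == [0.1, 1.0, 10.0, 100.0]

    def test_singleton(self):
        grid = build_concentration_grid([1], [0])
        assert grid.values.tolist() == [1.0]

    def test_empty_mantissas_rejected(self):
        with pytest.raises(ValueError):
            build_concentration_grid([], [0])
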