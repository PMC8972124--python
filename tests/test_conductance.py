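import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vineflux.conductance import (
    bulk_boundary_resistances,
    canopy_latent_heat,
    compute_flux_records,
    daily_max_hourly_running_mean,
    filter_low_radiation,
    invert_to_r_bs,
    leaf_stomatal_equivalent,
)
from vineflux.core import PhysicalConstants
from vineflux.exceptions import InvalidInputError

from ._oracles import solve_r_bs_numerically

C = PhysicalConstants()

positive_drivers = {
    "lam_e": st.floats(10.0, 600.0),
    "r_c": st.floats(0.0, 900.0),
    "d_c": st.floats(1.0, 4000.0),
    "r_bh": st.floats(1.0, 60.0),
}


class TestBulkBoundaryResistances:
    def test_worked_examples(self):
        r_bh, r_bv = bulk_boundary_resistances(2.0, 25.0, 2.0)
        assert (r_bh, r_bv) == (6.25, 12.5)
        r_bh, _ = bulk_boundary_resistances(0.5, 25.0, 2.0)
        assert r_bh == 25.0

    def test_vapor_to_heat_ratio_is_n_for_hypostomatous_leaves(self):
        for lai in (0.3, 1.0, 2.7):
            r_bh, r_bv = bulk_boundary_resistances(lai, 25.0, 2.0)
            assert r_bv / r_bh == pytest.approx(2.0, rel=1e-12)

    def test_nonpositive_lai_rejected(self):
        with pytest.raises(InvalidInputError):
            bulk_boundary_resistances(0.0, 25.0)


class TestForwardFlux:
    def test_no_drivers_no_flux(self):
        assert canopy_latent_heat(100.0, 0.0, 0.0, 10.0) == 0.0

    def test_hand_evaluated_example(self):
        # (145*300 + 1212*1000/10) / (145 + 65.8*(2 + 12.483))
        assert canopy_latent_heat(124.83, 300.0, 1000.0, 10.0) == pytest.approx(
            150.0, rel=1e-3
        )

    def test_strictly_decreasing_in_r_bs(self):
        vals = [canopy_latent_heat(r, 300.0, 1000.0, 10.0) for r in (50, 100, 200, 400)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_closed_stomata_limit(self):
        assert canopy_latent_heat(np.inf, 300.0, 1000.0, 10.0) == 0.0


class TestInversion:
    def test_matches_numerical_root_solve(self):
        r_bs = invert_to_r_bs(150.0 / C.lambda_v, 300.0, 1000.0, 10.0)
        oracle = solve_r_bs_numerically(150.0 / C.lambda_v, 300.0, 1000.0, 10.0, C)
        assert r_bs == pytest.approx(124.83, rel=1e-3)
        assert r_bs == pytest.approx(oracle, rel=1e-9)

    def test_conductance_units_for_example(self):
        r_bs = invert_to_r_bs(150.0 / C.lambda_v, 300.0, 1000.0, 10.0)
        g_mm_s = 1000.0 / r_bs
        assert g_mm_s == pytest.approx(8.01, rel=2e-3)
        assert g_mm_s * 41.04 == pytest.approx(328.8, rel=2e-3)

    def test_oracle_equivalence_on_random_tuples(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            lam_e = rng.uniform(10, 600)
            r_c = rng.uniform(0, 900)
            d_c = rng.uniform(1, 4000)
            r_bh = rng.uniform(1, 60)
            closed = invert_to_r_bs(lam_e / C.lambda_v, r_c, d_c, r_bh)
            if closed <= 1e-5:  # non-physical tuple; closed form flags it
                continue
            oracle = solve_r_bs_numerically(lam_e / C.lambda_v, r_c, d_c, r_bh, C)
            assert closed == pytest.approx(oracle, rel=1e-9)

    @settings(max_examples=300, deadline=None)
    @given(**positive_drivers)
    def test_round_trip_identity(self, lam_e, r_c, d_c, r_bh):
        """Inversion then forward evaluation returns the input flux."""
        r_bs = invert_to_r_bs(lam_e / C.lambda_v, r_c, d_c, r_bh)
        if r_bs <= 0:
            return  # inconsistent drivers are flagged upstream, not clamped
        assert canopy_latent_heat(r_bs, r_c, d_c, r_bh) == pytest.approx(
            lam_e, rel=1e-9
        )

    @settings(max_examples=200, deadline=None)
    @given(r_bs=st.floats(5.0, 2000.0), r_c=st.floats(0.0, 900.0),
           d_c=st.floats(1.0, 4000.0), r_bh=st.floats(1.0, 60.0))
    def test_reverse_round_trip_identity(self, r_bs, r_c, d_c, r_bh):
        """Forward evaluation then inversion returns the input resistance."""
        lam_e = canopy_latent_heat(r_bs, r_c, d_c, r_bh)
        assert invert_to_r_bs(lam_e / C.lambda_v, r_c, d_c, r_bh) == pytest.approx(
            r_bs, rel=1e-9
        )

    def test_monotonicity_in_drivers(self):
        base = invert_to_r_bs(0.05, 300.0, 1000.0, 10.0)
        assert invert_to_r_bs(0.06, 300.0, 1000.0, 10.0) < base
        assert invert_to_r_bs(0.05, 300.0, 1500.0, 10.0) > base

    def test_nonpositive_flux_rejected(self):
        with pytest.raises(InvalidInputError):
            invert_to_r_bs(0.0, 300.0, 1000.0, 10.0)


class TestLeafScaling:
    @pytest.mark.parametrize("r_bs, lai, expected", [(100.0, 1.0, 100.0),
                                                     (100.0, 2.0, 200.0)])
    def test_examples(self, r_bs, lai, expected):
        assert leaf_stomatal_equivalent(r_bs, lai, 2.0) == expected

    @settings(max_examples=100, deadline=None)
    @given(r_s=st.floats(10, 5000), lai=st.floats(0.2, 4.0))
    def test_round_trip_with_bulk_aggregation(self, r_s, lai):
        r_bs = 2.0 * r_s / (2.0 * lai)  # n r_s / (2 LAI)
        assert leaf_stomatal_equivalent(r_bs, lai, 2.0) == pytest.approx(r_s, rel=1e-12)


class TestFiltering:
    def _records(self, r_c_values):
        n = len(r_c_values)
        return compute_flux_records(
            np.full(n, 0.05), np.full(n, 1000.0), np.asarray(r_c_values, float),
            np.full(n, 10.0),
        )

    def test_strictly_less_than_threshold_excluded(self):
        records = self._records([0.0, 49.0, 50.0, 51.0, 300.0])
        kept = records.loc[~records["filtered"], "r_c"].tolist()
        assert kept == [50.0, 51.0, 300.0]
        assert len(records) == 5  # marking, never deletion

    def test_zero_threshold_retains_all(self):
        records = compute_flux_records(
            np.full(3, 0.05), np.full(3, 1000.0), np.array([0.0, 10.0, 300.0]),
            np.full(3, 10.0), rc_threshold=0.0,
        )
        assert (~records["filtered"]).all()

    def test_filter_reasons_are_recorded(self):
        records = compute_flux_records(
            np.array([0.05, -0.01, 0.05, np.nan]),
            np.array([1000.0, 1000.0, -5.0, 1000.0]),
            np.full(4, 300.0), np.full(4, 10.0),
        )
        assert records["filter_reason"].tolist() == [
            "", "nonpositive_flux", "nonpositive_vpd", "missing",
        ]

    def test_nonphysical_resistance_flagged_not_clamped(self):
        # huge flux at tiny drivers forces a negative closed-form r_bs
        records = compute_flux_records(
            np.array([5.0]), np.array([10.0]), np.array([60.0]), np.array([10.0]),
        )
        assert records["filter_reason"].iloc[0] == "nonphysical_rbs"
        assert records["r_bs"].iloc[0] < 0
        assert np.isnan(records["g_bs_mm_s"].iloc[0])

    def test_filter_low_radiation_marks_in_place(self):
        records = self._records([20.0, 300.0])
        records.loc[records.index[0], ["filtered", "filter_reason"]] = [False, ""]
        out = filter_low_radiation(records, threshold=100.0)
        assert out["filtered"].tolist() == [True, False]
        assert len(out) == len(records)


class TestDailySummary:
    def _series(self, values, start="2020-07-01 00:15"):
        idx = pd.date_range(start, periods=len(values), freq="15min")
        return pd.Series(values, index=idx, dtype=float)

    def test_constant_series_returns_constant(self):
        s = self._series([3.0] * 96)
        daily = daily_max_hourly_running_mean(s)
        assert daily.iloc[0] == pytest.approx(3.0)

    def test_single_spike_spreads_over_window(self):
        values = [0.0] * 40
        values[20] = 8.0
        daily = daily_max_hourly_running_mean(self._series(values))
        assert daily.iloc[0] == pytest.approx(2.0)  # 8 / 4

    def test_windows_containing_gaps_are_skipped(self):
        values = [1.0, 1.0, np.nan, 1.0, 9.0, 1.0, 1.0]
        daily = daily_max_hourly_running_mean(self._series(values))
        # only the final window (9,1,1 preceded by 1) is complete
        assert daily.iloc[0] == pytest.approx(3.0)

    def test_all_filtered_day_is_missing(self):
        s = self._series([np.nan] * 96)
        daily = daily_max_hourly_running_mean(s)
        assert daily.isna().all()
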