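import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npbudget.core_data import (EARTH_RADIUS_M, GridField, StatTable,
                                backcast_with_proxy, cell_area_ha,
                                disaggregate_to_grid, interpolate_gaps,
                                scale_subnational)


class TestInterpolateGaps:
    @pytest.mark.parametrize("series, year, expected", [
        ({2000: 10, 2004: 18}, 2002, 14.0),
        ({2000: 10}, 2000, 10.0),
        ({1990: 0, 1995: 10, 2000: 10}, 1993, 6.0),
    ])
    def test_examples(self, series, year, expected):
        assert interpolate_gaps(series)[year] == pytest.approx(expected)

    def test_observed_years_pass_through(self):
        out = interpolate_gaps({1990: 3.5, 1993: 9.0, 2000: 1.0})
        assert out[1990] == 3.5 and out[1993] == 9.0 and out[2000] == 1.0

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            interpolate_gaps({})

    def test_extrapolation_rejected(self):
        with pytest.raises(ValueError, match="outside observed span"):
            interpolate_gaps({2000: 1, 2005: 2}, years=[1999])

    @settings(max_examples=50, derandomize=True)
    @given(a=st.floats(-5, 5), b=st.floats(-100, 100),
           obs=st.sets(st.integers(1970, 2010), min_size=2, max_size=10))
    def test_exact_on_affine_series(self, a, b, obs):
        """Linear interpolation recovers y = a*year + b at every year."""
        obs = sorted(obs)
        series = {y: a * y + b for y in obs}
        out = interpolate_gaps(series, range(obs[0], obs[-1] + 1))
        for y in range(obs[0], obs[-1] + 1):
            assert out[y] == pytest.approx(a * y + b, rel=1e-9, abs=1e-7)


class TestBackcastWithProxy:
    def test_ratio_rule(self):
        out = backcast_with_proxy({1990: 50}, {1985: 80, 1990: 100})
        assert out[1985] == pytest.approx(40.0)

    def test_flat_proxy_keeps_anchor(self):
        out = backcast_with_proxy({1990: 7.0}, {1980: 3, 1985: 3, 1990: 3})
        assert out[1980] == out[1985] == 7.0

    def test_zero_anchor_target_gives_zeros(self):
        out = backcast_with_proxy({1990: 0.0}, {1985: 80, 1990: 100})
        assert out[1985] == 0.0

    def test_zero_proxy_at_anchor_rejected(self):
        with pytest.raises(ValueError, match="zero at anchor"):
            backcast_with_proxy({1990: 50}, {1985: 80, 1990: 0})

    def test_forward_fill_uses_latest_anchor(self):
        out = backcast_with_proxy({1990: 10}, {1990: 100, 1995: 150})
        assert out[1995] == pytest.approx(15.0)


class TestScaleSubnational:
    @pytest.mark.parametrize("sub, total, expected", [
        ({"a": 2, "b": 3}, 10, {"a": 4.0, "b": 6.0}),
        ({"a": 5, "b": 5}, 10, {"a": 5.0, "b": 5.0}),
        ({"a": 1, "b": 2, "c": 7}, 5, {"a": 0.5, "b": 1.0, "c": 3.5}),
    ])
    def test_examples(self, sub, total, expected):
        out = scale_subnational(sub, total)
        for k in expected:
            assert out[k] == pytest.approx(expected[k])

    def test_zero_key_rejected(self):
        with pytest.raises(ValueError, match="no distribution key"):
            scale_subnational({"a": 0.0, "b": 0.0}, 5.0)

    def test_zero_total_gives_zeros(self):
        assert scale_subnational({"a": 1, "b": 2}, 0.0) == {"a": 0.0, "b": 0.0}

    @settings(max_examples=100, derandomize=True)
    @given(vals=st.lists(st.floats(0.01, 1e6), min_size=1, max_size=20),
           total=st.floats(0, 1e9))
    def test_conserves_total(self, vals, total):
        sub = {f"u{i}": v for i, v in enumerate(vals)}
        out = scale_subnational(sub, total)
        assert sum(out.values()) == pytest.approx(total, rel=1e-9, abs=1e-9)


class TestGridField:
    def _weights(self):
        data = np.zeros((360, 720))
        mask = np.zeros((360, 720), bool)
        data[100, 5], data[101, 5] = 1.0, 3.0
        mask[100, 5] = mask[101, 5] = True
        return GridField(data, mask)

    def test_disaggregate_proportional(self):
        out = disaggregate_to_grid(100.0, self._weights())
        assert out.data[100, 5] == pytest.approx(25.0)
        assert out.data[101, 5] == pytest.approx(75.0)
        assert out.total() == pytest.approx(100.0, rel=1e-12)

    def test_disaggregate_zero_total(self):
        assert disaggregate_to_grid(0.0, self._weights()).total() == 0.0

    def test_disaggregate_zero_weights_rejected(self):
        empty = GridField(np.zeros((360, 720)), np.ones((360, 720), bool))
        with pytest.raises(ValueError, match="zero weight"):
            disaggregate_to_grid(5.0, empty)

    def test_rate_mass_round_trip(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 10, (360, 720))
        mask = rng.random((360, 720)) > 0.5
        gf = GridField(data, mask, units="kg/ha")
        back = gf.rate_to_mass().mass_to_rate()
        assert np.allclose(back.data[mask], data[mask], rtol=1e-12)

    def test_cell_areas_sum_to_earth_surface(self):
        total_m2 = cell_area_ha().sum() * 720 * 1e4
        assert total_m2 == pytest.approx(4 * np.pi * EARTH_RADIUS_M**2, rel=1e-9)

    def test_masked_cells_excluded_from_total(self):
        gf = self._weights()
        gf.data[np.where(~gf.mask)] = np.nan
        assert gf.total() == pytest.approx(4.0)

    def test_netcdf_round_trip(self, tmp_path):
        gf = self._weights()
        gf.units = "kg N/ha/yr"
        gf.to_netcdf(tmp_path / "f.nc")
        back = GridField.from_netcdf(tmp_path / "f.nc")
        assert back.units == "kg N/ha/yr"
        assert np.array_equal(back.mask, gf.mask)
        assert np.allclose(back.data[gf.mask], gf.data[gf.mask])

    def test_text_round_trip(self, tmp_path):
        gf = self._weights()
        gf.to_text(tmp_path / "f.txt")
        back = GridField.from_text(tmp_path / "f.txt")
        assert np.allclose(back.data[gf.mask], gf.data[gf.mask])


class TestStatTable:
    def _df(self):
        return pd.DataFrame({
            "unit_id": ["A", "A", "A"], "year": [1970, 1972, 1974],
            "item": ["wheat"] * 3, "value": [1.0, 3.0, 5.0],
            "unit": ["kg/yr"] * 3})

    def test_duplicate_keys_rejected(self):
        df = self._df()
        df.loc[1, "year"] = 1970
        with pytest.raises(ValueError, match="duplicate"):
            StatTable(df)

    def test_negative_values_rejected(self):
        df = self._df()
        df.loc[0, "value"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            StatTable(df)

    def test_complete_fills_interior_years(self):
        tbl = StatTable(self._df()).complete(range(1970, 1975))
        ser = tbl.series("A", "wheat")
        assert ser[1971] == pytest.approx(2.0)
        assert ser[1973] == pytest.approx(4.0)
        assert ser[1970] == 1.0 and ser[1974] == 5.0
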