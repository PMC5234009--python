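import numpy as np
import pandas as pd
import pytest

from npbudget.budgets_indicators import (TERM_COLUMNS, aggregate_regions,
                                         compute_budgets,
                                         cumulative_residual_p,
                                         fixation_share, n_budget,
                                         np_molar_ratio, nue_pue, p_budget,
                                         residual_p)
from npbudget.core_data import RegionMap, UnitInfo


def terms_frame(rows):
    df = pd.DataFrame(rows, columns=["unit_id", "year"] + TERM_COLUMNS)
    return df.set_index(["unit_id", "year"])


class TestBudgetEquations:
    def test_n_budget_example(self):
        t = terms_frame([("A", 2000, 10, 5, 100, 35, 90, 0, 0, 0, 0, 1)])
        assert n_budget(t).iloc[0] == pytest.approx(60.0)

    def test_all_zero(self):
        t = terms_frame([("A", 2000, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1)])
        assert n_budget(t).iloc[0] == 0.0

    def test_balance_boundary(self):
        t = terms_frame([("A", 2000, 10, 10, 10, 10, 40, 0, 0, 0, 0, 1)])
        assert n_budget(t).iloc[0] == 0.0

    def test_p_budget_and_residual(self):
        t = terms_frame([("A", 2000, 0, 0, 0, 0, 0, 15, 5, 12, 2, 1)])
        pb = p_budget(t)
        assert pb.iloc[0] == pytest.approx(8.0)
        assert residual_p(pb, t["P_runoff"]).iloc[0] == pytest.approx(6.0)

    def test_residual_can_signal_mining(self):
        t = terms_frame([("A", 2000, 0, 0, 0, 0, 0, 6, 0, 6, 2, 1)])
        assert residual_p(p_budget(t), t["P_runoff"]).iloc[0] == pytest.approx(-2.0)

    def test_missing_term_rejected(self):
        t = terms_frame([("A", 2000, 1, 1, 1, 1, 1, 1, 1, 1, 0, 1)])
        with pytest.raises(KeyError):
            n_budget(t.drop(columns="N_dep"))

    def test_closure_identity_random_tables(self):
        rng = np.random.default_rng(1)
        rows = [("U%d" % i, 2000 + i, *rng.uniform(0, 100, 9), 1.0)
                for i in range(50)]
        t = terms_frame(rows)
        out = compute_budgets(t)
        lhs = out["N_budget"]
        rhs = (t["N_fix"] + t["N_dep"] + t["N_fert"] + t["N_man"]
               - t["N_withdr"])
        assert np.allclose(lhs, rhs, rtol=1e-12)
        assert np.allclose(out["P_residual"],
                           out["P_budget"] - t["P_runoff"], rtol=1e-12)


class TestEfficiencies:
    def test_identity_when_balanced(self):
        assert nue_pue(100.0, 100.0) == 1.0

    def test_global_scale_example(self):
        assert nue_pue(100.0, 45.0) == pytest.approx(0.45)

    def test_zero_inputs_undefined(self):
        assert np.isnan(nue_pue(0.0, 5.0))

    def test_pue_above_one_iff_negative_p_budget(self):
        """With runoff excluded from inputs, PUE > 1 <=> P_fert+P_man < P_withdr."""
        rng = np.random.default_rng(2)
        for _ in range(200):
            fert, man, withdr = rng.uniform(0.1, 50, 3)
            pue = nue_pue(fert + man, withdr)
            assert (pue > 1) == (fert + man - withdr < 0)


class TestIndicatorArithmetic:
    def test_cumulative_unit_conversion(self):
        # 10 kg/ha/yr on 1e6 ha for 4 years -> 0.04 Tg
        out = cumulative_residual_p([10.0] * 4, [1e6] * 4)
        assert out[-1] == pytest.approx(0.04)

    def test_zero_residual(self):
        assert cumulative_residual_p([0, 0], [1e6, 1e6])[-1] == 0.0

    def test_negative_residual_draws_down(self):
        out = cumulative_residual_p([10.0, -5.0], [1e6, 1e6])
        assert out[1] < out[0]

    def test_misaligned_series_rejected(self):
        with pytest.raises(ValueError):
            cumulative_residual_p([1.0], [1e6, 1e6])

    def test_molar_ratio_one_mole_each(self):
        assert np_molar_ratio(14.007, 30.974) == pytest.approx(1.0)

    def test_molar_ratio_mass_ratio_one(self):
        assert np_molar_ratio(5.0, 5.0) == pytest.approx(30.974 / 14.007)

    def test_molar_ratio_global_fertilizer_scale(self):
        assert np_molar_ratio(95.0, 38.0) == pytest.approx(
            95.0 * 30.974 / (14.007 * 38.0), rel=1e-12)

    def test_fixation_share(self):
        assert fixation_share(20.0, 30.0, 30.0, 20.0) == pytest.approx(0.20)
        assert fixation_share(0.0, 1.0, 1.0, 1.0) == 0.0
        assert fixation_share(5.0, 0.0, 0.0, 0.0) == 1.0


class TestAggregateRegions:
    def _map(self):
        return RegionMap({
            "A": UnitInfo("A", "R", "high_income", "high_income"),
            "B": UnitInfo("B", "R", "high_income", "high_income"),
            "C": UnitInfo("C", "R", "ssa", "developing"),
        })

    def test_region_nue_is_ratio_of_sums(self):
        # NUE 0.4 and 0.6 with equal inputs -> regional NUE 0.5
        t = terms_frame([
            ("A", 2000, 0, 0, 100, 0, 40, 0, 0, 0, 0, 10.0),
            ("B", 2000, 0, 0, 100, 0, 60, 0, 0, 0, 0, 10.0),
        ])
        out = aggregate_regions(t, self._map(), ["high_income"])
        assert out.loc[("high_income", 2000), "NUE"] == pytest.approx(0.5)

    def test_single_country_region_identity(self):
        t = terms_frame([("C", 2000, 1, 2, 3, 4, 5, 6, 7, 8, 1, 10.0)])
        out = aggregate_regions(t, self._map(), ["ssa"])
        assert out.loc[("ssa", 2000), "NUE"] == pytest.approx(5.0 / 10.0)

    def test_world_is_partition_of_archetypes(self):
        t = terms_frame([
            ("A", 2000, 1, 1, 10, 1, 5, 3, 1, 2, 0.5, 10.0),
            ("C", 2000, 2, 0, 5, 2, 4, 1, 1, 1, 0.2, 20.0),
        ])
        out = aggregate_regions(t, self._map(),
                                ["world", "high_income", "ssa"])
        total_area = (out.loc[("high_income", 2000), "area_ha"]
                      + out.loc[("ssa", 2000), "area_ha"])
        assert out.loc[("world", 2000), "area_ha"] == pytest.approx(total_area)

    def test_unmapped_unit_rejected(self):
        t = terms_frame([("Z", 2000, 1, 1, 1, 1, 1, 1, 1, 1, 0, 1.0)])
        with pytest.raises(KeyError, match="Z"):
            aggregate_regions(t, self._map(), ["world"])
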