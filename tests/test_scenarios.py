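"""Scenario engine: pricing rules, demand response, revenue identities."""

import numpy as np
import pytest

from cigtax.elasticity import ElasticityTable
from cigtax.market import LEGAL_PCS, packs_per_year
from cigtax.scenarios import (
    CostTable,
    baseline_markups,
    demand_response,
    scenario_I_price,
)
from cigtax.tax import LOCAL, NATIONAL_MAX, TaxComponent, TaxRegime

from conftest import make_market


def cbs_regime():
    return TaxRegime([
        TaxComponent("CBS av", "ad_valorem", rate=0.22, base=NATIONAL_MAX),
        TaxComponent("CBS sp", "specific", amount=1.10),
    ])


class TestBaselineMarkups:
    def test_price_twice_cost_no_tax(self):
        mkt = make_market(
            {("SP", 2): (100.0, 6.0, 10.0), ("RJ", 2): (100.0, 6.0, 10.0)},
            {"SP": 1e6, "RJ": 1e6},
        )
        marks = baseline_markups(mkt, TaxRegime([]), CostTable({2: 3.0}))
        assert np.allclose(marks.by_state, 1.0)
        assert marks.weighted_avg[2] == pytest.approx(1.0)
        assert marks.maximum[2] == pytest.approx(1.0)

    def test_hand_cross_check_and_state_variation(self):
        regime = TaxRegime(
            [TaxComponent("ICMS", "ad_valorem", rate=0.30, level="state")],
            {"RJ": {"ICMS": 0.35}},
        )
        mkt = make_market(
            {("SP", 2): (300.0, 6.0, 10.0), ("RJ", 2): (100.0, 6.0, 10.0)},
            {"SP": 1e6, "RJ": 1e6},
        )
        marks = baseline_markups(mkt, regime, CostTable({2: 2.0}))
        # SP: (6 - 1.8 - 2)/2 = 1.1 ; RJ: (6 - 2.1 - 2)/2 = 0.95
        assert marks.by_state.loc[("SP", 2)] == pytest.approx(1.10)
        assert marks.by_state.loc[("RJ", 2)] == pytest.approx(0.95)
        # markups differ across states iff rates differ (same prices here)
        assert marks.by_state.loc[("SP", 2)] != marks.by_state.loc[("RJ", 2)]
        # consumer-weighted average: (300*1.1 + 100*0.95)/400
        assert marks.weighted_avg[2] == pytest.approx(1.0625)
        assert marks.maximum[2] == pytest.approx(1.10)

    def test_negative_markup_rejected(self):
        mkt = make_market({("SP", 2): (100.0, 6.0, 10.0)}, {"SP": 1e6})
        with pytest.raises(ValueError, match="inconsistent"):
            baseline_markups(mkt, TaxRegime([]), CostTable({2: 7.0}))


class TestScenarioPrices:
    def test_single_state_cbs_floor(self):
        # negligible cost: the floor is set by the tax wedge alone
        prices = scenario_I_price(CostTable({2: 0.005}), cbs_regime(), ["SP"])
        assert prices[2] == pytest.approx(1.42)

    def test_higher_icms_state_never_lowers_price(self):
        base = TaxRegime(
            [TaxComponent("ICMS", "ad_valorem", rate=0.30, level="state"),
             TaxComponent("CBS av", "ad_valorem", rate=0.22, base=NATIONAL_MAX),
             TaxComponent("CBS sp", "specific", amount=1.10)],
            {"RJ": {"ICMS": 0.35}},
        )
        costs = CostTable({2: 1.0, 3: 1.5, 4: 3.0})
        p_one = scenario_I_price(costs, base, ["SP"])
        p_two = scenario_I_price(costs, base, ["SP", "RJ"])
        for k in costs.pcs():
            assert p_two[k] >= p_one[k]


class TestDemandResponse:
    def one_cell_market(self, price=10.0):
        return make_market({("PR", 4): (1000.0, price, 12.0)}, {"PR": 1e6})

    def elasticities(self, prev, cond, region="South", pc=4):
        return ElasticityTable({region: prev}, {(region, pc): cond})

    def test_zero_price_change_is_identity(self):
        mkt = self.one_cell_market()
        out = demand_response(mkt, self.elasticities(-0.21, -0.18), {4: 10.0})
        assert np.allclose(out.table["smokers"], mkt.table["smokers"])
        assert np.allclose(out.table["mean_cpd"], mkt.table["mean_cpd"])

    def test_total_elasticity_applied_linearly(self):
        # +10% with total elasticity -0.39 -> exactly -3.9% packs
        mkt = self.one_cell_market()
        out = demand_response(mkt, self.elasticities(-0.21, -0.18), {4: 11.0})
        packs0 = packs_per_year(1000.0, 12.0)
        packs1 = packs_per_year(
            out.table.loc[("PR", 4), "smokers"], out.table.loc[("PR", 4), "mean_cpd"]
        )
        assert 100.0 * (packs1 / packs0 - 1.0) == pytest.approx(-3.9, abs=1e-9)
        # smokers carry the extensive margin
        assert out.table.loc[("PR", 4), "smokers"] == pytest.approx(1000.0 * (1 - 0.021))

    def test_pc1_cells_fixed(self):
        mkt = make_market(
            {("PR", 1): (500.0, 4.0, 14.0), ("PR", 4): (1000.0, 10.0, 12.0)},
            {"PR": 1e6},
        )
        out = demand_response(mkt, self.elasticities(-0.21, -0.18), {4: 12.0})
        assert out.table.loc[("PR", 1)].equals(mkt.table.loc[("PR", 1)])

    def test_extreme_change_clamped_with_warning(self):
        mkt = self.one_cell_market(price=2.0)
        elas = self.elasticities(-0.3, -0.9)  # total -1.2, d = +100%
        with pytest.warns(UserWarning, match="clamped"):
            out = demand_response(mkt, elas, {4: 4.0})
        packs = packs_per_year(
            out.table.loc[("PR", 4), "smokers"], out.table.loc[("PR", 4), "mean_cpd"]
        )
        assert packs == 0.0

    def test_price_decrease_handled_symmetrically(self):
        mkt = self.one_cell_market(price=10.0)
        out = demand_response(mkt, self.elasticities(-0.21, -0.18), {4: 9.0})
        packs0 = packs_per_year(1000.0, 12.0)
        packs1 = packs_per_year(
            out.table.loc[("PR", 4), "smokers"], out.table.loc[("PR", 4), "mean_cpd"]
        )
        assert 100.0 * (packs1 / packs0 - 1.0) == pytest.approx(+3.9, abs=1e-9)


class TestDefaultSimulation:
    """Properties of the three scenarios under the default study fixture."""

    def test_prices_ordered_and_uniform(self, default_run):
        res = default_run["results"]
        for k in LEGAL_PCS:
            assert res["I"].prices[k] <= res["II"].prices[k] <= res["III"].prices[k]
        for sid in ("I", "II", "III"):
            t = res[sid].market.table
            for k in LEGAL_PCS:
                prices = t["mean_price"].xs(k, level="pc")
                assert float(prices.std()) == pytest.approx(0.0, abs=1e-12)

    def test_consumption_decline_deepens(self, default_run):
        res = default_run["results"]
        for k in LEGAL_PCS:
            assert (
                res["I"].consumption_change_by_pc[k]
                > res["II"].consumption_change_by_pc[k]
                > res["III"].consumption_change_by_pc[k]
            )

    def test_revenue_ordering(self, default_run):
        res = default_run["results"]
        assert (
            res["I"].revenue_change_pct
            > res["II"].revenue_change_pct
            > res["III"].revenue_change_pct
            > 0.0
        )

    def test_low_and_medium_categories_collapse_in_scenario_I(self, default_run):
        p = default_run["results"]["I"].prices
        assert abs(p[2] / p[3] - 1.0) < 0.02

    def test_implicit_floor_above_official_floor(self, default_run):
        assert default_run["results"]["I"].prices[2] > 5.00

    def test_burden_below_one_everywhere(self, default_run):
        for res in default_run["results"].values():
            assert all(0 < b < 1 for b in res.burden_by_pc.values())

    def test_revenue_decomposition(self, default_run):
        for res in default_run["results"].values():
            assert res.revenue_by_state.sum() == pytest.approx(res.revenue, rel=1e-6)
            assert sum(res.revenue_by_pc.values()) == pytest.approx(res.revenue, rel=1e-6)

    def test_illicit_consumption_conserved(self, default_run):
        base = default_run["calibration"].market
        base_pc1 = packs_per_year(
            base.table["smokers"].xs(1, level="pc"),
            base.table["mean_cpd"].xs(1, level="pc"),
        ).sum()
        for res in default_run["results"].values():
            after = packs_per_year(
                res.market.table["smokers"].xs(1, level="pc"),
                res.market.table["mean_cpd"].xs(1, level="pc"),
            ).sum()
            assert after == pytest.approx(base_pc1, rel=1e-12)

    def test_smokers_never_negative(self, default_run):
        for res in default_run["results"].values():
            assert (res.market.table["smokers"] >= 0).all()
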