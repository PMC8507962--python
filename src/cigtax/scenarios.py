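"""Industry price-setting scenarios under the reform regime.

Because the reform charges the ad-valorem component on the *highest*
national price per brand, undercutting the top price raises a seller's
burden without lowering its tax bill, so producers rationally charge one
uniform national price per price category. Three strategies are simulated:

* **Scenario I — minimum price adjustment**: the lowest uniform price with
  non-negative profit and burden below 100% in every state (the implicit
  price floor, taken at the least favourable state);
* **Scenario II — average pre-reform markup**: the price restoring the
  consumer-weighted average of baseline state markups, never below the
  scenario I floor;
* **Scenario III — maximum pre-reform markup**: the price restoring the
  highest baseline state markup.

Smokers respond through the linear point-elasticity rule
``%ΔQ = elasticity x %ΔP`` applied per state against that state's baseline
price: the smoker count scales with the prevalence elasticity, the
intensity with the conditional elasticity, both floored at zero. The
illicit segment (PC1) is held fixed throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .elasticity import ElasticityTable
from .market import (
    LEGAL_PCS,
    MarketState,
    baseline_revenue,
    national_max_prices,
    packs_per_year,
    revenue_table,
)
from .states import region_of
from .tax import TaxRegime, assess, floor_price, price_from_markup, round_up_cent

SCENARIOS = ("I", "II", "III")


@dataclass(frozen=True)
class CostTable:
    """Constant per-pack production-to-retail unit cost per price category
    (BRL/pack, identical across states)."""

    unit_cost: dict[int, float]

    def __post_init__(self) -> None:
        for k, c in self.unit_cost.items():
            if c <= 0:
                raise ValueError(f"unit cost for PC{k} must be positive")

    def __getitem__(self, pc: int) -> float:
        return self.unit_cost[pc]

    def pcs(self) -> list[int]:
        return sorted(self.unit_cost)


@dataclass(frozen=True)
class MarkupTable:
    """Baseline producer markups per (state, PC) with consumer-weighted
    averages and maxima per PC."""

    by_state: pd.Series  # index (state, pc)
    weighted_avg: dict[int, float]
    maximum: dict[int, float]


def baseline_markups(
    market: MarketState, regime: TaxRegime, costs: CostTable
) -> MarkupTable:
    """Markup over unit cost in every legal (state, PC) cell of the
    baseline market: ``m = (p - tax - c) / c``.

    Weights for the per-PC average are each state's share of the PC's
    smokers. Raises if any markup is negative (costs inconsistent with
    observed prices).
    """
    pmax = national_max_prices(market)
    rows = {}
    for (state, pc), row in market.table.iterrows():
        if pc == 1 or row["smokers"] <= 0:
            continue
        a = assess(row["mean_price"], max(pmax[pc], row["mean_price"]), state, regime)
        c = costs[pc]
        m = (row["mean_price"] - a.total_tax - c) / c
        if m < -1e-9:
            raise ValueError(
                f"negative baseline markup {m:.3f} in ({state}, PC{pc}): "
                "unit costs are inconsistent with observed prices"
            )
        rows[(state, pc)] = m
    ser = pd.Series(rows).rename_axis(["state", "pc"]).sort_index()
    smokers = market.table["smokers"]
    avg, mx = {}, {}
    for k in costs.pcs():
        if k == 1:
            continue
        cells = ser.xs(k, level="pc")
        w = smokers.xs(k, level="pc").reindex(cells.index)
        avg[k] = float(np.average(cells, weights=w))
        mx[k] = float(cells.max())
    return MarkupTable(ser, avg, mx)


# -- uniform national price per scenario --------------------------------------

def scenario_I_price(costs: CostTable, regime_reform: TaxRegime, states) -> dict[int, float]:
    """Implicit price floor per PC: the highest state-level floor price, so
    the price is feasible everywhere."""
    return {
        k: max(floor_price(costs[k], s, regime_reform) for s in states)
        for k in costs.pcs() if k != 1
    }


def scenario_II_price(
    markups: MarkupTable, costs: CostTable, regime_reform: TaxRegime, states
) -> dict[int, float]:
    """Price restoring the weighted-average baseline markup, floored at the
    scenario I price."""
    floor = scenario_I_price(costs, regime_reform, states)
    out = {}
    for k, m in markups.weighted_avg.items():
        p = max(
            round_up_cent(price_from_markup(m, costs[k], s, regime_reform))
            for s in states
        )
        out[k] = max(p, floor[k])
    return out


def scenario_III_price(
    markups: MarkupTable, costs: CostTable, regime_reform: TaxRegime, states
) -> dict[int, float]:
    """Price restoring the highest baseline state markup, floored at the
    scenario I price."""
    floor = scenario_I_price(costs, regime_reform, states)
    out = {}
    for k, m in markups.maximum.items():
        p = max(
            round_up_cent(price_from_markup(m, costs[k], s, regime_reform))
            for s in states
        )
        out[k] = max(p, floor[k])
    return out


# -- demand response ----------------------------------------------------------

def demand_response(
    market: MarketState,
    elasticities: ElasticityTable,
    new_prices: dict[int, float],
) -> MarketState:
    """Apply the linear point-elasticity demand response to new uniform
    prices.

    Per legal (state, PC) cell with relative price change
    ``d = (p_new - p_old) / p_old``, pack consumption scales by exactly
    ``1 + total_elasticity(region, PC) * d``: the smoker count carries the
    extensive margin (``1 + prevalence_elasticity * d``) and the intensity
    the remainder (to first order ``1 + conditional_elasticity * d``).
    Both factors are clamped at zero with a warning — the linear
    extrapolation limit. PC1 is unchanged; smokers do not switch
    categories.
    """
    out = market.copy()
    t = out.table
    clamped = []
    for (state, pc), row in market.table.iterrows():
        if pc == 1 or pc not in new_prices:
            continue
        r = region_of(state)
        p_old = row["mean_price"]
        if not np.isfinite(p_old) or row["smokers"] <= 0:
            t.loc[(state, pc), "mean_price"] = new_prices[pc]
            continue
        d = (new_prices[pc] - p_old) / p_old
        e_prev = elasticities.prevalence[r]
        e_tot = e_prev + elasticities.conditional[(r, pc)]
        f_prev = 1.0 + e_prev * d
        f_tot = 1.0 + e_tot * d
        if f_prev < 0 or f_tot < 0:
            clamped.append((state, pc))
            f_prev, f_tot = max(f_prev, 0.0), max(f_tot, 0.0)
        f_cond = f_tot / f_prev if f_prev > 0 else 0.0
        t.loc[(state, pc), "smokers"] = row["smokers"] * f_prev
        t.loc[(state, pc), "mean_cpd"] = row["mean_cpd"] * f_cond
        t.loc[(state, pc), "mean_price"] = new_prices[pc]
    if clamped:
        warnings.warn(
            f"elasticity x price change below -100% in cells {clamped}; "
            "consumption clamped to zero (linear extrapolation limit)",
            stacklevel=2,
        )
    return out


# -- scenario results ---------------------------------------------------------

@dataclass
class ScenarioResults:
    """Post-reform prices, demand and revenue of one industry strategy."""

    scenario: str
    prices: dict[int, float]
    market: MarketState
    baseline_market: MarketState
    revenue: float
    baseline_revenue: float
    revenue_by_state: pd.Series = field(repr=False, default=None)
    revenue_by_pc: dict[int, float] = field(default=None)
    burden_by_pc: dict[int, float] = field(default=None)
    consumption_change_by_pc: dict[int, float] = field(default=None)
    consumption_change_by_cell: pd.Series = field(repr=False, default=None)

    @property
    def revenue_change_pct(self) -> float:
        return 100.0 * (self.revenue - self.baseline_revenue) / self.baseline_revenue

    def revenue_shares(self) -> dict[int, float]:
        """Share of tax revenue by legal PC, in percent (sums to 100)."""
        tot = sum(self.revenue_by_pc.values())
        return {k: 100.0 * v / tot for k, v in self.revenue_by_pc.items()}

    def summary(self) -> str:
        lines = [
            f"Scenario {self.scenario}",
            f"  tax revenue: {self.revenue / 1e9:,.2f} BRL Bi "
            f"({self.revenue_change_pct:+.1f}% vs baseline {self.baseline_revenue / 1e9:,.2f})",
        ]
        shares = self.revenue_shares()
        for k in sorted(self.prices):
            lines.append(
                f"  PC{k}: price {self.prices[k]:.2f} BRL, "
                f"burden {100 * self.burden_by_pc[k]:.1f}%, "
                f"consumption {self.consumption_change_by_pc[k]:+.1f}%, "
                f"revenue share {shares[k]:.1f}%"
            )
        return "\n".join(lines)


def run_scenario(
    scenario: str,
    market: MarketState,
    elasticities: ElasticityTable,
    regime_now: TaxRegime,
    regime_reform: TaxRegime,
    costs: CostTable,
) -> ScenarioResults:
    """Price-setting, demand response and revenue aggregation for one
    scenario, against the calibrated baseline market."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    states = market.states
    regime_reform.validate_feasible(states)
    if scenario == "I":
        prices = scenario_I_price(costs, regime_reform, states)
    else:
        marks = baseline_markups(market, regime_now, costs)
        if scenario == "II":
            prices = scenario_II_price(marks, costs, regime_reform, states)
        else:
            prices = scenario_III_price(marks, costs, regime_reform, states)

    base_rev = baseline_revenue(market, regime_now)
    adjusted = demand_response(market, elasticities, prices)
    rev_cells = revenue_table(adjusted, regime_reform)
    revenue = float(rev_cells["revenue"].sum())
    rev_by_state = rev_cells["revenue"].groupby(level="state").sum()
    rev_by_pc = {
        k: float(rev_cells["revenue"].xs(k, level="pc").sum()) for k in LEGAL_PCS
    }

    # burden per PC at the uniform price: consumption-weighted across states
    burden = {}
    for k in LEGAL_PCS:
        p = prices[k]
        packs = packs_per_year(
            adjusted.table["smokers"].xs(k, level="pc"),
            adjusted.table["mean_cpd"].xs(k, level="pc"),
        )
        burdens = np.array([assess(p, p, s, regime_reform).burden for s in states])
        burden[k] = float(np.average(burdens, weights=np.maximum(packs, 1e-9)))

    packs_old = packs_per_year(
        market.table["smokers"], market.table["mean_cpd"]
    )
    packs_new = packs_per_year(
        adjusted.table["smokers"], adjusted.table["mean_cpd"]
    )
    packs_old = pd.Series(packs_old, index=market.table.index)
    packs_new = pd.Series(packs_new, index=adjusted.table.index)
    cell_change = 100.0 * (packs_new - packs_old) / packs_old.replace(0, np.nan)
    change_pc = {}
    for k in LEGAL_PCS:
        o = packs_old.xs(k, level="pc").sum()
        n = packs_new.xs(k, level="pc").sum()
        change_pc[k] = float(100.0 * (n - o) / o)

    return ScenarioResults(
        scenario=scenario,
        prices=prices,
        market=adjusted,
        baseline_market=market,
        revenue=revenue,
        baseline_revenue=base_rev,
        revenue_by_state=rev_by_state,
        revenue_by_pc=rev_by_pc,
        burden_by_pc=burden,
        consumption_change_by_pc=change_pc,
        consumption_change_by_cell=cell_change,
    )


class TaxReformSimulation:
    """Model object tying together a calibrated market, estimated
    elasticities, the two tax regimes and the cost table.

    ``run(scenario)`` returns a :class:`ScenarioResults`; ``run_all()``
    returns the three scenarios keyed by id.
    """

    def __init__(
        self,
        market: MarketState,
        elasticities: ElasticityTable,
        regime_now: TaxRegime,
        regime_reform: TaxRegime,
        costs: CostTable,
    ):
        self.market = market
        self.elasticities = elasticities
        self.regime_now = regime_now
        self.regime_reform = regime_reform
        self.costs = costs

    def run(self, scenario: str) -> ScenarioResults:
        return run_scenario(
            scenario,
            self.market,
            self.elasticities,
            self.regime_now,
            self.regime_reform,
            self.costs,
        )

    def run_all(self) -> dict[str, ScenarioResults]:
        return {s: self.run(s) for s in SCENARIOS}
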