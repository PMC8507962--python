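"""State x price-category market grid and tax-revenue aggregation.

The market is a grid over states and the four price categories (PC1 =
illicit, below the official floor; PC2/PC3/PC4 = low/medium/premium legal
brands). Each cell carries the number of smokers (population-scaled), the
mean pack price and the mean smoking intensity. Revenue aggregation taxes
only the legal categories — illicit packs pay nothing by definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tax import TaxRegime, assess

PCS = (1, 2, 3, 4)
LEGAL_PCS = (2, 3, 4)
PACK_SIZE = 20  # cigarettes per pack, constant throughout
DAYS_PER_YEAR = 365

_COLS = ["smokers", "mean_price", "mean_cpd"]


@dataclass
class MarketState:
    """State x price-category grid of smokers, prices and intensities.

    ``table`` is indexed by ``(state, pc)`` with columns ``smokers``
    (persons), ``mean_price`` (BRL/pack) and ``mean_cpd`` (cigarettes per
    smoker per day). ``populations`` maps state to inhabitants and
    ``price_floor`` is the official minimum legal pack price.
    """

    table: pd.DataFrame
    populations: dict[str, float] = field(default_factory=dict)
    price_floor: float = 5.00

    def __post_init__(self) -> None:
        t = self.table
        if list(t.index.names) != ["state", "pc"]:
            raise ValueError("table must be indexed by (state, pc)")
        missing = [c for c in _COLS if c not in t.columns]
        if missing:
            raise ValueError(f"table missing columns: {missing}")
        self.table = t[_COLS].astype(float).sort_index()

    # -- basic accessors ------------------------------------------------------

    @property
    def states(self) -> list[str]:
        return list(self.table.index.get_level_values("state").unique())

    def shares(self) -> pd.Series:
        """Smoker share of each PC within its state (sums to 1 per state)."""
        smokers = self.table["smokers"]
        tot = smokers.groupby(level="state").transform("sum")
        return smokers / tot

    def total_smokers(self) -> float:
        return float(self.table["smokers"].sum())

    def copy(self) -> "MarketState":
        return MarketState(self.table.copy(), dict(self.populations), self.price_floor)

    # -- validation -----------------------------------------------------------

    def validate(self) -> None:
        t = self.table
        if (t["smokers"] < 0).any():
            raise ValueError("negative smoker counts")
        for state in self.states:
            pcs = set(t.loc[state].index)
            if pcs != set(PCS):
                raise ValueError(f"state {state} missing price categories {set(PCS) - pcs}")
        occupied = t["smokers"] > 0
        pc = t.index.get_level_values("pc")
        illicit_high = occupied & (pc == 1) & (t["mean_price"] >= self.price_floor)
        legal_low = occupied & (pc != 1) & (t["mean_price"] < self.price_floor)
        if illicit_high.any():
            raise ValueError("PC1 cells at or above the official price floor")
        if legal_low.any():
            raise ValueError("legal cells priced below the official price floor")

    # -- serialisation --------------------------------------------------------

    def to_csv(self, path) -> None:
        out = self.table.reset_index()
        out["population"] = out["state"].map(self.populations)
        out["price_floor"] = self.price_floor
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MarketState":
        df = pd.read_csv(path)
        pops = df.drop_duplicates("state").set_index("state")["population"].to_dict()
        floor = float(df["price_floor"].iloc[0]) if "price_floor" in df else 5.00
        table = df.set_index(["state", "pc"])[_COLS]
        return cls(table, pops, floor)


def packs_per_year(smokers, mean_cpd):
    """Annual pack demand of a cell: smokers x cigarettes/day x 365 / 20."""
    return np.asarray(smokers) * np.asarray(mean_cpd) * DAYS_PER_YEAR / PACK_SIZE


def national_max_prices(market: MarketState) -> dict[int, float]:
    """Highest state mean price per PC — the CBS base of each category."""
    return market.table["mean_price"].groupby(level="pc").max().to_dict()


def revenue_table(market: MarketState, regime: TaxRegime) -> pd.DataFrame:
    """Annual tax revenue per (state, pc) cell, BRL/year.

    Legal cells pay the regime's per-pack tax at the cell's mean price
    (ad-valorem components on the national-maximum base use the highest
    state price of the same PC); PC1 cells contribute zero.
    """
    pmax = national_max_prices(market)
    rows = []
    for (state, pc), row in market.table.iterrows():
        if row["smokers"] <= 0:
            rows.append((state, pc, 0.0, 0.0, 0.0))
            continue
        packs = float(packs_per_year(row["smokers"], row["mean_cpd"]))
        if pc == 1 or packs == 0:
            tax_pp = 0.0
        else:
            a = assess(row["mean_price"], max(pmax[pc], row["mean_price"]), state, regime)
            tax_pp = a.total_tax
        rows.append((state, pc, packs, tax_pp, packs * tax_pp))
    out = pd.DataFrame(
        rows, columns=["state", "pc", "packs_year", "tax_per_pack", "revenue"]
    ).set_index(["state", "pc"])
    return out


def baseline_revenue(market: MarketState, regime: TaxRegime) -> float:
    """Total annual tobacco tax revenue of the market under a regime, BRL."""
    regime.validate_feasible(market.states)
    return float(revenue_table(market, regime)["revenue"].sum())
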