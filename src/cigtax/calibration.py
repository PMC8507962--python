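"""Illicit-market calibration against an aggregate revenue target.

Phone-survey data understates the illicit segment, so the baseline market
grid would overstate taxable consumption. The calibration inflates PC1 by
moving a single proportional share ``delta`` of each legal category (the
same factor in every state and category) into PC1 until simulated annual
tax revenue matches the observed aggregate collection. Multiplicative
shrinkage of the legal shares guarantees they never go negative; once
calibrated, the illicit segment is held fixed in every reform scenario.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .market import LEGAL_PCS, MarketState, baseline_revenue
from .tax import TaxRegime


def shift_market(market: MarketState, delta: float) -> MarketState:
    """Move fraction ``delta`` of each legal cell's smokers into PC1.

    Total smokers per state are conserved; cell prices and intensities are
    unchanged (newcomers adopt the illicit segment's price and intensity).
    """
    if not 0 <= delta <= 1:
        raise ValueError("delta must lie in [0, 1]")
    out = market.copy()
    t = out.table
    pc = t.index.get_level_values("pc")
    legal = t.loc[pc != 1, "smokers"]
    moved = legal.groupby(level="state").sum() * delta
    t.loc[pc != 1, "smokers"] = legal * (1.0 - delta)
    for state, extra in moved.items():
        t.loc[(state, 1), "smokers"] += extra
    return out


def revenue_at(market: MarketState, regime: TaxRegime, delta: float) -> float:
    return baseline_revenue(shift_market(market, delta), regime)


@dataclass
class CalibrationResults:
    """Outcome of the illicit-market calibration."""

    delta: float
    market: MarketState
    achieved_revenue: float
    target_revenue: float
    shift_points: pd.Series  # percentage points of smokers moved into PC1, per state

    @property
    def mean_shift_points(self) -> float:
        """Unweighted state average of the PC1 share increase, in p.p."""
        return float(self.shift_points.mean())

    def pc1_shares(self) -> pd.Series:
        sh = self.market.shares()
        return sh[sh.index.get_level_values("pc") == 1].droplevel("pc")

    def summary(self) -> str:
        pc1 = self.pc1_shares()
        return "\n".join([
            "Illicit-market calibration",
            f"  proportional legal-share reduction delta = {self.delta:.6f}",
            f"  target revenue   : {self.target_revenue:,.0f} BRL/yr",
            f"  achieved revenue : {self.achieved_revenue:,.0f} BRL/yr",
            f"  mean shift into PC1: {self.mean_shift_points:.1f} p.p.",
            f"  PC1 share range: {pc1.min():.1%} ({pc1.idxmin()}) "
            f"to {pc1.max():.1%} ({pc1.idxmax()})",
        ])


class IllicitMarketCalibrator:
    """Calibrate the PC1 share of a market so that revenue under the
    current regime matches an observed aggregate target.

    ``fit(target_revenue)`` solves ``revenue(delta) = target`` by bisection
    on ``delta in [0, 1]`` to relative tolerance ``rtol`` (revenue is
    continuous and strictly decreasing in ``delta`` while legal cells are
    populated).
    """

    def __init__(self, market: MarketState, regime: TaxRegime, rtol: float = 1e-6):
        self.market = market
        self.regime = regime
        self.rtol = rtol

    def fit(self, target_revenue: float) -> CalibrationResults:
        if target_revenue < 0:
            raise ValueError("target revenue must be non-negative")
        r0 = baseline_revenue(self.market, self.regime)
        if target_revenue > r0 * (1 + 1e-12):
            raise ValueError(
                f"target revenue {target_revenue:,.0f} exceeds the uncalibrated "
                f"revenue {r0:,.0f}; the calibration can only shrink the legal market"
            )
        if target_revenue == 0 and r0 > 0:
            warnings.warn(
                "zero revenue target: moving the entire legal market into PC1",
                stacklevel=2,
            )
            delta = 1.0
        elif r0 == 0:
            delta = 0.0
        elif abs(r0 - target_revenue) <= self.rtol * target_revenue:
            delta = 0.0
        else:
            lo, hi = 0.0, 1.0  # f(lo) > 0 >= f(hi)
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                f_mid = revenue_at(self.market, self.regime, mid) - target_revenue
                if abs(f_mid) <= self.rtol * target_revenue:
                    lo = hi = mid
                    break
                if f_mid > 0:
                    lo = mid
                else:
                    hi = mid
            delta = 0.5 * (lo + hi)

        adjusted = shift_market(self.market, delta)
        achieved = baseline_revenue(adjusted, self.regime)
        legal_share = self.market.shares()
        legal_share = legal_share[legal_share.index.get_level_values("pc") != 1]
        shift_pp = legal_share.groupby(level="state").sum() * delta * 100.0
        return CalibrationResults(
            delta=float(delta),
            market=adjusted,
            achieved_revenue=float(achieved),
            target_revenue=float(target_revenue),
            shift_points=shift_pp,
        )


def calibrate(
    market: MarketState, regime: TaxRegime, target_revenue: float, rtol: float = 1e-6
) -> CalibrationResults:
    """Functional wrapper around :class:`IllicitMarketCalibrator`."""
    return IllicitMarketCalibrator(market, regime, rtol).fit(target_revenue)
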