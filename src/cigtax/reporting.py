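"""End-to-end pipeline orchestration and summary tables.

Monetary outputs are rounded to 0.01 BRL and percentages to 0.1 p.p. in
the printed tables (internal arithmetic is unrounded).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import calibrate
from .defaults import (
    TARGET_REVENUE,
    current_regime,
    default_config,
    default_costs,
    reform_regime,
)
from .elasticity import ElasticityTable, TwoPartDemandModel
from .market import LEGAL_PCS, MarketState, baseline_revenue, packs_per_year, revenue_table
from .scenarios import SCENARIOS, ScenarioResults, TaxReformSimulation
from .survey import aggregate_market, generate_survey
from .tax import TaxRegime

logger = logging.getLogger("cigtax")


def percent_change(new: float, old: float) -> float:
    """Percent change ``100 (new - old) / old``, reported to one decimal."""
    if old <= 0:
        raise ValueError("reference value must be positive")
    return round(100.0 * (new - old) / old, 1)


def revenue_shares(result: ScenarioResults) -> dict[int, float]:
    """Revenue share per legal PC in percent (sums to 100 within rounding)."""
    return {k: round(v, 2) for k, v in result.revenue_shares().items()}


def baseline_summary(market: MarketState, regime: TaxRegime) -> dict:
    """Baseline column of the summary table: consumption-weighted mean
    price, burden and revenue share per legal PC, plus total collection."""
    cells = revenue_table(market, regime)
    packs = packs_per_year(market.table["smokers"], market.table["mean_cpd"])
    packs = pd.Series(np.asarray(packs), index=market.table.index)
    total = float(cells["revenue"].sum())
    out = {"revenue": total, "pc": {}}
    for k in LEGAL_PCS:
        w = packs.xs(k, level="pc")
        p = market.table["mean_price"].xs(k, level="pc")
        price = float(np.average(p, weights=np.maximum(w, 1e-9)))
        tax_pp = cells["tax_per_pack"].xs(k, level="pc")
        burden = float(np.average(tax_pp / p, weights=np.maximum(w, 1e-9)))
        share = 100.0 * float(cells["revenue"].xs(k, level="pc").sum()) / total
        out["pc"][k] = {"price": price, "burden": burden, "revenue_share": share}
    return out


def summary_table(
    baseline: dict, results: dict[str, ScenarioResults]
) -> pd.DataFrame:
    """Assemble the scenario-comparison table (one feature per row, one
    column per scenario next to the baseline)."""
    cols: dict[str, dict[str, float | str]] = {}
    base_col: dict[str, float | str] = {
        "Tax collection (BRL Bi/yr)": round(baseline["revenue"] / 1e9, 2),
        "Change vs baseline (%)": "",
    }
    for k in LEGAL_PCS:
        b = baseline["pc"][k]
        base_col[f"PC{k} price (BRL)"] = round(b["price"], 2)
        base_col[f"PC{k} tax burden (%)"] = round(100 * b["burden"], 1)
        base_col[f"PC{k} revenue share (%)"] = round(b["revenue_share"], 2)
        base_col[f"PC{k} consumption change (%)"] = ""
    cols["Baseline"] = base_col
    for sid, res in results.items():
        shares = res.revenue_shares()
        col: dict[str, float | str] = {
            "Tax collection (BRL Bi/yr)": round(res.revenue / 1e9, 2),
            "Change vs baseline (%)": percent_change(res.revenue, res.baseline_revenue),
        }
        for k in LEGAL_PCS:
            col[f"PC{k} price (BRL)"] = round(res.prices[k], 2)
            col[f"PC{k} tax burden (%)"] = round(100 * res.burden_by_pc[k], 1)
            col[f"PC{k} revenue share (%)"] = round(shares[k], 2)
            col[f"PC{k} consumption change (%)"] = round(
                res.consumption_change_by_pc[k], 1
            )
        cols[f"Scenario {sid}"] = col
    return pd.DataFrame(cols)


@dataclass
class RunConfig:
    """Parameters of an end-to-end pipeline run."""

    seed: int = 0
    n_respondents: int = 50_000
    target_revenue: float = TARGET_REVENUE
    scenarios: tuple[str, ...] = SCENARIOS
    outdir: Path | None = None
    use_estimated_elasticities: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        bad = [s for s in self.scenarios if s not in SCENARIOS]
        if bad:
            raise ValueError(f"unknown scenario id(s): {bad}")


def run_pipeline(config: RunConfig) -> dict:
    """Run generate -> aggregate -> estimate -> calibrate -> simulate ->
    report; deterministic for a given seed.

    Returns the report bundle (survey, market, elasticities, calibration,
    scenario results, summary table); writes CSV/JSON files when
    ``config.outdir`` is set.
    """
    logging.basicConfig(level=config.log_level)
    logger.info("pipeline start: seed=%d n=%d", config.seed, config.n_respondents)

    gen_cfg = default_config(seed=config.seed, n_respondents=config.n_respondents)
    survey = generate_survey(gen_cfg)
    logger.info("generated %d respondents, %d smokers", len(survey), survey["smokes"].sum())

    market = aggregate_market(survey, gen_cfg.state_populations, gen_cfg.price_floor)
    regime_now, regime_ref = current_regime(), reform_regime()

    if config.use_estimated_elasticities:
        elas = TwoPartDemandModel(survey).fit().table
    else:
        from .defaults import CONDITIONAL_ELASTICITY, PREVALENCE_ELASTICITY

        elas = ElasticityTable(
            dict(PREVALENCE_ELASTICITY),
            {(r, k): v for r, d in CONDITIONAL_ELASTICITY.items() for k, v in d.items()},
        )
    logger.info("elasticities estimated (prevalence %s)", {
        r: round(v, 3) for r, v in elas.prevalence.items()
    })

    cal = calibrate(market, regime_now, config.target_revenue)
    logger.info(
        "calibration: delta=%.4f mean shift %.1f p.p.", cal.delta, cal.mean_shift_points
    )

    costs = default_costs(cal.market, regime_now)
    sim = TaxReformSimulation(cal.market, elas, regime_now, regime_ref, costs)
    results = {sid: sim.run(sid) for sid in config.scenarios}
    base = baseline_summary(cal.market, regime_now)
    table = summary_table(base, results)

    bundle = {
        "survey": survey,
        "market": market,
        "elasticities": elas,
        "calibration": cal,
        "costs": costs,
        "results": results,
        "summary": table,
    }

    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        survey.to_csv(out / "survey.csv", index=False)
        market.to_csv(out / "market.csv")
        cal.market.to_csv(out / "market_calibrated.csv")
        elas.to_csv(out / "elasticities.csv")
        with open(out / "calibration.json", "w") as fh:
            json.dump(
                {
                    "delta": cal.delta,
                    "achieved_revenue": cal.achieved_revenue,
                    "target_revenue": cal.target_revenue,
                    "mean_shift_points": cal.mean_shift_points,
                    "shift_points": cal.shift_points.round(3).to_dict(),
                },
                fh,
                indent=2,
            )
        for sid, res in results.items():
            with open(out / f"scenario_{sid}.json", "w") as fh:
                json.dump(
                    {
                        "scenario": sid,
                        "prices": {k: round(v, 2) for k, v in res.prices.items()},
                        "burden_by_pc": {k: round(v, 4) for k, v in res.burden_by_pc.items()},
                        "revenue": res.revenue,
                        "revenue_change_pct": round(res.revenue_change_pct, 1),
                        "revenue_shares": revenue_shares(res),
                        "consumption_change_by_pc": {
                            k: round(v, 1) for k, v in res.consumption_change_by_pc.items()
                        },
                        "revenue_by_state": res.revenue_by_state.round(0).to_dict(),
                    },
                    fh,
                    indent=2,
                )
        table.to_csv(out / "summary.csv")
        logger.info("report bundle written to %s", out)
    return bundle
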