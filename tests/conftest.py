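"""Shared fixtures: small hand-built markets, and two expensive
session-scoped studies (the Monte-Carlo elasticity-recovery study and the
default end-to-end simulation) reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cigtax.defaults import (
    CONDITIONAL_ELASTICITY,
    PREVALENCE_ELASTICITY,
    TARGET_REVENUE,
    current_regime,
    default_config,
    reform_regime,
)
from cigtax.elasticity import TwoPartDemandModel
from cigtax.market import MarketState
from cigtax.reporting import RunConfig, run_pipeline
from cigtax.survey import generate_survey

RECOVERY_SEEDS = tuple(range(20))
RECOVERY_N = 50_000
GEN_PREVALENCE = -0.24
GEN_CONDITIONAL = -0.60


def make_market(cells, populations, floor=5.00):
    """Build a MarketState from {(state, pc): (smokers, price, cpd)},
    filling unmentioned PCs of each state with empty cells."""
    states = sorted({s for s, _ in cells})
    rows = []
    for s in states:
        for k in (1, 2, 3, 4):
            smokers, price, cpd = cells.get((s, k), (0.0, np.nan, 0.0))
            rows.append((s, k, smokers, price, cpd))
    table = pd.DataFrame(
        rows, columns=["state", "pc", "smokers", "mean_price", "mean_cpd"]
    ).set_index(["state", "pc"])
    return MarketState(table, dict(populations), floor)


@pytest.fixture(scope="session")
def regimes():
    return current_regime(), reform_regime()


@pytest.fixture(scope="session")
def recovery_study():
    """Per-seed elasticity estimates on data generated with uniform
    elasticities (prevalence -0.24, conditional -0.60), n = 50,000."""
    runs = []
    for seed in RECOVERY_SEEDS:
        cfg = default_config(
            seed=seed,
            n_respondents=RECOVERY_N,
            prevalence_elasticity=GEN_PREVALENCE,
            conditional_elasticity=GEN_CONDITIONAL,
        )
        res = TwoPartDemandModel(generate_survey(cfg)).fit()
        runs.append(res.table)
    return runs


@pytest.fixture(scope="session")
def default_run():
    """End-to-end run under the default study conditions (seed 0,
    n = 50,000, Table-1-seeded elasticities, calibration to 17.75 BRL Bi)."""
    return run_pipeline(
        RunConfig(seed=0, use_estimated_elasticities=False, log_level="WARNING")
    )


@pytest.fixture(scope="session")
def default_survey():
    cfg = default_config(seed=0, n_respondents=20_000)
    return cfg, generate_survey(cfg)
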