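"""Default study fixture: tax regimes, market structure and demand
parameters.

The statutory inputs that vary by state (the ICMS rates on tobacco) and
the effective federal excise under the IPI special rule are not public in
a directly usable per-pack form, so the default *current* regime is a flat
effective decomposition — a federal turnover contribution (PIS/COFINS) and
per-state ICMS as ad-valorem rates on the local retail price plus the IPI
as a specific amount — calibrated once so that the tax burden at the
baseline mean prices of the three legal price categories (5.38, 7.90 and
12.84 BRL) reproduces the observed 78.3/69.4/62.2 percent within one
percentage point. Fitting ``burden(p) = alpha + beta / p`` through those
three points gives ``alpha ~ 0.506`` and ``beta ~ 1.491`` BRL/pack.

The *reform* regime replaces PIS/COFINS with the CBS cigarette regime —
22% ad valorem on the highest national brand price plus 1.10 BRL/pack —
and leaves IPI and ICMS untouched.

Default demand elasticities are seeded from the estimated regional pattern
(poorer regions and cheaper categories more elastic); default per-state
smoker shares are constructed *from* the prevalence elasticity so that the
state-level price gradient the estimator exploits is exactly the
configured one (state-level heterogeneity is orthogonalised against log
price within each region).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .market import PCS, MarketState
from .scenarios import CostTable
from .states import STATE_POPULATION, STATE_REGION, region_of, states_in
from .survey import GeneratorConfig
from .tax import LOCAL, NATIONAL_MAX, TaxComponent, TaxRegime

#: observed aggregate tobacco tax collection, BRL per year (2019)
TARGET_REVENUE = 17.75e9

DEFAULT_PRICE_FLOOR = 5.00

# effective decomposition of the current-regime burden alpha + beta/p;
# the IPI special rule mixes ad-valorem and specific parts, so the flat
# effective split keeps both
IPI_SPECIFIC = 1.491          # BRL/pack, effective IPI specific part
IPI_AD_VALOREM = 0.083        # effective IPI ad-valorem part, on retail price
PIS_COFINS_RATE = 0.115       # federal, on local retail price
CBS_RATE = 0.22               # reform: on highest national brand price
CBS_SPECIFIC = 1.10           # BRL/pack

#: default ICMS rate on tobacco per state (effective, on retail price);
#: population-weighted mean ~ 0.308 so the combined local ad-valorem rate
#: matches the calibrated alpha
ICMS_RATES: dict[str, float] = {
    # North
    "AC": 0.32, "AP": 0.31, "AM": 0.30, "PA": 0.31, "RO": 0.32, "RR": 0.32, "TO": 0.31,
    # Northeast
    "AL": 0.32, "BA": 0.32, "CE": 0.33, "MA": 0.31, "PB": 0.33, "PE": 0.32,
    "PI": 0.32, "RN": 0.31, "SE": 0.31,
    # Southeast
    "ES": 0.30, "MG": 0.30, "RJ": 0.35, "SP": 0.30,
    # South
    "PR": 0.29, "RS": 0.30, "SC": 0.29,
    # Midwest
    "DF": 0.34, "GO": 0.32, "MT": 0.33, "MS": 0.34,
}


def current_regime() -> TaxRegime:
    """The pre-reform regime: PIS/COFINS + IPI + state-varying ICMS."""
    comps = [
        TaxComponent("PIS/COFINS", "ad_valorem", rate=PIS_COFINS_RATE, base=LOCAL),
        TaxComponent("IPI ad valorem", "ad_valorem", rate=IPI_AD_VALOREM, base=LOCAL),
        TaxComponent("IPI specific", "specific", amount=IPI_SPECIFIC),
        TaxComponent("ICMS", "ad_valorem", rate=0.31, base=LOCAL, level="state"),
    ]
    overrides = {s: {"ICMS": r} for s, r in ICMS_RATES.items()}
    return TaxRegime(comps, overrides)


def reform_regime() -> TaxRegime:
    """The post-reform regime: CBS replaces PIS/COFINS; IPI, ICMS unchanged."""
    comps = [
        TaxComponent("CBS ad valorem", "ad_valorem", rate=CBS_RATE, base=NATIONAL_MAX),
        TaxComponent("CBS specific", "specific", amount=CBS_SPECIFIC),
        TaxComponent("IPI ad valorem", "ad_valorem", rate=IPI_AD_VALOREM, base=LOCAL),
        TaxComponent("IPI specific", "specific", amount=IPI_SPECIFIC),
        TaxComponent("ICMS", "ad_valorem", rate=0.31, base=LOCAL, level="state"),
    ]
    overrides = {s: {"ICMS": r} for s, r in ICMS_RATES.items()}
    return TaxRegime(comps, overrides)


# -- regional demand parameters (estimated pattern: poorer regions and
#    cheaper categories more price sensitive) --------------------------------

PREVALENCE_ELASTICITY: dict[str, float] = {
    "Northeast": -0.26, "North": -0.24, "Southeast": -0.24,
    "South": -0.21, "Midwest": -0.23,
}

CONDITIONAL_ELASTICITY: dict[str, dict[int, float]] = {
    "Northeast": {1: -0.60, 2: -0.42, 3: -0.36, 4: -0.31},
    "North":     {1: -0.49, 2: -0.44, 3: -0.26, 4: -0.24},
    "Southeast": {1: -0.32, 2: -0.44, 3: -0.22, 4: -0.18},
    "South":     {1: -0.30, 2: -0.45, 3: -0.19, 4: -0.18},
    "Midwest":   {1: -0.46, 2: -0.44, 3: -0.19, 4: -0.24},
}

#: regional baseline smoking prevalence (share of residents), spanning the
#: observed 4-13% range across states
REGION_PREVALENCE: dict[str, float] = {
    "North": 0.075, "Northeast": 0.09, "Southeast": 0.10,
    "South": 0.12, "Midwest": 0.065,
}

# national mean pack price per PC (BRL), matching the baseline price table
PC_BASE_PRICE: dict[int, float] = {1: 3.20, 2: 5.42, 3: 7.90, 4: 12.84}

# log-price spread multipliers: state price level (l) and PC-specific (h)
PC_H_SPREAD: dict[int, float] = {1: 0.19, 2: 0.03, 3: 0.06, 4: 0.08}
L_SPREAD = 0.15
PC2_FLOOR_MEAN = 5.10  # cheapest admissible PC2 state mean (just above floor)


def _spread(n: int, width: float) -> np.ndarray:
    if n == 1:
        return np.zeros(1)
    return np.linspace(-width, width, n)


def _permuted(values: np.ndarray) -> np.ndarray:
    """Deterministic reorder (evens then odds) so the two state scores are
    not collinear within a region."""
    n = len(values)
    order = list(range(0, n, 2)) + list(range(1, n, 2))
    out = np.empty(n)
    out[order] = values
    return out


def state_scores() -> dict[str, tuple[float, float, float]]:
    """Per state: (price level l, PC price score h, market-split score h2)."""
    out = {}
    for region in sorted(set(STATE_REGION.values())):
        ss = states_in(region)
        n = len(ss)
        l = _spread(n, L_SPREAD)
        h = _permuted(_spread(n, 1.0))
        h2 = _permuted(_spread(n, 1.0))[::-1]
        for i, s in enumerate(ss):
            out[s] = (float(l[i]), float(h[i]), float(h2[i]))
    return out


def default_price_means() -> dict[str, dict[int, float]]:
    """State x PC mean pack prices: a common state price level times a
    PC-specific spread, with PC1 capped below the official floor and PC2
    floored just above it."""
    scores = state_scores()
    out: dict[str, dict[int, float]] = {}
    for s, (l, h, _) in scores.items():
        p1 = min(PC_BASE_PRICE[1] * math.exp(l + PC_H_SPREAD[1] * h), 4.60)
        p2 = max(PC_BASE_PRICE[2] * math.exp(0.5 * l + PC_H_SPREAD[2] * h), PC2_FLOOR_MEAN)
        p3 = PC_BASE_PRICE[3] * math.exp(0.8 * l + PC_H_SPREAD[3] * h)
        p4 = PC_BASE_PRICE[4] * math.exp(l + PC_H_SPREAD[4] * h)
        out[s] = {1: round(p1, 2), 2: round(p2, 2), 3: round(p3, 2), 4: round(p4, 2)}
    return out


#: pre-calibration PC1 share multiplier per region (border/poorer regions
#: carry more illicit trade) and legal-market split tilt
REGION_PC1_FACTOR = {
    "Northeast": 1.45, "North": 1.10, "Midwest": 1.35, "Southeast": 0.80, "South": 1.00,
}
REGION_LEGAL_SPLIT = {
    "Northeast": (0.36, 0.34, 0.30),
    "North": (0.33, 0.34, 0.33),
    "Midwest": (0.30, 0.34, 0.36),
    "Southeast": (0.27, 0.34, 0.39),
    "South": (0.25, 0.33, 0.42),
}
BASE_PC1_SHARE = 0.12


def default_pc_shares() -> dict[str, tuple[float, float, float, float]]:
    scores = state_scores()
    out = {}
    for s, (l, _, h2) in scores.items():
        r = region_of(s)
        s1 = BASE_PC1_SHARE * REGION_PC1_FACTOR[r] * math.exp(-0.6 * l + 0.35 * h2)
        s1 = min(max(s1, 0.03), 0.35)
        w2, w3, w4 = REGION_LEGAL_SPLIT[r]
        rest = 1.0 - s1
        out[s] = (s1, rest * w2, rest * w3, rest * w4)
    return out


def consistent_smoker_shares(
    price_means: dict[str, dict[int, float]],
    prevalence_elasticity: dict[str, float],
    region_prevalence: dict[str, float] | None = None,
    u_sd: float = 0.05,
    u_seed: int = 73291,
) -> dict[str, float]:
    """Per-state smoker shares embedding the configured prevalence
    elasticity in the state-level price gradient.

    ``share_s = Phi(Phi^{-1}(rho_r) + b_r (log P_s - mean_r log P) + u_s)``
    with ``b_r = elasticity * Phi(z)/phi(z)`` at the regional prevalence,
    ``P_s`` the state price index (mean of the four PC means) and ``u_s``
    state heterogeneity orthogonalised against log price within the region
    so it cannot bias the estimator's identifying variation.
    """
    rho = region_prevalence or REGION_PREVALENCE
    rng = np.random.default_rng(u_seed)
    u_raw = {s: rng.normal(0.0, u_sd) for s in sorted(price_means)}
    shares: dict[str, float] = {}
    by_region: dict[str, list[str]] = {}
    for s in sorted(price_means):
        by_region.setdefault(region_of(s), []).append(s)
    for r, ss in by_region.items():
        logp = np.array([
            math.log(sum(price_means[s][k] for k in PCS) / len(PCS)) for s in ss
        ])
        z0 = stats.norm.ppf(rho[r])
        b = prevalence_elasticity[r] * rho[r] / stats.norm.pdf(z0)
        u = np.array([u_raw[s] for s in ss])
        if len(ss) >= 2:
            X = np.column_stack([np.ones(len(ss)), logp - logp.mean()])
            u = u - X @ np.linalg.lstsq(X, u, rcond=None)[0]
        z = z0 + b * (logp - logp.mean()) + u
        for s, zs in zip(ss, z):
            shares[s] = float(stats.norm.cdf(zs))
    return shares


def _as_region_map(value, template: dict[str, float]) -> dict[str, float]:
    if isinstance(value, dict):
        return dict(value)
    return {r: float(value) for r in template}


def _as_region_pc_map(value, template) -> dict[str, dict[int, float]]:
    if isinstance(value, dict):
        return {r: dict(v) for r, v in value.items()}
    return {r: {k: float(value) for k in PCS} for r in template}


def default_config(
    seed: int = 0,
    n_respondents: int = 50_000,
    prevalence_elasticity=None,
    conditional_elasticity=None,
) -> GeneratorConfig:
    """The default generator configuration.

    ``prevalence_elasticity`` / ``conditional_elasticity`` accept a scalar
    (applied uniformly) or a full map; the smoker-share map is rebuilt so
    it stays consistent with the chosen prevalence elasticity.
    """
    prev = _as_region_map(
        PREVALENCE_ELASTICITY if prevalence_elasticity is None else prevalence_elasticity,
        PREVALENCE_ELASTICITY,
    )
    cond = _as_region_pc_map(
        CONDITIONAL_ELASTICITY if conditional_elasticity is None else conditional_elasticity,
        CONDITIONAL_ELASTICITY,
    )
    price_means = default_price_means()
    return GeneratorConfig(
        state_populations={s: float(p) for s, p in STATE_POPULATION.items()},
        smoker_share=consistent_smoker_shares(price_means, prev),
        pc_shares=default_pc_shares(),
        pc_price_means=price_means,
        true_prevalence_elasticity=prev,
        true_conditional_elasticity=cond,
        seed=seed,
        n_respondents=n_respondents,
        price_floor=DEFAULT_PRICE_FLOOR,
    )


# -- unit costs ---------------------------------------------------------------

#: assumed markup of the least profitable state at baseline, used to
#: back-solve the constant unit costs from observed net-of-tax prices.
#: Low and medium brands share essentially the same production cost (the
#: medium-price premium is branding, hence its much larger markup); premium
#: brands cost more to produce and distribute.
MIN_STATE_MARKUP = {2: 0.10, 4: 0.10}
PC3_COST_RATIO = 1.01  # medium-brand cost relative to low-brand cost


def default_costs(market: MarketState, regime: TaxRegime | None = None) -> CostTable:
    """Back-solve constant per-PC unit costs from the baseline market:
    the cheapest-state net-of-tax price defines cost times (1 + minimum
    markup) for PC2 and PC4; PC3 cost is tied to PC2's."""
    from .market import national_max_prices
    from .tax import assess

    regime = regime or current_regime()
    pmax = national_max_prices(market)
    net_min: dict[int, float] = {}
    for (state, pc), row in market.table.iterrows():
        if pc == 1 or row["smokers"] <= 0 or not np.isfinite(row["mean_price"]):
            continue
        a = assess(row["mean_price"], max(pmax[pc], row["mean_price"]), state, regime)
        net = row["mean_price"] - a.total_tax
        net_min[pc] = min(net_min.get(pc, np.inf), net)
    c2 = net_min[2] / (1.0 + MIN_STATE_MARKUP[2])
    c3 = min(c2 * PC3_COST_RATIO, net_min[3])
    c4 = net_min[4] / (1.0 + MIN_STATE_MARKUP[4])
    return CostTable({2: round(c2, 4), 3: round(c3, 4), 4: round(c4, 4)})
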