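"""Synthetic smoker-survey generator.

Emulates the statistical structure of a telephone risk-factor survey
(Vigitel-like): respondents sampled roughly equally across the 27 federative
units, a binary smoking status, and — for smokers — the pack price of the
last purchase, the brand price category and daily cigarette consumption.

The generating process mirrors the identification strategy of the two-part
demand model estimated downstream:

* smoking status follows a latent-index probit whose state-level intercept
  is ``Phi^{-1}(smoker_share_s)``; the configured *prevalence* elasticity is
  encoded in how the share map varies with the state price index (see
  :mod:`cigtax.defaults`, which constructs consistent share maps);
* conditional on smoking, ``log(cigarettes/day)`` is linear in the log of
  the state x price-category mean price with slope equal to the configured
  *conditional* elasticity, plus covariate effects and Gaussian noise.

Price variation is placed at the state level — records within a (state, PC)
cell share the configured cell mean plus small noise — because estimation
substitutes state-average prices for the individually reported ones.
Identification therefore requires cross-state price variation, and configs
without it are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .market import LEGAL_PCS, PCS, MarketState
from .states import region_of

RECORD_COLUMNS = [
    "state", "region", "smokes", "cigarettes_per_day", "price_paid",
    "price_category", "age", "female", "income", "education",
    "years_smoking", "survey_weight",
]


@dataclass(frozen=True)
class CovariateParams:
    """Distributions and effect sizes of the individual-level covariates.

    Effects on the smoking latent index (``z_*``) and on log consumption
    (``cpd_*``) are per standardised unit of the covariate; they are kept
    modest so the state-level price gradient remains the dominant source of
    systematic variation.
    """

    age_mean: float = 45.0
    age_sd: float = 13.0
    female_share: float = 0.47
    income_log_mean: float = math.log(1800.0)
    income_log_sd: float = 0.60
    education_probs: tuple[float, ...] = (0.18, 0.30, 0.28, 0.16, 0.08)
    start_age_mean: float = 17.0
    start_age_sd: float = 4.0
    z_age: float = 0.05
    z_female: float = -0.10
    z_income: float = -0.06
    z_education: float = -0.08
    cpd_age: float = 0.05
    cpd_years: float = 0.06
    cpd_female: float = -0.08
    cpd_education: float = -0.03


@dataclass
class GeneratorConfig:
    """Full parameterisation of the synthetic survey.

    ``smoker_share`` is the target smoking prevalence per state at that
    state's own prices; ``pc_price_means`` gives the mean pack price per
    (state, price category) and ``pc_shares`` the market split of smokers
    over the four categories. The ``true_*`` elasticities are the
    generating demand parameters the estimation stage should recover
    (all non-positive).
    """

    state_populations: dict[str, float]
    smoker_share: dict[str, float]
    pc_shares: dict[str, tuple[float, float, float, float]]
    pc_price_means: dict[str, dict[int, float]]
    true_prevalence_elasticity: dict[str, float]
    true_conditional_elasticity: dict[str, dict[int, float]]
    seed: int = 0
    n_respondents: int = 50_000
    price_noise_sd: float = 0.12
    price_floor: float = 5.00
    intensity_log_median: float = math.log(12.0)
    intensity_log_sd: float = 0.35
    covariates: CovariateParams = field(default_factory=CovariateParams)

    @property
    def states(self) -> list[str]:
        return sorted(self.state_populations)

    def state_price_index(self, state: str) -> float:
        """Unweighted mean of the four PC mean prices — the state price
        index the prevalence margin is keyed to."""
        prices = self.pc_price_means[state]
        return sum(prices[k] for k in PCS) / len(PCS)

    def validate(self) -> None:
        states = self.states
        if not states:
            raise ValueError("no states configured")
        for s in states:
            if not 0 <= self.smoker_share.get(s, -1) <= 1:
                raise ValueError(f"smoker_share for {s} missing or outside [0, 1]")
            sh = self.pc_shares[s]
            if len(sh) != 4 or abs(sum(sh) - 1.0) > 1e-9 or min(sh) < 0:
                raise ValueError(f"pc_shares for {s} must be a 4-vector summing to 1")
            prices = self.pc_price_means[s]
            if set(prices) != set(PCS):
                raise ValueError(f"pc_price_means for {s} must cover PCs 1-4")
            if prices[1] >= self.price_floor:
                raise ValueError(
                    f"PC1 mean price in {s} must lie below the official floor"
                )
            for k in LEGAL_PCS:
                if prices[k] < self.price_floor:
                    raise ValueError(
                        f"PC{k} mean price in {s} must lie at or above the floor"
                    )
        for r, e in self.true_prevalence_elasticity.items():
            if e > 0:
                raise ValueError(f"prevalence elasticity for {r} must be <= 0")
        for r, by_pc in self.true_conditional_elasticity.items():
            for k, e in by_pc.items():
                if e > 0:
                    raise ValueError(f"conditional elasticity ({r}, PC{k}) must be <= 0")
        if len(states) > 1:
            idx = np.array([self.state_price_index(s) for s in states])
            if float(np.var(idx)) <= 1e-12:
                raise ValueError(
                    "zero cross-state price variance: elasticities are "
                    "unidentifiable from state-average prices"
                )


def _truncnorm(rng, mean, sd, low, high):
    a = (low - mean) / sd
    b = (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)


def generate_survey(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a synthetic survey as one row per respondent.

    Deterministic for a given ``(config, seed)``; ``seed`` overrides
    ``config.seed`` when given. Non-smokers carry missing values for
    consumption, price and price category.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cov = config.covariates
    states = config.states
    n_states = len(states)

    base, extra = divmod(config.n_respondents, n_states)
    n_by_state = {s: base + (1 if i < extra else 0) for i, s in enumerate(states)}
    state = np.repeat(states, [n_by_state[s] for s in states])
    n = len(state)
    region = np.array([region_of(s) for s in state])

    # covariates
    age = np.clip(rng.normal(cov.age_mean, cov.age_sd, n), 18, 90)
    female = rng.random(n) < cov.female_share
    income = rng.lognormal(cov.income_log_mean, cov.income_log_sd, n)
    education = rng.choice(
        np.arange(1, len(cov.education_probs) + 1), size=n, p=cov.education_probs
    )

    # smoking status: latent-index probit anchored at the state share
    z = (
        np.array([stats.norm.ppf(config.smoker_share[s]) for s in state])
        + cov.z_age * (age - cov.age_mean) / 15.0
        + cov.z_female * (female - cov.female_share)
        + cov.z_income * (np.log(income) - cov.income_log_mean) / cov.income_log_sd
        + cov.z_education * (education - 3.0) / 1.2
    )
    smokes = rng.random(n) < stats.norm.cdf(z)
    idx = np.flatnonzero(smokes)
    m = len(idx)

    # price category: categorical draw per smoker from the state's split
    cum = {s: np.cumsum(config.pc_shares[s]) for s in states}
    u = rng.random(m)
    pc = np.empty(m, dtype=int)
    for j, i in enumerate(idx):
        pc[j] = int(np.searchsorted(cum[state[i]], u[j], side="right")) + 1
    pc = np.minimum(pc, 4)

    # last-purchase price: truncated normal around the (state, PC) mean,
    # respecting the official floor partition on both sides
    price = np.empty(m)
    for j, i in enumerate(idx):
        mu = config.pc_price_means[state[i]][pc[j]]
        if pc[j] == 1:
            lo, hi = 0.50, config.price_floor - 0.01
        else:
            lo, hi = config.price_floor, np.inf
        price[j] = _truncnorm(rng, mu, config.price_noise_sd, lo, hi)
    price = np.round(price, 2)
    # cent rounding must not cross the floor partition
    price[pc == 1] = np.minimum(price[pc == 1], config.price_floor - 0.01)
    price[pc != 1] = np.maximum(price[pc != 1], config.price_floor)

    # smoking history
    start_age = np.clip(
        rng.normal(cov.start_age_mean, cov.start_age_sd, m), 10.0, 40.0
    )
    years = np.clip(age[idx] - start_age, 1.0, None)

    # intensity: log-linear in the log cell price with the configured slope,
    # centred at the regional mean log price of the same category
    logp_ref: dict[tuple[str, int], float] = {}
    by_region: dict[str, list[str]] = {}
    for s in states:
        by_region.setdefault(region_of(s), []).append(s)
    for r, ss in by_region.items():
        for k in PCS:
            logp_ref[(r, k)] = float(
                np.mean([math.log(config.pc_price_means[s][k]) for s in ss])
            )
    slope = np.array(
        [config.true_conditional_elasticity[region[i]][k] for i, k in zip(idx, pc)]
    )
    logp_true = np.array(
        [math.log(config.pc_price_means[state[i]][k]) for i, k in zip(idx, pc)]
    )
    centred = logp_true - np.array(
        [logp_ref[(region[i], k)] for i, k in zip(idx, pc)]
    )
    log_cpd = (
        config.intensity_log_median
        + slope * centred
        + cov.cpd_age * (age[idx] - cov.age_mean) / 15.0
        + cov.cpd_years * (years - 20.0) / 15.0
        + cov.cpd_female * (female[idx] - cov.female_share)
        + cov.cpd_education * (education[idx] - 3.0) / 1.2
        + rng.normal(0.0, config.intensity_log_sd, m)
    )
    cpd = np.clip(np.round(np.exp(log_cpd)), 1, 60)

    out = pd.DataFrame(
        {
            "state": state,
            "region": region,
            "smokes": smokes,
            "cigarettes_per_day": pd.array(np.full(n, np.nan), dtype="Float64"),
            "price_paid": np.full(n, np.nan),
            "price_category": pd.array(np.full(n, np.nan), dtype="Float64"),
            "age": np.round(age, 1),
            "female": female,
            "income": np.round(income, 2),
            "education": education,
            "years_smoking": np.zeros(n),
            "survey_weight": np.ones(n),
        }
    )
    out.loc[idx, "cigarettes_per_day"] = cpd
    out.loc[idx, "price_paid"] = price
    out.loc[idx, "price_category"] = pc.astype(float)
    out.loc[idx, "years_smoking"] = np.round(years, 1)
    return out[RECORD_COLUMNS]


def aggregate_market(
    records: pd.DataFrame,
    populations: dict[str, float],
    price_floor: float = 5.00,
) -> MarketState:
    """Aggregate respondent records into the (state, PC) market grid.

    Smoker counts are expanded to the state population with the survey
    weights: a cell's smokers are ``population_s`` times the cell's weight
    share among all of the state's respondents. Cell prices and intensities
    are weight-averaged. Raises if any state in ``populations`` has no
    respondents.
    """
    missing = [s for s in sorted(populations) if s not in set(records["state"])]
    if missing:
        raise ValueError(f"no survey records for state(s): {', '.join(missing)}")

    rows = []
    for s in sorted(populations):
        sub = records[records["state"] == s]
        w_all = float(sub["survey_weight"].sum())
        smk = sub[sub["smokes"].astype(bool)]
        for k in PCS:
            cell = smk[smk["price_category"] == k]
            w = float(cell["survey_weight"].sum())
            count = populations[s] * w / w_all if w_all > 0 else 0.0
            if w > 0:
                price = float(np.average(cell["price_paid"], weights=cell["survey_weight"]))
                cpd = float(
                    np.average(cell["cigarettes_per_day"], weights=cell["survey_weight"])
                )
            else:
                price, cpd = np.nan, 0.0
            rows.append((s, k, count, price, cpd))
    table = pd.DataFrame(
        rows, columns=["state", "pc", "smokers", "mean_price", "mean_cpd"]
    ).set_index(["state", "pc"])
    ms = MarketState(table, dict(populations), price_floor)
    ms.validate()
    return ms
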