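# Methods

This note documents the model implemented by `cigtax`, the assumptions
behind it, the default parameter choices and their rationale, and what the
synthetic data can and cannot establish.

## 1. Tax engine

A regime is a list of components, each ad valorem (rate on a declared
base) or specific (BRL per 20-cigarette pack; a pack is 20 cigarettes
throughout). Two bases exist: the local retail price and the highest
national price of the brand — the base that defines the CBS cigarette
regime (22% + 1.10 BRL/pack). State-varying rates (ICMS) enter as
per-state overrides. The ICMS is legally computed "por dentro"
(tax-inclusive); we represent it as an effective rate on the retail
price, which is the only object the burden accounting needs.

Under uniform national pricing the per-pack tax in state *s* is
`α_s p + β_s`, so the inverse problems are closed-form:

* implicit price floor at unit cost *c* (smallest price with non-negative
  profit and burden < 100%): `p* = (β_s + c)/(1 − α_s)`, rounded **up** to
  the cent — rounding down would violate one of the two constraints;
* price restoring markup *m*: `p = ((1 + m)c + β_s)/(1 − α_s)`, returned
  exactly so that `markup_of` inverts it to 1e-9; the scenario engine
  rounds final prices up to the cent.

Both are verified against an exhaustive 0.01-BRL grid search in the tests.

### Default regimes

The statutory per-state ICMS rates on tobacco and the effective IPI
special rule are not available here in per-pack form, so the default
current regime is an *effective* decomposition calibrated to reproduce
observed burdens. Writing the burden at price *p* as `α + β/p` and fitting
through the three observed (price, burden) pairs of the legal market
segments — (5.38, 78.3%), (7.90, 69.4%), (12.84, 62.2%) — gives
`α ≈ 0.506` and `β ≈ 1.491` BRL/pack. The default split is:

| component | kind | default |
|---|---|---|
| ICMS | ad valorem, state-level | 0.29–0.35 by state, weighted mean ≈ 0.308 |
| PIS/COFINS | ad valorem, federal | 0.115 |
| IPI (ad-valorem part) | ad valorem, federal | 0.083 |
| IPI (specific part) | specific | 1.491 BRL/pack |

The split of the non-ICMS ad-valorem mass between PIS/COFINS and IPI is
identified from the *reform-side* arithmetic: the ratio of tax to price
differences across the markup-preserving scenarios implies a combined
post-reform ad-valorem rate near 0.61, and since the reform removes only
PIS/COFINS and adds the 0.22 CBS, the current PIS/COFINS effective rate
must be near 0.115, leaving 0.083 with the IPI. With this split the
baseline burdens match the observed ones within half a percentage point
and the qualitative reform pattern (revenue ordering I > II > III > 0)
emerges. The reform regime swaps PIS/COFINS for the CBS (22% on the
national maximum + 1.10 specific) and leaves IPI and ICMS untouched.

## 2. Synthetic survey

The generator emulates a Vigitel-like telephone survey. Respondents are
allocated approximately equally across the 27 units (the survey samples a
fixed number of interviews per state capital); population scaling happens
at aggregation through survey weights (defaulting to 1), where a cell's
smoker count is the state population times the cell's weight share.

**Prices.** Price variation is placed at the state level: a record's price
is its (state, PC) configured mean plus truncated-normal noise
(sd 0.12 BRL), truncated so the floor partition is exact — PC1 strictly
below the official 5.00 BRL floor, legal categories at or above it. State
means combine a common state price level (±15%) with PC-specific spreads;
the illicit category is given the widest cross-state dispersion (illicit
prices track smuggling routes), the low-price category the narrowest
(it is compressed against the price floor from below). Cross-state
dispersion of this size mirrors the motivating fact of the analysis —
large inter-state price gaps and cross-border shopping. Configs with zero
cross-state price variance are rejected: the estimator's identifying
variation would vanish.

**Smoking status** follows a latent-index probit with intercept
`Φ⁻¹(smoker_share_s)` plus small covariate effects (age, gender, income,
education). The default share map is *constructed from* the prevalence
elasticity: `share_s = Φ(Φ⁻¹(ρ_r) + b_r (log P_s − mean) + u_s)` where
`P_s` is the state price index (unweighted mean of the four PC means),
`b_r = ε_prev,r · ρ_r / φ(Φ⁻¹(ρ_r))` converts the elasticity into a probit
slope at the regional prevalence ρ_r, and the state heterogeneity `u_s`
is orthogonalised against log price within each region. Without this
construction a fixed share map would sever the price–prevalence link and
no estimator could recover the generating elasticity from state-level
price variation; without the orthogonalisation, accidental correlation
between the (fixed) heterogeneity and the (fixed) price design would bias
it. Regional prevalences (6.5–12%) plus heterogeneity keep all state
shares inside the observed 4–13% band.

**Intensity.** For smokers, `log(cigarettes/day)` is linear in the log
(state, PC) mean price with the configured conditional elasticity, centred
at the regional mean log price of the category, plus covariate effects and
N(0, 0.35) noise; the level is anchored at a median of 12 cigarettes/day
and the count is rounded and truncated to [1, 60]. The distributional
choices (log-normal intensity, truncation bounds, noise scales) are not
dictated by any data source and are package defaults chosen for
plausibility.

**What the generator does not emulate:** item non-response, recall error
in reported prices, brand-level heterogeneity within a category,
ex-smokers (years smoked is zero for all non-smokers), or sampling-frame
effects of telephone surveys. Passing recovery tests therefore show that
the estimators are consistent for the data-generating process they assume,
not that the real surveys satisfy those assumptions.

## 3. Elasticity estimation

The prevalence probit regresses smoking status on the log state price
index interacted with region, plus age, gender, education and log income.
The elasticity per region is the sample-average marginal effect of log
price divided by the region's prevalence (average effects rather than
effects-at-means: they answer the population question the simulation
asks). Years smoked is *excluded* from this margin: in the synthetic data
it is positive exactly for smokers, so including it would produce perfect
separation; it remains a control in the conditional margin.

The conditional margin is one OLS regression of log consumption on the log
cell price with a full set of (region × PC) intercepts and slopes plus the
same controls and years smoked, with HC1 robust standard errors. Both
margins substitute state-average prices for reported prices — the
endogeneity defence for brand switching — implemented as the unweighted
mean of the four cell means for the prevalence index (robust to the
sampling noise of the cell composition) and the (state, PC) cell mean for
the conditional margin. The total elasticity is the elementwise sum of the
margins, an identity asserted for every estimated table.

Monte-Carlo recovery under the default conditions (20 seeds, n = 50,000
respondents, generating elasticities −0.24 prevalence / −0.60
conditional) is part of the acceptance suite, with a ±0.05 tolerance on
the mean estimate; a null-effect configuration and a 5k-vs-50k consistency
check guard the estimator from the other side.

## 4. Illicit-market calibration

Telephone surveys understate the illicit segment, so simulated baseline
revenue under current rules overshoots the observed collection
(17.75 BRL Bi/year). The calibrator moves one proportional share δ of
every legal cell's smokers into PC1 — the same factor in all states and
categories, which by construction can never drive a legal share negative —
and solves `revenue(δ) = target` by bisection to relative tolerance 1e-6.
Multiplicative shrinkage was chosen over subtracting equal percentage
points precisely because of the non-negativity requirement; with cell
prices fixed it also makes revenue exactly linear in δ, which the grid
oracle test exploits. A single national δ (rather than 27 state-level
ones) is used because one aggregate revenue figure identifies only one
parameter. Under the default fixture the calibration lands at a mean shift
of roughly 31 p.p. of smokers into the illicit segment, with calibrated
PC1 shares of 40–56% across states. Once calibrated, the illicit segment
is frozen: no cross-price substitution into the illicit market is
modelled, consistent with holding its consumption constant in every
scenario.

## 5. Scenarios and demand response

All scenarios price uniformly across states within a category (the
national-maximum base removes any incentive to undercut) and take the
maximum over states of the relevant state-level inversion, so the price is
feasible in the least favourable (highest-ICMS) state:

* **I** — `max_s floor_price(c_k, s)`: the implicit floor;
* **II** — `max_s price_from_markup(m̄_k, c_k, s)` with m̄ the
  smoker-weighted average baseline markup, floored at the scenario I
  price (a safeguard; it does not bind under the default fixture);
* **III** — the same with `max_s m(s,k)`.

Baseline markups come from `m(s,k) = (p − tax − c_k)/c_k` on the
calibrated market under the current regime. Unit costs are constant across
states (state logistics differences are absorbed into the markup, which is
the object the scenarios manipulate) and are back-solved from the baseline
market: the cheapest-state net-of-tax price of PC2 and PC4 is assigned a
10% minimum markup, and the PC3 cost is set 1% above PC2's. That last
choice encodes a reading of the market the simulation needs to be
explicit about: low- and medium-price brands are essentially the same
product at different brand positioning, so their production costs nearly
coincide and the medium-price premium is markup. It is what makes the
scenario-I floors of PC2 and PC3 essentially collapse to one price, as
the observed pattern requires; costs remain strictly increasing in PC.

The demand response applies the **total** elasticity linearly at the pack
level: with relative price change d per (state, PC) cell — measured
against that state's own baseline price — packs scale by exactly
`1 + ε_total d`, the smoker count carries the extensive margin
`1 + ε_prev d`, and intensity the residual ratio (to first order
`1 + ε_cond d`). Applying the two margins independently would introduce a
spurious `ε_prev ε_cond d²` cross term in consumption; the observed
scenario arithmetic is consistent with the pure linear form. Factors are
clamped at zero with a warning once `|ε d| ≥ 1` — the linear rule is an
extrapolation and large price jumps (they reach +120% for cheap
categories in Scenario III) can exceed its range. Smokers do not switch
categories; aggregate per-PC changes are consumption-weighted.

Revenue aggregates per (state, PC): annual packs (smokers × cigarettes/day
× 365/20) times the per-pack tax at the cell price, with PC1 contributing
nothing. The decomposition identities (state sums = PC sums = total) are
asserted to 1e-6 relative.

## 6. Problem sizes and numerics

Defaults: 50,000 respondents (≈ 1,850 per state, matching the scale of a
national telephone survey wave), 20 Monte-Carlo seeds for recovery
studies, bisection tolerance 1e-6 relative, cent rounding only at final
prices, monetary outputs to 0.01 BRL and percentages to 0.1 p.p. in
printed tables. Degenerate inputs are handled explicitly: empty regimes
(floor = cost), zero smoker shares (all-non-smoker surveys), empty market
cells (zero revenue, excluded from markups), a zero revenue target (full
shift with warning), and combined ad-valorem rates ≥ 1 (infeasibility
errors).

## 7. Known limitations

Partial equilibrium with a single period: no dynamics, no second-order
price adjustment, no brand-level pricing below the category, no
cross-price substitution between legal and illicit segments, and no
income-level incidence analysis. The default regime decomposition is an
effective calibration, not the statute; users with access to the actual
per-state ICMS and IPI rules should supply them as a YAML regime, which
replaces the defaults everywhere.
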