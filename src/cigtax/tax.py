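"""Cigarette excise engine.

A tax regime is a list of components, each either *ad valorem* (a rate on a
declared price base) or *specific* (a fixed BRL amount per 20-cigarette
pack). Two bases exist:

``local_retail_price``
    the pack price actually charged in the assessed state (the base of the
    current PIS/COFINS and of the state ICMS);
``highest_national_brand_price``
    the highest retail price of the brand across all states — the novel
    base of the proposed CBS, which makes the tax bill independent of the
    local price.

For a state ``s`` write ``alpha_s`` for the combined effective ad-valorem
rate and ``beta_s`` for the combined specific amount. Under uniform
national pricing (local price == national maximum == p) the per-pack tax is
``alpha_s * p + beta_s``, which makes the inverse problems closed-form:

* the implicit price floor given a unit cost ``c`` (smallest price with
  non-negative profit and burden < 100%) is ``(beta_s + c) / (1 - alpha_s)``;
* the price attaining a markup ``m`` over cost is
  ``((1 + m) * c + beta_s) / (1 - alpha_s)``.

Floor prices are rounded *up* to the cent: rounding down would leave the
seller below cost or above a 100% burden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import yaml

LOCAL = "local_retail_price"
NATIONAL_MAX = "highest_national_brand_price"

_BASES = (LOCAL, NATIONAL_MAX)
_KINDS = ("ad_valorem", "specific")


class InfeasibleRegimeError(ValueError):
    """Combined ad-valorem rate >= 1: no finite price covers the tax."""


@dataclass(frozen=True)
class TaxComponent:
    """One excise component.

    Parameters
    ----------
    name : str
        Label (e.g. ``"ICMS"``, ``"CBS"``).
    kind : {"ad_valorem", "specific"}
    rate : float, optional
        Fraction of the base in [0, 1); required for ad-valorem components.
    amount : float, optional
        BRL per pack; required for specific components.
    base : {"local_retail_price", "highest_national_brand_price"}
        Price base of an ad-valorem component (ignored for specific ones).
    level : {"federal", "state"}
    """

    name: str
    kind: str
    rate: float | None = None
    amount: float | None = None
    base: str = LOCAL
    level: str = "federal"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown component kind: {self.kind!r}")
        if self.base not in _BASES:
            raise ValueError(f"unknown tax base: {self.base!r}")
        if self.kind == "ad_valorem":
            if self.rate is None or not (0 <= self.rate < 1):
                raise ValueError(
                    f"ad-valorem component {self.name!r} needs a rate in [0, 1)"
                )
        else:
            if self.amount is None or self.amount < 0:
                raise ValueError(
                    f"specific component {self.name!r} needs a non-negative amount"
                )


@dataclass(frozen=True)
class TaxRegime:
    """A set of components plus optional per-state rate/amount overrides.

    ``state_overrides`` maps a state code to ``{component name: value}``
    where the value replaces the component's ``rate`` (ad valorem) or
    ``amount`` (specific) in that state — how the state-level ICMS varies
    across the federation.
    """

    components: tuple[TaxComponent, ...]
    state_overrides: dict[str, dict[str, float]] = field(default_factory=dict)

    def __init__(self, components, state_overrides=None):
        object.__setattr__(self, "components", tuple(components))
        object.__setattr__(self, "state_overrides", dict(state_overrides or {}))
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError("component names must be unique")
        for state, over in self.state_overrides.items():
            unknown = set(over) - set(names)
            if unknown:
                raise ValueError(
                    f"override for {state} names unknown components: {sorted(unknown)}"
                )

    # -- effective parameters -------------------------------------------------

    def _value(self, comp: TaxComponent, state: str | None) -> float:
        over = self.state_overrides.get(state or "", {})
        if comp.name in over:
            return float(over[comp.name])
        return float(comp.rate if comp.kind == "ad_valorem" else comp.amount)

    def effective(self, state: str | None = None) -> tuple[float, float, float]:
        """Return ``(alpha_local, alpha_national, beta)`` for a state."""
        a_loc = a_nat = beta = 0.0
        for comp in self.components:
            v = self._value(comp, state)
            if comp.kind == "specific":
                beta += v
            elif comp.base == LOCAL:
                a_loc += v
            else:
                a_nat += v
        return a_loc, a_nat, beta

    def alpha(self, state: str | None = None) -> float:
        """Combined ad-valorem rate under uniform national pricing."""
        a_loc, a_nat, _ = self.effective(state)
        return a_loc + a_nat

    def beta(self, state: str | None = None) -> float:
        return self.effective(state)[2]

    def validate_feasible(self, states) -> None:
        """Raise if any state's local ad-valorem rates sum to >= 1."""
        for s in states:
            a_loc, _, _ = self.effective(s)
            if a_loc >= 1:
                raise InfeasibleRegimeError(
                    f"state {s}: combined local ad-valorem rate {a_loc:.3f} >= 1"
                )

    # -- serialisation --------------------------------------------------------

    def to_dict(self) -> dict:
        comps = []
        for c in self.components:
            d = {"name": c.name, "kind": c.kind, "level": c.level}
            if c.kind == "ad_valorem":
                d["rate"] = c.rate
                d["base"] = c.base
            else:
                d["amount"] = c.amount
            comps.append(d)
        return {"components": comps, "state_overrides": self.state_overrides}

    @classmethod
    def from_dict(cls, d: dict) -> "TaxRegime":
        comps = [TaxComponent(**c) for c in d.get("components", [])]
        return cls(comps, d.get("state_overrides") or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TaxRegime":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class TaxAssessment:
    """Per-pack tax bill of one price point in one state."""

    price_local: float
    price_national_max: float
    by_component: dict[str, float]
    total_tax: float
    burden: float


def assess(
    price_local: float,
    price_national_max: float,
    state: str | None,
    regime: TaxRegime,
) -> TaxAssessment:
    """Assess the per-pack tax at a local price given the brand's national
    maximum price.

    The burden is measured against the *local* retail price, so under a
    national-maximum base a seller undercutting the top price carries a
    strictly larger burden for the same tax bill.
    """
    if price_local <= 0:
        raise ValueError("price_local must be positive")
    if price_national_max < price_local - 1e-12:
        raise ValueError(
            "price_national_max cannot be below the local price "
            f"({price_national_max} < {price_local})"
        )
    by_comp: dict[str, float] = {}
    for comp in regime.components:
        v = regime._value(comp, state)
        if comp.kind == "specific":
            amt = v
        elif comp.base == LOCAL:
            amt = v * price_local
        else:
            amt = v * price_national_max
        by_comp[comp.name] = amt
    total = float(sum(by_comp.values()))
    return TaxAssessment(
        price_local=float(price_local),
        price_national_max=float(price_national_max),
        by_component=by_comp,
        total_tax=total,
        burden=total / price_local,
    )


def _check_alpha(alpha: float, state) -> None:
    if alpha >= 1:
        raise InfeasibleRegimeError(
            f"combined ad-valorem rate {alpha:.3f} >= 1 in state {state}: "
            "no feasible price exists"
        )


def round_up_cent(price: float) -> float:
    """Round a BRL price up to the next cent (tolerating float fuzz)."""
    return math.ceil(price * 100 - 1e-9) / 100


def floor_price(
    unit_cost: float, state: str | None, regime: TaxRegime, *, rounded: bool = True
) -> float:
    """Smallest uniform national price with non-negative profit and burden
    below 100%: ``p* = (beta_s + c) / (1 - alpha_s)``, rounded up to the
    cent by default.
    """
    if unit_cost < 0:
        raise ValueError("unit_cost must be non-negative")
    alpha = regime.alpha(state)
    _check_alpha(alpha, state)
    p = (regime.beta(state) + unit_cost) / (1.0 - alpha)
    return round_up_cent(p) if rounded else p


def price_from_markup(
    markup: float,
    unit_cost: float,
    state: str | None,
    regime: TaxRegime,
    *,
    rounded: bool = False,
) -> float:
    """Uniform national price at which profit equals ``markup * unit_cost``:
    ``p = ((1 + m) c + beta_s) / (1 - alpha_s)``.

    Exact by default so that :func:`markup_of` inverts it; pass
    ``rounded=True`` for a cent-grid price (rounded up, preserving the
    markup as a lower bound).
    """
    if markup < 0:
        raise ValueError("markup must be non-negative")
    if unit_cost < 0:
        raise ValueError("unit_cost must be non-negative")
    alpha = regime.alpha(state)
    _check_alpha(alpha, state)
    p = ((1.0 + markup) * unit_cost + regime.beta(state)) / (1.0 - alpha)
    return round_up_cent(p) if rounded else p


def markup_of(
    price: float,
    unit_cost: float,
    state: str | None,
    regime: TaxRegime,
    price_national_max: float | None = None,
) -> float:
    """Markup over unit cost net of all taxes at a given price.

    ``price_national_max`` defaults to ``price`` (uniform pricing); pass the
    brand's national maximum explicitly when assessing a baseline regime
    with dispersed state prices.
    """
    if unit_cost <= 0:
        raise ValueError("markup undefined for zero or negative unit cost")
    pmax = price if price_national_max is None else price_national_max
    a = assess(price, pmax, state, regime)
    return (price - a.total_tax - unit_cost) / unit_cost
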