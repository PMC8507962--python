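"""Excise engine: assessment arithmetic, inverse problems, oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cigtax.tax import (
    LOCAL,
    NATIONAL_MAX,
    InfeasibleRegimeError,
    TaxComponent,
    TaxRegime,
    assess,
    floor_price,
    markup_of,
    price_from_markup,
    round_up_cent,
)


def cbs_regime():
    return TaxRegime([
        TaxComponent("CBS ad valorem", "ad_valorem", rate=0.22, base=NATIONAL_MAX),
        TaxComponent("CBS specific", "specific", amount=1.10),
    ])


def flat_regime(alpha, beta):
    comps = []
    if alpha:
        comps.append(TaxComponent("av", "ad_valorem", rate=alpha, base=LOCAL))
    if beta:
        comps.append(TaxComponent("sp", "specific", amount=beta))
    return TaxRegime(comps)


class TestAssess:
    def test_national_max_base_gives_same_tax_at_every_local_price(self):
        # brand sold at 10.00 / 12.50 / 14.00 across states: the tax is set
        # by the 14.00 maximum everywhere
        regime = cbs_regime()
        for local in (10.00, 12.50, 14.00):
            a = assess(local, 14.00, None, regime)
            assert a.total_tax == pytest.approx(14.00 * 0.22 + 1.10, abs=1e-12)
            assert a.total_tax == pytest.approx(4.18)

    def test_empty_regime(self):
        a = assess(7.50, 7.50, None, TaxRegime([]))
        assert a.total_tax == 0.0 and a.burden == 0.0

    def test_burden_larger_when_undercutting_national_max(self):
        regime = cbs_regime()
        lo, hi = assess(10.00, 14.00, None, regime), assess(14.00, 14.00, None, regime)
        assert lo.total_tax == hi.total_tax == pytest.approx(4.18)
        assert lo.burden == pytest.approx(0.418)
        assert hi.burden == pytest.approx(4.18 / 14.00, abs=1e-9)
        assert lo.burden > hi.burden

    def test_national_max_below_local_price_rejected(self):
        with pytest.raises(ValueError, match="national"):
            assess(10.0, 9.0, None, cbs_regime())

    def test_additive_over_components(self):
        r1 = flat_regime(0.2, 0.0)
        r2 = flat_regime(0.0, 1.5)
        both = flat_regime(0.2, 1.5)
        p = 8.00
        assert assess(p, p, None, both).total_tax == pytest.approx(
            assess(p, p, None, r1).total_tax + assess(p, p, None, r2).total_tax
        )

    @given(st.floats(1.0, 30.0), st.floats(1.0, 30.0))
    @settings(max_examples=50, deadline=None)
    def test_burden_decreasing_in_local_price(self, p1, p2):
        regime = cbs_regime()
        pmax = 30.0
        b1 = assess(p1, pmax, None, regime).burden
        b2 = assess(p2, pmax, None, regime).burden
        if p1 < p2:
            assert b1 > b2
        elif p1 > p2:
            assert b1 < b2


def grid_floor(alpha, beta, cost, upper=None):
    """Brute-force 0.01-BRL grid search for the smallest feasible price."""
    if upper is None:
        upper = (beta + cost) / (1 - alpha) * 1.5 + 1.0
    grid = np.round(np.arange(1, int(math.ceil(upper * 100)) + 1) * 0.01, 2)
    net = grid * (1 - alpha) - beta
    feasible = (net >= cost - 1e-9) & (alpha * grid + beta < grid)
    return float(grid[feasible][0])


class TestFloorPrice:
    def test_cbs_only_zero_cost(self):
        # (0 + 1.10) / 0.78 = 1.4103 -> 1.42 after rounding up to the cent
        assert floor_price(0.0, None, cbs_regime()) == pytest.approx(1.42)
        assert floor_price(0.0, None, cbs_regime(), rounded=False) == pytest.approx(
            1.10 / 0.78
        )

    def test_empty_regime_floor_is_the_cost(self):
        assert floor_price(0.0, None, TaxRegime([])) == 0.0
        assert floor_price(2.334, None, TaxRegime([])) == pytest.approx(2.34)

    def test_infeasible_rate(self):
        r = TaxRegime([
            TaxComponent("a", "ad_valorem", rate=0.6, base=LOCAL),
            TaxComponent("b", "ad_valorem", rate=0.5, base=NATIONAL_MAX),
        ])
        with pytest.raises(InfeasibleRegimeError):
            floor_price(1.0, None, r)

    def test_closed_form_matches_grid_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            alpha = rng.uniform(0.0, 0.95)
            beta = rng.uniform(0.0, 5.0)
            cost = rng.uniform(0.0, 5.0)
            regime = flat_regime(alpha, beta)
            assert floor_price(cost, None, regime) == pytest.approx(
                grid_floor(alpha, beta, cost), abs=1e-9
            )

    def test_floor_is_tight(self):
        # the floor satisfies both constraints; one cent less violates one
        regime = flat_regime(0.45, 2.0)
        p = floor_price(1.3, None, regime)
        a = assess(p, p, None, regime)
        assert a.burden < 1 and p - a.total_tax >= 1.3 - 1e-9
        q = p - 0.01
        aq = assess(q, q, None, regime)
        assert (aq.burden >= 1) or (q - aq.total_tax < 1.3)


class TestMarkupInversion:
    def test_zero_markup_equals_unrounded_floor(self):
        regime = flat_regime(0.3, 1.2)
        assert price_from_markup(0.0, 0.8, None, regime) == pytest.approx(
            floor_price(0.8, None, regime, rounded=False)
        )

    def test_hand_example(self):
        # markup 100%, cost 1, alpha 0.5: p = (2 + 0) / 0.5 = 4; net 2.00
        regime = flat_regime(0.5, 0.0)
        p = price_from_markup(1.0, 1.0, None, regime)
        assert p == pytest.approx(4.00)
        assert p - assess(p, p, None, regime).total_tax == pytest.approx(2.00)

    @given(
        st.floats(0.0, 3.0), st.floats(0.05, 5.0),
        st.floats(0.0, 0.9), st.floats(0.0, 4.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip_and_feasible_burden(self, m, c, alpha, beta):
        regime = flat_regime(alpha, beta)
        p = price_from_markup(m, c, None, regime)
        assert markup_of(p, c, None, regime) == pytest.approx(m, abs=1e-9)
        if m > 0:
            assert assess(p, p, None, regime).burden < 1

    def test_zero_cost_markup_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            markup_of(5.0, 0.0, None, cbs_regime())


class TestRegime:
    def test_state_overrides_change_effective_rate(self):
        r = TaxRegime(
            [TaxComponent("ICMS", "ad_valorem", rate=0.30, base=LOCAL, level="state")],
            {"RJ": {"ICMS": 0.35}},
        )
        assert r.alpha("RJ") == pytest.approx(0.35)
        assert r.alpha("SP") == pytest.approx(0.30)

    def test_override_unknown_component_rejected(self):
        with pytest.raises(ValueError, match="unknown components"):
            TaxRegime([TaxComponent("a", "specific", amount=1.0)], {"SP": {"b": 2.0}})

    def test_yaml_round_trip(self, tmp_path):
        from cigtax.defaults import current_regime

        r = current_regime()
        path = tmp_path / "regime.yaml"
        r.to_yaml(path)
        r2 = TaxRegime.from_yaml(path)
        assert r2.to_dict() == r.to_dict()
        assert r2.alpha("MS") == pytest.approx(r.alpha("MS"))

    def test_component_validation(self):
        with pytest.raises(ValueError):
            TaxComponent("bad", "ad_valorem", rate=1.2)
        with pytest.raises(ValueError):
            TaxComponent("bad", "specific", amount=-0.5)
        with pytest.raises(ValueError):
            TaxComponent("bad", "madeup", rate=0.1)

    def test_round_up_cent(self):
        assert round_up_cent(1.4103) == pytest.approx(1.42)
        assert round_up_cent(1.42) == pytest.approx(1.42)
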