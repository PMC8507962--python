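"""Brazilian federative units, regions and reference populations.

The 26 states plus the Federal District are identified by their two-letter
codes. Region membership is fixed geography and is used throughout the
package to pool elasticity estimates (demand parameters are region-level,
prices and taxes are state-level).
"""

from __future__ import annotations

REGIONS = ("North", "Northeast", "Southeast", "South", "Midwest")

#: state code -> region (fixed geography, 27 units)
STATE_REGION: dict[str, str] = {
    # North
    "AC": "North", "AP": "North", "AM": "North", "PA": "North",
    "RO": "North", "RR": "North", "TO": "North",
    # Northeast
    "AL": "Northeast", "BA": "Northeast", "CE": "Northeast",
    "MA": "Northeast", "PB": "Northeast", "PE": "Northeast",
    "PI": "Northeast", "RN": "Northeast", "SE": "Northeast",
    # Southeast
    "ES": "Southeast", "MG": "Southeast", "RJ": "Southeast", "SP": "Southeast",
    # South
    "PR": "South", "RS": "South", "SC": "South",
    # Midwest
    "DF": "Midwest", "GO": "Midwest", "MT": "Midwest", "MS": "Midwest",
}

STATES: tuple[str, ...] = tuple(sorted(STATE_REGION))

#: approximate resident population per state, 2019 (IBGE projections), persons
STATE_POPULATION: dict[str, int] = {
    "SP": 45_919_000, "MG": 21_168_000, "RJ": 17_264_000, "BA": 14_873_000,
    "PR": 11_434_000, "RS": 11_377_000, "PE": 9_557_000, "CE": 9_132_000,
    "PA": 8_603_000, "SC": 7_164_000, "MA": 7_075_000, "GO": 7_018_000,
    "AM": 4_144_000, "ES": 4_018_000, "PB": 4_018_000, "RN": 3_506_000,
    "MT": 3_484_000, "AL": 3_337_000, "PI": 3_273_000, "DF": 3_015_000,
    "MS": 2_778_000, "SE": 2_299_000, "RO": 1_777_000, "TO": 1_572_000,
    "AC": 881_000, "AP": 845_000, "RR": 605_000,
}


def region_of(state: str) -> str:
    """Return the region of a state code, raising ``KeyError`` with the
    offending code for unknown units."""
    try:
        return STATE_REGION[state]
    except KeyError:
        raise KeyError(f"unknown state code: {state!r}") from None


def states_in(region: str) -> list[str]:
    if region not in REGIONS:
        raise KeyError(f"unknown region: {region!r}")
    return [s for s in STATES if STATE_REGION[s] == region]
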