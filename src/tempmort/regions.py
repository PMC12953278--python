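"""Default registry of Finnish wellbeing service counties.

Minimum-mortality temperatures (MMT) decline from 16 °C on the southern
coast to 14 °C in the north, following prior Finnish temperature-mortality
studies; all values are overridable via configuration.  The four
lowest-population counties are listed because real daily death counts there
are suppressed (counts below three are withheld) on more than half of all
days, which triggers the exclusion rule.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class RegionRegistry:
    """Per-region metadata used across the pipeline."""

    region_id: str
    mmt: float
    missing_fraction: float = 0.0
    included: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ValueError("missing_fraction must be within [0, 1]")


# region_id -> MMT (deg C); south ~16, north ~14
DEFAULT_MMT: dict[str, float] = {
    "Helsinki": 16.0,
    "Vantaa & Kerava": 16.0,
    "West Uusimaa": 16.0,
    "Central Uusimaa": 16.0,
    "East Uusimaa": 16.0,
    "Kymenlaakso": 16.0,
    "South Karelia": 16.0,
    "Paijat-Hame": 16.0,
    "Kanta-Hame": 16.0,
    "Southwest Finland": 16.0,
    "Satakunta": 15.5,
    "Pirkanmaa": 15.5,
    "South Savo": 15.5,
    "Central Finland": 15.0,
    "South Ostrobothnia": 15.0,
    "Ostrobothnia": 15.0,
    "Central Ostrobothnia": 15.0,
    "North Savo": 15.0,
    "North Karelia": 15.0,
    "Kainuu": 14.5,
    "North Ostrobothnia": 14.5,
    "Lapland": 14.0,
    "Aland": 16.0,
}

# Counties whose real data fail the >50% missing-days inclusion rule.
LOW_POPULATION_REGIONS = ("Aland", "Kainuu", "Central Ostrobothnia", "East Uusimaa")


def default_registry() -> dict[str, RegionRegistry]:
    """Registry with packaged MMT defaults and everything included."""
    return {rid: RegionRegistry(region_id=rid, mmt=mmt) for rid, mmt in DEFAULT_MMT.items()}
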