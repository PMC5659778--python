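"""Net-energy requirements (Dutch VEM system) and ration/feed-intake handling.

Requirements are computed per cow-day for maintenance (42.4 VEM per kg^0.75
body weight, +6.7% on grazing days), milk production (VEM per kg FPCM),
growth (parity 1 and 2) and gestation (last four months of pregnancy), with
1,000 VEM = 6.9 MJ net energy.  Lactating cows graze 8 h/day during a
170-day summer block; dry cows are housed indoors year-round.

Feed dry matter follows from dividing net energy by the ration's energy
density per season.  Two rations are shipped: the average Dutch dairy ration
and a reduced-concentrate variant matched to the lower energy demand of
herds with a shortened or omitted dry period.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "EnergyConstants",
    "RationSpec",
    "load_rations",
    "body_weight",
    "maintenance_vem",
    "daily_energy",
    "feed_intake",
    "season",
    "is_summer",
    "WINTER_DAYS",
    "SUMMER_DAYS",
]

WINTER_DAYS = 195
SUMMER_DAYS = 170
#: First/last day-of-year (0-based) of the contiguous summer grazing block.
#: The anchor within the calendar is arbitrary; only seasonal totals matter.
SUMMER_START, SUMMER_END = 105, 274  # inclusive; 170 days

#: Body weight (kg) at calving by parity; constant 650 from third calving on.
WEIGHT_AT_CALVING = {1: 540.0, 2: 595.0, 3: 650.0}

#: Ingredient names used in the ration composition columns.
INGREDIENTS = (
    "grass", "grass_silage", "maize_silage",
    "wet_byproducts", "concentrate", "protein_concentrate",
)


@dataclass(frozen=True)
class EnergyConstants:
    """Coefficients of the VEM net-energy requirement model."""

    maintenance_vem_per_kg075: float = 42.4
    grazing_uplift: float = 1.067
    growth_vem_parity1: float = 660.0
    growth_vem_parity2: float = 330.0
    #: VEM/day in gestation months -4, -3, -2, -1 before calving.
    gestation_vem: tuple = (450.0, 850.0, 1500.0, 2700.0)
    #: Energy requirement for milk; standard value of the VEM system.
    milk_vem_per_kg_fpcm: float = 442.0
    mj_per_1000_vem: float = 6.9
    gestation_length: int = 280

    @property
    def mj_per_vem(self) -> float:
        return self.mj_per_1000_vem / 1000.0


@dataclass(frozen=True)
class RationSpec:
    """One ration: seasonal composition, energy density and GHG factors."""

    name: str
    composition: dict  # season -> {ingredient: % of DM}
    ne_density: dict  # season -> MJ per kg DM
    ghg_feed_production: dict  # season -> kg CO2e per t DM
    ghg_enteric: dict  # season -> kg CO2e per t DM

    def __post_init__(self) -> None:
        for s, comp in self.composition.items():
            total = sum(comp.values())
            if abs(total - 100.0) > 0.2:
                raise ValueError(f"{self.name}/{s} composition sums to {total}")
            if not 6.0 <= self.ne_density[s] <= 7.2:
                raise ValueError(f"{self.name}/{s} energy density out of range")

    def crude_protein(self, cp_per_ingredient: dict, season_: str) -> float:
        """Composition-weighted crude protein (g per kg DM) for a season."""
        comp = self.composition[season_]
        return sum(pct / 100.0 * cp_per_ingredient[ing] for ing, pct in comp.items())


def load_rations() -> dict[str, RationSpec]:
    """Load the shipped ration table keyed by ration name."""
    with resources.files("drysim.data").joinpath("rations.csv").open() as fh:
        df = pd.read_csv(fh)
    out: dict[str, RationSpec] = {}
    for name, grp in df.groupby("ration"):
        comp, dens, prod, ent = {}, {}, {}, {}
        for r in grp.itertuples():
            comp[r.season] = {ing: getattr(r, ing) for ing in INGREDIENTS}
            dens[r.season] = r.ne_mj_per_kg_dm
            prod[r.season] = r.ghg_feed_production
            ent[r.season] = r.ghg_enteric
        out[name] = RationSpec(name, comp, dens, prod, ent)
    return out


def is_summer(day_of_year):
    """Vectorised summer test for 0-based day-of-year (0..364)."""
    d = np.asarray(day_of_year)
    return (d >= SUMMER_START) & (d <= SUMMER_END)


def season(day_of_year: int) -> str:
    """Season of a (1-based) calendar day: 170 summer days, 195 winter days."""
    if not 1 <= day_of_year <= 365:
        raise ValueError("day of year must be in 1..365")
    return "summer" if is_summer(day_of_year - 1) else "winter"


def weight_at_calving(parity: int) -> float:
    return WEIGHT_AT_CALVING[min(parity, 3)]


def body_weight(parity: int, days_since_calving: float, ci: float) -> float:
    """Body weight (kg): linear between consecutive calving weights.

    From the third calving onward weight is constant at 650 kg.  ``ci`` is the
    calving interval over which the gain is spread.
    """
    if not 0 <= days_since_calving <= ci:
        raise ValueError("days_since_calving must lie within the calving interval")
    w0 = weight_at_calving(parity)
    w1 = weight_at_calving(parity + 1)
    return w0 + (w1 - w0) * days_since_calving / ci


def maintenance_vem(
    weight: float, grazing: bool = False, constants: EnergyConstants = EnergyConstants()
):
    """Maintenance requirement (VEM/day) for a given body weight."""
    if np.any(np.asarray(weight) <= 0):
        raise ValueError("weight must be positive")
    base = constants.maintenance_vem_per_kg075 * np.asarray(weight, dtype=float) ** 0.75
    return base * (constants.grazing_uplift if grazing else 1.0)


def gestation_vem(days_to_calving: float, constants: EnergyConstants = EnergyConstants()):
    """Gestation requirement (VEM/day); non-zero in the last four 30-d months."""
    dtc = days_to_calving
    if dtc <= 0 or dtc > 120:
        return 0.0
    tier = min(int((120 - dtc) // 30), 3)  # -4 months .. -1 month
    return constants.gestation_vem[tier]


def daily_energy(
    parity: int,
    weight: float,
    fpcm_today: float,
    lactating: bool,
    summer: bool,
    days_to_calving: float | None,
    constants: EnergyConstants = EnergyConstants(),
) -> float:
    """Total net energy requirement (MJ NE/day) of one cow on one day.

    Grazing applies only to lactating cows on summer days (dry cows stay
    indoors).  ``days_to_calving`` is ``None`` for cows that will not calve
    again (fertility culls receive no gestation allowance).
    """
    vem = maintenance_vem(weight, grazing=(lactating and summer), constants=constants)
    vem += constants.milk_vem_per_kg_fpcm * fpcm_today
    if parity == 1:
        vem += constants.growth_vem_parity1
    elif parity == 2:
        vem += constants.growth_vem_parity2
    if days_to_calving is not None:
        vem += gestation_vem(days_to_calving, constants)
    return float(vem) * constants.mj_per_vem


def feed_intake(energy_mj: float, ration: RationSpec, season_: str) -> float:
    """Feed dry-matter intake (kg DM) needed to supply ``energy_mj``."""
    if energy_mj < 0:
        raise ValueError("energy must be >= 0")
    density = ration.ne_density[season_]
    if density <= 0:
        raise ValueError("energy density must be positive")
    return energy_mj / density
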