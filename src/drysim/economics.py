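"""Partial cash flow per herd-year.

Revenues from sold milk (paid on solids: protein, fat and lactose valued
10:5:1), surplus calves and culled cows, minus costs of feed and of rearing
replacement heifers.  This is a partial budget: veterinary costs, labour,
insemination and discounting are deliberately outside its scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
import warnings

import numpy as np
import pandas as pd
import yaml

from . import lactation as lac

__all__ = [
    "PriceSet",
    "load_prices",
    "milk_revenue",
    "cull_revenue",
    "calf_accounting",
    "partial_cash_flow",
]


@dataclass(frozen=True)
class PriceSet:
    """All prices entering the partial cash flow (EUR, Dutch 2008-2016 means)."""

    protein_per_100kg: float = 576.48
    fat_per_100kg: float = 288.25
    lactose_per_100kg: float = 57.65
    calf_female: float = 51.0
    calf_male: float = 109.0
    cull_meat_per_kg: float = 2.32
    dressing_fraction: float = 0.60
    replacement_heifer: float = 969.0
    #: feed price, EUR per t DM: {ration: {season: price}}
    feed_per_t_dm: dict = None
    replacement_rearing_ratio: float = 1.134
    surplus_calf_mortality: float = 0.07
    sex_ratio_female: float = 0.5

    def milk_price_per_kg(self, fat_pct: float, protein_pct: float,
                          lactose_pct: float) -> float:
        """EUR per kg of milk with the given solids content."""
        return (
            protein_pct / 100.0 * self.protein_per_100kg
            + fat_pct / 100.0 * self.fat_per_100kg
            + lactose_pct / 100.0 * self.lactose_per_100kg
        ) / 100.0


def load_prices() -> PriceSet:
    with resources.files("drysim.data").joinpath("prices.yaml").open() as fh:
        d = yaml.safe_load(fh)
    solids = d["milk_solids_eur_per_100kg"]
    return PriceSet(
        protein_per_100kg=solids["protein"],
        fat_per_100kg=solids["fat"],
        lactose_per_100kg=solids["lactose"],
        calf_female=d["calf_eur_per_head"]["female"],
        calf_male=d["calf_eur_per_head"]["male"],
        cull_meat_per_kg=d["cull_meat_eur_per_kg"],
        dressing_fraction=d["dressing_fraction"],
        replacement_heifer=d["replacement_heifer_eur"],
        feed_per_t_dm=d["feed_eur_per_t_dm"],
        replacement_rearing_ratio=d["replacement_rearing_ratio"],
        surplus_calf_mortality=d["surplus_calf_mortality"],
        sex_ratio_female=d["sex_ratio_female"],
    )


def milk_revenue(milk_kg: float, fat_pct: float, protein_pct: float,
                 lactose_pct: float, prices: PriceSet) -> float:
    """Revenue (EUR) for milk of a given composition under the solids scheme."""
    if np.any(np.asarray(milk_kg) < 0):
        raise ValueError("milk must be >= 0")
    return milk_kg * prices.milk_price_per_kg(fat_pct, protein_pct, lactose_pct)


def cull_revenue(liveweight_kg: float, prices: PriceSet) -> float:
    """Meat revenue (EUR) for a culled cow: live weight x dressing x meat price."""
    if np.any(np.asarray(liveweight_kg) <= 0):
        raise ValueError("live weight must be positive")
    return liveweight_kg * prices.dressing_fraction * prices.cull_meat_per_kg


def calf_accounting(calves: float, culls: float, prices: PriceSet) -> dict:
    """Continuous (expected-value) calf flows for one herd-year.

    Half of the calves are female; 113.4% of the culled-cow count of female
    calves is retained for replacement rearing (covering 13.4% rearing
    mortality); 7% of surplus calves die on farm, the rest are sold.
    """
    if calves < 0 or culls < 0:
        raise ValueError("counts must be >= 0")
    females = prices.sex_ratio_female * calves
    males = calves - females
    retained = prices.replacement_rearing_ratio * culls
    if retained > females:
        warnings.warn("herd cannot self-replace: retained female calves clamped",
                      stacklevel=2)
        retained = females
    surplus_f = females - retained
    surplus_m = males
    survival = 1.0 - prices.surplus_calf_mortality
    sold_f = survival * surplus_f
    sold_m = survival * surplus_m
    return {
        "retained": retained,
        "surplus_female": surplus_f,
        "surplus_male": surplus_m,
        "sold_female": sold_f,
        "sold_male": sold_m,
        "died": (surplus_f + surplus_m) * prices.surplus_calf_mortality,
        "revenue": sold_f * prices.calf_female + sold_m * prices.calf_male,
    }


def _category_milk_prices(prices: PriceSet) -> np.ndarray:
    """EUR/kg for each lactation-curve category's milk composition."""
    table = lac.load_curve_table()
    return np.array([
        prices.milk_price_per_kg(p.fat_pct, p.protein_pct, p.lactose_pct)
        for p in table.values()
    ])


def partial_cash_flow(ledger: pd.DataFrame, prices: PriceSet,
                      ration: str = "average") -> pd.DataFrame:
    """Cash-flow components (EUR) per ledger row (herd-year).

    Milk revenue is composition-specific: each curve category's milk is
    priced at its own solids content.  The decomposition
    ``total = milk + calves + culls - feed - rearing`` is exact.
    """
    cat_prices = _category_milk_prices(prices)
    milk_cols = [c for c in ledger.columns if c.startswith("milk_cat")]
    if len(milk_cols) != len(cat_prices):
        raise ValueError("ledger milk categories do not match the curve table")
    milk_rev = ledger[milk_cols].to_numpy() @ cat_prices

    calf_rows = [calf_accounting(c, k, prices)
                 for c, k in zip(ledger["calves"], ledger["culls"])]
    calf_rev = np.array([r["revenue"] for r in calf_rows])
    surplus = np.array([r["surplus_female"] + r["surplus_male"] for r in calf_rows])

    cull_rev = (ledger["cull_liveweight_kg"].to_numpy()
                * prices.dressing_fraction * prices.cull_meat_per_kg)

    feed_prices = prices.feed_per_t_dm[ration]
    feed_cost = (ledger["dm_winter_kg"].to_numpy() / 1000.0 * feed_prices["winter"]
                 + ledger["dm_summer_kg"].to_numpy() / 1000.0 * feed_prices["summer"])
    rearing = ledger["replacements"].to_numpy() * prices.replacement_heifer

    out = ledger[["herd", "strategy_dp", "year", "year_label"]].copy()
    out["milk_revenue"] = milk_rev
    out["calf_revenue"] = calf_rev
    out["cull_revenue"] = cull_rev
    out["feed_cost"] = feed_cost
    out["rearing_cost"] = rearing
    out["cash_flow"] = milk_rev + calf_rev + cull_rev - feed_cost - rearing
    out["surplus_calves"] = surplus
    return out
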