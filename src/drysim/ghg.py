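"""Life-cycle greenhouse-gas accounting of milk production.

Per herd-year the model sums, in kg CO2 equivalents (GWP-100: CO2 1,
biogenic CH4 28, fossil CH4 30, N2O 265):

* feed production and enteric fermentation, from ration-specific factors
  per t feed DM;
* manure management: CH4 from volatile solids and direct plus indirect N2O
  from excreted N, with location-specific factors (stable slurry vs
  pasture; grazing cows deposit 1/3 of their excretion on pasture during
  summer days);
* rearing of replacement heifers (4,905 kg CO2e per heifer entering);
* minus system-expansion credits for meat from culled cows (2,795 kg CO2e
  each) and, optionally, for surplus calves leaving to the veal chain.

The total is expressed per t fat-and-protein-corrected milk (FPCM).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import energy_feed as ef

__all__ = [
    "EmissionFactorSet",
    "load_emission_factors",
    "feed_and_enteric_emissions",
    "nitrogen_excretion",
    "manure_emissions",
    "ghg_per_t_fpcm",
]

N2O_N_TO_N2O = 44.0 / 28.0


@dataclass(frozen=True)
class EmissionFactorSet:
    """Emission factors outside the ration table (manure, rearing, credits)."""

    rearing_per_heifer: float
    meat_credit_per_cull_cow: float
    veal_credit_per_surplus_calf: float
    ch4_per_kg_vs_stable: float
    ch4_per_kg_vs_pasture: float
    n2o_n_frac_stable: float
    n2o_n_frac_pasture: float
    frac_n_volatilized_stable: float
    frac_n_volatilized_pasture: float
    frac_n_leached_stable: float
    frac_n_leached_pasture: float
    ef4_volatilization: float
    ef5_leaching: float
    pasture_excretion_share: float
    digestibility: float
    ash_fraction: float
    crude_protein_g_per_kg_dm: dict
    n_per_kg_gain: float
    n_gestation_kg_per_day: list
    gwp_co2: float = 1.0
    gwp_ch4_biogenic: float = 28.0
    gwp_ch4_fossil: float = 30.0
    gwp_n2o: float = 265.0

    def __post_init__(self) -> None:
        for name in ("rearing_per_heifer", "meat_credit_per_cull_cow",
                     "ch4_per_kg_vs_stable", "ch4_per_kg_vs_pasture",
                     "n2o_n_frac_stable", "n2o_n_frac_pasture"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def load_emission_factors() -> EmissionFactorSet:
    with resources.files("drysim.data").joinpath("emission_factors.yaml").open() as fh:
        d = yaml.safe_load(fh)
    m = d["manure"]
    return EmissionFactorSet(
        rearing_per_heifer=d["rearing_kg_co2e_per_heifer"],
        meat_credit_per_cull_cow=d["meat_credit_kg_co2e_per_cull_cow"],
        veal_credit_per_surplus_calf=d["veal_credit_kg_co2e_per_surplus_calf"],
        ch4_per_kg_vs_stable=m["ch4_kg_per_kg_vs_stable"],
        ch4_per_kg_vs_pasture=m["ch4_kg_per_kg_vs_pasture"],
        n2o_n_frac_stable=m["n2o_n_frac_stable"],
        n2o_n_frac_pasture=m["n2o_n_frac_pasture"],
        frac_n_volatilized_stable=m["frac_n_volatilized_stable"],
        frac_n_volatilized_pasture=m["frac_n_volatilized_pasture"],
        frac_n_leached_stable=m["frac_n_leached_stable"],
        frac_n_leached_pasture=m["frac_n_leached_pasture"],
        ef4_volatilization=m["ef4_volatilization"],
        ef5_leaching=m["ef5_leaching"],
        pasture_excretion_share=d["pasture_excretion_share"],
        digestibility=d["digestibility"],
        ash_fraction=d["ash_fraction"],
        crude_protein_g_per_kg_dm=d["crude_protein_g_per_kg_dm"],
        n_per_kg_gain=d["n_per_kg_gain"],
        n_gestation_kg_per_day=d["n_gestation_kg_per_day"],
        gwp_co2=d["gwp"]["co2"],
        gwp_ch4_biogenic=d["gwp"]["ch4_biogenic"],
        gwp_ch4_fossil=d["gwp"]["ch4_fossil"],
        gwp_n2o=d["gwp"]["n2o"],
    )


def feed_and_enteric_emissions(dm_winter_kg, dm_summer_kg,
                               ration: ef.RationSpec) -> np.ndarray:
    """kg CO2e from producing and digesting the feed DM of each season."""
    dm_w = np.asarray(dm_winter_kg, dtype=float)
    dm_s = np.asarray(dm_summer_kg, dtype=float)
    if np.any(dm_w < 0) or np.any(dm_s < 0):
        raise ValueError("feed DM must be >= 0")
    f_w = ration.ghg_feed_production["winter"] + ration.ghg_enteric["winter"]
    f_s = ration.ghg_feed_production["summer"] + ration.ghg_enteric["summer"]
    return dm_w / 1000.0 * f_w + dm_s / 1000.0 * f_s


def nitrogen_excretion(feed_dm_kg: float, crude_protein_g_per_kg: float,
                       milk_kg: float, milk_protein_pct: float,
                       n_growth_kg: float = 0.0,
                       n_gestation_kg: float = 0.0) -> float:
    """Excreted N (kg): feed N intake minus retention in milk, growth, gestation."""
    n_in = feed_dm_kg * crude_protein_g_per_kg / 1000.0 / 6.25
    n_milk = milk_kg * milk_protein_pct / 100.0 / 6.38
    n_ex = n_in - n_milk - n_growth_kg - n_gestation_kg
    if n_ex < 0:
        raise ValueError("negative nitrogen excretion: inconsistent crude-protein input")
    return n_ex


def manure_emissions(n_stable_kg, n_pasture_kg, vs_stable_kg, vs_pasture_kg,
                     factors: EmissionFactorSet, breakdown: bool = False):
    """kg CO2e from manure management given location-split N and VS excretion."""
    n_s = np.asarray(n_stable_kg, dtype=float)
    n_p = np.asarray(n_pasture_kg, dtype=float)
    vs_s = np.asarray(vs_stable_kg, dtype=float)
    vs_p = np.asarray(vs_pasture_kg, dtype=float)
    ch4 = vs_s * factors.ch4_per_kg_vs_stable + vs_p * factors.ch4_per_kg_vs_pasture
    n2o_direct = (n_s * factors.n2o_n_frac_stable
                  + n_p * factors.n2o_n_frac_pasture) * N2O_N_TO_N2O
    n_vol = (n_s * factors.frac_n_volatilized_stable
             + n_p * factors.frac_n_volatilized_pasture)
    n_leach = (n_s * factors.frac_n_leached_stable
               + n_p * factors.frac_n_leached_pasture)
    n2o_indirect = (n_vol * factors.ef4_volatilization
                    + n_leach * factors.ef5_leaching) * N2O_N_TO_N2O
    co2e = (ch4 * factors.gwp_ch4_biogenic
            + (n2o_direct + n2o_indirect) * factors.gwp_n2o)
    if breakdown:
        return {"ch4_kg": ch4, "n2o_direct_kg": n2o_direct,
                "n2o_indirect_kg": n2o_indirect, "co2e_kg": co2e}
    return co2e


def ghg_per_t_fpcm(ledger: pd.DataFrame, factors: EmissionFactorSet,
                   ration: ef.RationSpec,
                   surplus_calves=None) -> pd.DataFrame:
    """GHG components and intensity (kg CO2e per t FPCM) per ledger row.

    ``surplus_calves`` (per row) enables the veal-chain credit; without it
    only the cull-cow meat credit applies.
    """
    fpcm_t = ledger["fpcm_kg"].to_numpy() / 1000.0
    if np.any(fpcm_t <= 0):
        raise ValueError("FPCM must be positive to express an intensity")

    feed = feed_and_enteric_emissions(ledger["dm_winter_kg"],
                                      ledger["dm_summer_kg"], ration)
    n_p = ledger["n_pasture_kg"].to_numpy()
    n_s = ledger["n_excreted_kg"].to_numpy() - n_p
    vs_p = ledger["vs_pasture_kg"].to_numpy()
    vs_s = ledger["vs_kg"].to_numpy() - vs_p
    manure = manure_emissions(n_s, n_p, vs_s, vs_p, factors)
    rearing = ledger["replacements"].to_numpy() * factors.rearing_per_heifer
    credit = ledger["culls"].to_numpy() * factors.meat_credit_per_cull_cow
    if surplus_calves is not None:
        credit = credit + (np.asarray(surplus_calves, dtype=float)
                           * factors.veal_credit_per_surplus_calf)

    out = ledger[["herd", "strategy_dp", "year", "year_label"]].copy()
    out["feed_enteric_co2e"] = feed
    out["manure_co2e"] = manure
    out["rearing_co2e"] = rearing
    out["meat_credit_co2e"] = credit
    out["total_co2e"] = feed + manure + rearing - credit
    out["fpcm_t"] = fpcm_t
    out["intensity_co2e_per_t_fpcm"] = out["total_co2e"] / fpcm_t
    return out
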