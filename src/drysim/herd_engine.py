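"""Stochastic individual-based simulation of a 100-cow dairy herd.

The herd is modelled as 100 cow places, each permanently occupied by exactly
one cow.  Cows are simulated lactation by lactation: every lactation starts
with a calving (one calf born) and is stochastically assigned a fate —

* *healthy*: the cow gets a calving interval (CI) drawn from the fitted
  distribution of her parity class and dry-period (DP) category, milks until
  CI minus the next DP length (or until she runs dry spontaneously), is dry
  until the next calving, and starts her next lactation;
* *fertility culling*: the cow never conceives and is removed once her daily
  milk drops below 15 kg;
* *general culling*: the cow is removed at a Beta(1.3, 5)-distributed
  fraction of her assigned CI (median 0.17 of the interval).

A culled cow is replaced the following day by a first-parity heifer (fresh
production level) whose calving starts a new lactation, so places are never
empty.  Time steps have variable duration — a lactation is one step unless
it crosses a 365-day calendar-year boundary, in which case it is split so
that milk, energy and feed can be aggregated exactly per herd per year.

The experiment protocol runs every herd for 5 warm-up years under the
conventional 56-day DP, records year 6 as the baseline ("year 0") and
applies the assigned DP strategy (56, 28 or 0 days) for 5 further years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from . import lactation as lac
from . import energy_feed as ef
from .config import ScenarioConfig

__all__ = [
    "FateTable",
    "CIModel",
    "LactationEvent",
    "load_fate_table",
    "assign_fate",
    "sample_ci",
    "general_cull_day",
    "initialize_herd",
    "simulate_herd",
    "run_strategy",
    "run_experiment",
    "parity_composition_at",
    "ely_records",
    "CI_CAP",
]

CI_CAP = 518  # days; insemination stops ~34 weeks after calving

#: Initial herd: cows in parity 1, 2, 3, 4 and >4 (">4" instantiated as 5).
INITIAL_PARITY_COUNTS = ((1, 30), (2, 21), (3, 15), (4, 10), (5, 24))

_W0 = np.array([0.0, 540.0, 595.0, 650.0])  # weight at calving, parity-indexed


# ---------------------------------------------------------------------------
# stochastic inputs: culling fates and calving intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FateTable:
    """Per-lactation culling probabilities and general-cull timing shape."""

    p_general: float = 0.22
    #: (parity_class, dp_length) -> probability of fertility culling.
    p_fertility: dict = field(default_factory=dict)
    beta_shape_a: float = 1.3
    beta_shape_b: float = 5.0

    def __post_init__(self) -> None:
        for key, p in self.p_fertility.items():
            if not 0.0 <= p <= 1.0 or p + self.p_general >= 1.0:
                raise ValueError(f"inconsistent culling probabilities at {key}")

    def fertility_probability(self, parity_cls: str, dp_length: int,
                              equal: bool = False) -> float:
        if parity_cls == "1" or equal:
            dp_length = 56
        return self.p_fertility[(parity_cls, dp_length)]


def _load_ci_frame() -> pd.DataFrame:
    with resources.files("drysim.data").joinpath("calving_intervals.csv").open() as fh:
        return pd.read_csv(fh, dtype={"parity_class": str})


def load_fate_table(p_general: float = 0.22) -> FateTable:
    df = _load_ci_frame()
    p_fert = {(r.parity_class, int(r.dp_length)): float(r.p_fertility_culling)
              for r in df.itertuples()}
    return FateTable(p_general=p_general, p_fertility=p_fert)


@dataclass(frozen=True)
class _CIRow:
    median: float
    p5: float
    p95: float
    gamma: float  # location shift (days)
    mu: float
    sigma: float
    z_cap: float  # standard-normal coordinate of the 518-day cap


class CIModel:
    """Calving-interval distributions per parity class and DP category.

    Only the median and the 5th/95th percentiles of the observed CI records
    (after discarding intervals above 518 days) are available, so each cell
    is modelled as a *shifted* log-normal — right-skewed with a natural lower
    bound — truncated at 518 days.  The three parameters (shift, log-mean,
    log-sd) are fitted by least squares so that the quantiles of the
    truncated distribution reproduce the three observed quantiles.
    """

    def __init__(self, rows: dict[tuple[str, int], _CIRow], cap: int = CI_CAP):
        self.rows = rows
        self.cap = cap

    @classmethod
    def from_packaged_table(cls) -> "CIModel":
        df = _load_ci_frame()
        rows = {}
        for r in df.itertuples():
            rows[(r.parity_class, int(r.dp_length))] = cls._fit_row(
                float(r.median), float(r.p5), float(r.p95)
            )
        return cls(rows)

    @staticmethod
    def _fit_row(median: float, p5: float, p95: float, cap: float = CI_CAP) -> _CIRow:
        qs = np.array([0.05, 0.5, 0.95])
        targets = np.array([p5, median, p95])

        # Closed-form shift for an untruncated shifted log-normal through the
        # three quantiles; used as the starting point.
        denom = 2.0 * median - p5 - p95
        gamma0 = (median**2 - p5 * p95) / denom if denom != 0 else 0.0
        if not 0.0 <= gamma0 <= p5 - 30.0:
            gamma0 = max(0.0, p5 - 100.0)
        mu0 = np.log(median - gamma0)
        sigma0 = (np.log(p95 - gamma0) - np.log(p5 - gamma0)) / (2 * 1.6449)

        def quantiles(theta):
            gamma, mu, log_sigma = theta
            sigma = np.exp(log_sigma)
            z_cap = (np.log(cap - gamma) - mu) / sigma
            mass = ndtr(z_cap)
            z = ndtri(qs * mass)
            return gamma + np.exp(mu + sigma * z)

        def residuals(theta):
            return quantiles(theta) - targets

        fit = least_squares(
            residuals,
            x0=np.array([gamma0, mu0, np.log(sigma0)]),
            bounds=([0.0, 0.0, np.log(1e-3)], [p5 - 10.0, 10.0, np.log(2.0)]),
            xtol=1e-12, ftol=1e-12,
        )
        gamma, mu, log_sigma = fit.x
        sigma = float(np.exp(log_sigma))
        resid = quantiles(fit.x) - targets
        if np.max(np.abs(resid)) > 2.0:  # days
            raise RuntimeError(
                f"calving-interval fit did not reproduce quantiles: {resid}"
            )
        z_cap = (np.log(cap - gamma) - mu) / sigma
        return _CIRow(median, p5, p95, float(gamma), float(mu), sigma, float(z_cap))

    def _row(self, parity_cls: str, dp_length: int, equal: bool = False) -> _CIRow:
        if parity_cls == "1" or equal:
            dp_length = 56
        return self.rows[(parity_cls, dp_length)]

    def sample(self, rng: np.random.Generator, parity_cls: str, dp_length: int,
               size: Optional[int] = None, equal: bool = False):
        """Draw integer calving intervals (days), never exceeding the cap.

        Sampling inverts the truncated CDF directly, which is equivalent to
        resampling draws above the cap.
        """
        row = self._row(parity_cls, dp_length, equal)
        u = rng.random(size)
        z = ndtri(u * ndtr(row.z_cap))
        ci = row.gamma + np.exp(row.mu + row.sigma * z)
        ci = np.minimum(np.rint(ci), self.cap)
        return int(ci) if size is None else ci.astype(int)


def assign_fate(rng: np.random.Generator, parity_cls: str, dp_length: int,
                fates: FateTable, equal_fertility: bool = False) -> str:
    """Categorical fate draw: fertility cull, general cull, or healthy."""
    p_fert = fates.fertility_probability(parity_cls, dp_length, equal_fertility)
    u = rng.random()
    if u < p_fert:
        return "fertility_cull"
    if u < p_fert + fates.p_general:
        return "general_cull"
    return "healthy"


def sample_ci(rng: np.random.Generator, parity_cls: str, dp_length: int,
              ci_model: CIModel, equal: bool = False) -> int:
    """Assign a calving interval to a (non-fertility-cull) lactation."""
    return ci_model.sample(rng, parity_cls, dp_length, equal=equal)


def general_cull_day(rng: np.random.Generator, ci: int, fates: FateTable) -> int:
    """Day of general culling: a Beta(1.3, 5) fraction of the assigned CI."""
    if ci <= 0:
        raise ValueError("calving interval must be positive")
    frac = rng.beta(fates.beta_shape_a, fates.beta_shape_b)
    return max(1, int(round(ci * frac)))


# ---------------------------------------------------------------------------
# lactation-curve parameter arrays (with optional sensitivity milk shift)
# ---------------------------------------------------------------------------

class _ParamArrays:
    """Curve table flattened to arrays for vectorised day-level accounting."""

    def __init__(self, milk_shift: float = 0.0):
        table = lac.load_curve_table()
        self.rows: list[lac.LactationParams] = []
        self.index: dict[tuple[str, str], int] = {}
        for (pcls, cat), params in table.items():
            if milk_shift != 0.0 and cat in ("short28", "no0_after56", "no0_after0"):
                params = lac.LactationParams(
                    pcls, cat, params.ady + milk_shift, params.a + milk_shift,
                    params.b, params.c, params.k,
                    params.fat_pct, params.protein_pct, params.lactose_pct,
                )
            self.index[(pcls, cat)] = len(self.rows)
            self.rows.append(params)
        get = lambda attr: np.array([getattr(p, attr) for p in self.rows])
        self.a, self.b, self.c, self.k, self.ady = (
            get("a"), get("b"), get("c"), get("k"), get("ady"))
        self.protein = get("protein_pct")
        self.fpcm_f = np.array([lac.fpcm_factor(p) for p in self.rows])

    def row_id(self, parity: int, category: str) -> int:
        pcls = lac.parity_class(parity)
        if pcls == "1":
            return self.index[("1", "heifer")]
        if pcls == "2" and category == "no0_after0":
            category = "no0_after56"
        return self.index[(pcls, category)]

    def params(self, row_id: int) -> lac.LactationParams:
        return self.rows[row_id]


# ---------------------------------------------------------------------------
# event generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class LactationEvent:
    """One simulated lactation within a cow place."""

    place: int
    t0: int            # absolute calving day (0-based; year = t0 // 365)
    parity: int
    row_id: int
    category: str
    fate: str
    rpl: float
    ci: Optional[int]  # assigned calving interval (None for fertility culls)
    length: int        # days the lactation occupies the place
    milk_end: float    # DIM at which milk production stops


@dataclass
class _PlaceState:
    place: int
    parity: int
    rpl: float
    dp_before: int        # DP that preceded the current lactation
    dp_before_prev: int   # DP that preceded the previous lactation
    t0: int               # calving day of the current lactation


def initialize_herd(rng: np.random.Generator, n_places: int = 100,
                    rpl_sd: float = 0.1) -> list[_PlaceState]:
    """Create the day-1 herd: fixed parity mix, all after a conventional DP.

    Parity counts 30/21/15/10/24 for parities 1-4 and >4 reflect a 30%
    culling rate; ">4" cows are instantiated as parity 5 (the warm-up years
    erase any initialisation detail).
    """
    counts = dict(INITIAL_PARITY_COUNTS)
    if sum(counts.values()) != n_places:
        # scale proportionally for reduced test herds
        parities = np.repeat([p for p, c in INITIAL_PARITY_COUNTS],
                             [c for p, c in INITIAL_PARITY_COUNTS])
        idx = np.linspace(0, len(parities) - 1, n_places).round().astype(int)
        chosen = parities[idx]
    else:
        chosen = np.repeat(list(counts.keys()), list(counts.values()))
    return [
        _PlaceState(place=i, parity=int(p), rpl=float(rng.normal(0.0, rpl_sd)),
                    dp_before=56, dp_before_prev=56, t0=0)
        for i, p in enumerate(chosen)
    ]


def _strategy_on(day: int, switch_day: int, assigned_dp: int) -> int:
    return assigned_dp if day >= switch_day else 56


def _simulate_place(state: _PlaceState, cfg: ScenarioConfig, assigned_dp: int,
                    params: _ParamArrays, ci_model: CIModel, fates: FateTable,
                    rng: np.random.Generator, events: list[LactationEvent]) -> None:
    horizon, switch = cfg.horizon_days, cfg.switch_day
    while state.t0 < horizon:
        cat = lac.dp_category(state.parity, state.dp_before, state.dp_before_prev)
        rid = params.row_id(state.parity, cat)
        p = params.params(rid)
        pcls = lac.parity_class(state.parity)
        fate = assign_fate(rng, pcls, state.dp_before, fates,
                           cfg.equal_fertility_culling)
        if fate == "fertility_cull":
            cull_dim = max(1, int(round(lac.fertility_cull_day(p, state.rpl))))
            events.append(LactationEvent(state.place, state.t0, state.parity, rid,
                                         cat, fate, state.rpl, None, cull_dim,
                                         float(cull_dim)))
            state.parity, state.rpl = 1, float(rng.normal(0.0, cfg.rpl_sd))
            state.dp_before = state.dp_before_prev = 56
            state.t0 += cull_dim
            continue

        ci = sample_ci(rng, pcls, state.dp_before, ci_model, cfg.equal_ci)
        dryoff0 = lac.spontaneous_dryoff_day(p, state.rpl, float(CI_CAP + 1))

        if fate == "general_cull":
            cull_dim = general_cull_day(rng, ci, fates)
            milk_end = float(cull_dim) if dryoff0 is None else min(float(cull_dim), dryoff0)
            events.append(LactationEvent(state.place, state.t0, state.parity, rid,
                                         cat, fate, state.rpl, ci, cull_dim, milk_end))
            state.parity, state.rpl = 1, float(rng.normal(0.0, cfg.rpl_sd))
            state.dp_before = state.dp_before_prev = 56
            state.t0 += cull_dim
            continue

        # healthy: the DP ending this lactation follows the strategy in force
        # on the day the conventional dry-off would happen
        next_dp = _strategy_on(state.t0 + ci - 56, switch, assigned_dp)
        planned_end = float(ci - next_dp)
        milk_end = planned_end if (dryoff0 is None or dryoff0 >= planned_end) else dryoff0
        events.append(LactationEvent(state.place, state.t0, state.parity, rid,
                                     cat, fate, state.rpl, ci, ci, milk_end))
        state.parity += 1
        state.dp_before_prev, state.dp_before = state.dp_before, next_dp
        state.t0 += ci


# ---------------------------------------------------------------------------
# day-level accounting (vectorised per herd)
# ---------------------------------------------------------------------------

def _ledger_from_events(events: list[LactationEvent], cfg: ScenarioConfig,
                        params: _ParamArrays, ration: ef.RationSpec,
                        constants: ef.EnergyConstants,
                        activity: dict) -> pd.DataFrame:
    """Aggregate lactation events into one row per calendar year.

    Every occupied cow-day is expanded once; milk per day is the exact
    closed-form integral of the Wilmink curve over that day, so annual milk
    equals the whole-lactation integral no matter how lactations are split
    across calendar years.
    """
    n_years = cfg.total_years
    horizon = cfg.horizon_days

    t0 = np.array([e.t0 for e in events])
    length = np.array([e.length for e in events])
    rid = np.array([e.row_id for e in events])
    rpl = np.array([e.rpl for e in events])
    parity = np.array([e.parity for e in events])
    m_end = np.array([e.milk_end for e in events])
    ci = np.array([e.ci if e.ci is not None else -1 for e in events])
    fert = np.array([e.fate == "fertility_cull" for e in events])

    n_days = np.minimum(length, horizon - t0)
    total = int(n_days.sum())
    eid = np.repeat(np.arange(len(events)), n_days)
    starts = np.concatenate(([0], np.cumsum(n_days)[:-1]))
    dim = np.arange(total) - np.repeat(starts, n_days)

    t = t0[eid] + dim
    year = t // 365
    summer = ef.is_summer(t % 365)

    r = rid[eid]
    rp = rpl[eid]
    a_eff = params.a[r] + rp * params.ady[r]
    b, c, k = params.b[r], params.c[r], params.k[r]

    me = m_end[eid]
    lo = np.minimum(dim, me)
    hi = np.minimum(dim + 1.0, me)
    F = lambda x: a_eff * x + 0.5 * b * x * x - (c / k) * np.exp(-k * x)
    milk_d = np.maximum(F(hi) - F(lo), 0.0)
    fpcm_d = milk_d * params.fpcm_f[r]
    frac_milk = hi - lo
    lactating = frac_milk > 0.0

    # body weight: linear between calving weights over the assigned CI
    # (365 days assumed for fertility culls, which have no interval)
    par = parity[eid]
    w0 = _W0[np.minimum(par, 3)]
    w1 = _W0[np.minimum(par + 1, 3)]
    span = np.where(ci[eid] > 0, ci[eid], 365).astype(float)
    slope = (w1 - w0) / span
    weight = np.minimum(w0 + slope * dim, 650.0)

    graze = summer & lactating
    maint = constants.maintenance_vem_per_kg075 * weight**0.75
    maint = np.where(graze, maint * constants.grazing_uplift, maint)
    vem = maint + constants.milk_vem_per_kg_fpcm * fpcm_d
    vem += np.where(par == 1, constants.growth_vem_parity1,
                    np.where(par == 2, constants.growth_vem_parity2, 0.0))
    # gestation allowance in the last four 30-day months before next calving
    dtc = np.where(~fert[eid] & (ci[eid] > 0), ci[eid] - dim, 1e9)
    gest_t = np.asarray(constants.gestation_vem)
    in_gest = (dtc > 0) & (dtc <= 120)
    tier = np.clip(((120 - dtc) // 30).astype(int), 0, 3)
    vem += np.where(in_gest, gest_t[tier], 0.0)
    ne_mj = vem * constants.mj_per_vem

    dens = np.where(summer, ration.ne_density["summer"], ration.ne_density["winter"])
    dm = ne_mj / dens

    cp = activity["cp_per_ingredient"]
    cp_season = {s: ration.crude_protein(cp, s) for s in ("winter", "summer")}
    n_in = dm * np.where(summer, cp_season["summer"], cp_season["winter"]) / 1000.0 / 6.25
    n_milk = milk_d * params.protein[r] / 100.0 / 6.38
    gain = np.where((par <= 2) & (weight < 650.0), slope, 0.0)
    n_gain = gain * activity["n_per_kg_gain"]
    gest_n = np.asarray(activity["n_gestation_kg_per_day"])
    n_gest = np.where(in_gest, gest_n[tier], 0.0)
    n_ex = n_in - n_milk - n_gain - n_gest
    if np.any(n_ex < 0):
        raise ValueError("negative nitrogen excretion: inconsistent crude-protein input")

    vs = dm * (1.0 - activity["digestibility"]) * (1.0 - activity["ash_fraction"])
    pasture = np.where(graze, activity["pasture_excretion_share"], 0.0)

    def by_year(x):
        return np.bincount(year, weights=x, minlength=n_years)

    ys_key = year * 2 + summer.astype(int)
    def by_year_season(x):
        out = np.bincount(ys_key, weights=x, minlength=n_years * 2)
        return out.reshape(n_years, 2)  # [:, 0] winter, [:, 1] summer

    ne_ys = by_year_season(ne_mj)
    dm_ys = by_year_season(dm)
    milk_yr_row = np.bincount(year * len(params.rows) + r, weights=milk_d,
                              minlength=n_years * len(params.rows)
                              ).reshape(n_years, len(params.rows))

    data = {
        "year": np.arange(n_years),
        "year_label": np.arange(n_years) - cfg.warmup_years,
        "milk_kg": by_year(milk_d),
        "fpcm_kg": by_year(fpcm_d),
        "dry_days": by_year(1.0 - frac_milk),
        "ne_mj_winter": ne_ys[:, 0],
        "ne_mj_summer": ne_ys[:, 1],
        "dm_winter_kg": dm_ys[:, 0],
        "dm_summer_kg": dm_ys[:, 1],
        "n_excreted_kg": by_year(n_ex),
        "n_pasture_kg": by_year(n_ex * pasture),
        "vs_kg": by_year(vs),
        "vs_pasture_kg": by_year(vs * pasture),
    }
    for j in range(len(params.rows)):
        data[f"milk_cat{j}_kg"] = milk_yr_row[:, j]

    # event-level counts
    calves = np.bincount(t0 // 365, minlength=n_years)[:n_years]
    cull_mask = np.array([e.fate != "healthy" for e in events])
    cull_day = t0 + length - 1
    ok = cull_mask & (cull_day < horizon)
    culls = np.bincount(cull_day[ok] // 365, minlength=n_years)[:n_years]
    fert_ok = ok & fert
    culls_f = np.bincount(cull_day[fert_ok] // 365, minlength=n_years)[:n_years]
    entry = t0 + length
    repl_ok = cull_mask & (entry < horizon)
    repl = np.bincount(entry[repl_ok] // 365, minlength=n_years)[:n_years]
    # live weight of each culled cow on her cull day
    spans = np.where(ci > 0, ci, 365).astype(float)
    w_cull = np.minimum(
        _W0[np.minimum(parity, 3)]
        + (_W0[np.minimum(parity + 1, 3)] - _W0[np.minimum(parity, 3)])
        * np.minimum(length, spans) / spans,
        650.0,
    )
    meat = np.bincount(cull_day[ok] // 365, weights=w_cull[ok],
                       minlength=n_years)[:n_years]

    data.update({
        "calves": calves,
        "culls": culls,
        "culls_fertility": culls_f,
        "culls_general": culls - culls_f,
        "replacements": repl,
        "cull_liveweight_kg": meat,
    })
    return pd.DataFrame(data)


def simulate_herd(herd_index: int, cfg: ScenarioConfig, assigned_dp: int,
                  shared: Optional[dict] = None,
                  collect_events: bool = False):
    """Simulate one herd over the full protocol; return its yearly ledger.

    ``herd_index`` seeds the herd deterministically (child seed of
    ``cfg.seed``), so adding herds never reshuffles existing ones.
    """
    shared = shared or build_shared_inputs(cfg)
    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(herd_index,))))
    places = initialize_herd(rng, cfg.n_places, cfg.rpl_sd)
    events: list[LactationEvent] = []
    for st in places:
        _simulate_place(st, cfg, assigned_dp, shared["params"], shared["ci_model"],
                        shared["fates"], rng, events)
    ledger = _ledger_from_events(events, cfg, shared["params"], shared["ration"],
                                 shared["constants"], shared["activity"])
    ledger.insert(0, "herd", herd_index)
    ledger.insert(1, "strategy_dp", assigned_dp)
    if collect_events:
        return ledger, events
    return ledger


def build_shared_inputs(cfg: ScenarioConfig) -> dict:
    """Prepare the deterministic model inputs shared by all herds of a run."""
    from . import ghg  # deferred: activity constants live with the GHG config
    factors = ghg.load_emission_factors()
    return {
        "params": _ParamArrays(cfg.milk_shift),
        "ci_model": CIModel.from_packaged_table(),
        "fates": load_fate_table(cfg.p_general),
        "ration": ef.load_rations()[cfg.ration],
        "constants": ef.EnergyConstants(),
        "activity": {
            "cp_per_ingredient": factors.crude_protein_g_per_kg_dm,
            "n_per_kg_gain": factors.n_per_kg_gain,
            "n_gestation_kg_per_day": factors.n_gestation_kg_per_day,
            "digestibility": factors.digestibility,
            "ash_fraction": factors.ash_fraction,
            "pasture_excretion_share": factors.pasture_excretion_share,
        },
    }


def run_strategy(cfg: ScenarioConfig, assigned_dp: int, herd_offset: int = 0,
                 collect_events: bool = False):
    """Simulate ``cfg.n_herds`` herds under one DP strategy."""
    shared = build_shared_inputs(cfg)
    ledgers, all_events = [], {}
    for h in range(cfg.n_herds):
        idx = herd_offset + h
        out = simulate_herd(idx, cfg, assigned_dp, shared, collect_events)
        if collect_events:
            ledger, events = out
            all_events[idx] = events
        else:
            ledger = out
        ledgers.append(ledger)
    ledger = pd.concat(ledgers, ignore_index=True)
    return (ledger, all_events) if collect_events else ledger


def run_experiment(cfg: ScenarioConfig, collect_events: bool = False):
    """Run the full three-strategy experiment (56/28/0-day DP).

    Herds are independent across strategies: indices 0..n-1 warm up and stay
    at a 56-day DP, n..2n-1 switch to 28 days, 2n..3n-1 to no DP.
    """
    parts, events = [], {}
    for g, dp in enumerate((56, 28, 0)):
        out = run_strategy(cfg, dp, herd_offset=g * cfg.n_herds,
                           collect_events=collect_events)
        if collect_events:
            led, ev = out
            events.update(ev)
        else:
            led = out
        parts.append(led)
    ledger = pd.concat(parts, ignore_index=True)
    return (ledger, events) if collect_events else ledger


# ---------------------------------------------------------------------------
# derived views
# ---------------------------------------------------------------------------

def parity_composition_at(events: list[LactationEvent], day: int) -> dict[int, int]:
    """Parity histogram (1, 2, 3, 4, 5 = '>4') of the herd on a given day."""
    comp: dict[int, int] = {p: 0 for p in (1, 2, 3, 4, 5)}
    for e in events:
        if e.t0 <= day < e.t0 + e.length:
            comp[min(e.parity, 5)] += 1
    return comp


def ely_records(events: list[LactationEvent], params: _ParamArrays,
                horizon: int) -> pd.DataFrame:
    """Effective lactation yield per completed lactation.

    ELY is FPCM per day from 60 days before calving until 60 days before the
    next calving (healthy) or until culling.  The pre-calving milk comes from
    the tail of the same cow's previous lactation — zero for first-parity
    cows — and is expressed in the current lactation's milk composition.
    """
    by_place: dict[int, list[LactationEvent]] = {}
    for e in events:
        by_place.setdefault(e.place, []).append(e)
    rows = []
    for place, evs in by_place.items():
        evs.sort(key=lambda e: e.t0)
        for i, e in enumerate(evs):
            win_end = e.ci - 60 if e.fate == "healthy" else e.length
            if win_end <= -60 or e.t0 + max(win_end, 0) > horizon:
                continue
            p = params.params(e.row_id)
            own = lac.cumulative_milk(p, e.rpl, 0.0, max(min(e.milk_end, win_end), 0.0))
            pre = 0.0
            if e.parity >= 2 and i > 0 and evs[i - 1].fate == "healthy":
                prev = evs[i - 1]
                pp = params.params(prev.row_id)
                lo = prev.ci - 60.0
                hi = min(prev.milk_end, float(prev.ci))
                if hi > lo:
                    pre = lac.cumulative_milk(pp, prev.rpl, lo, hi)
            total_fpcm = lac.fpcm(own + pre, p.fat_pct, p.protein_pct)
            window = 60.0 + win_end
            if window <= 0:
                continue
            rows.append({
                "place": place,
                "parity_class": lac.parity_class(e.parity),
                "category": e.category,
                "fate": e.fate,
                "ely": lac.effective_lactation_yield(total_fpcm, window),
                "ci": e.ci,
                "cull_day": e.length if e.fate != "healthy" else np.nan,
            })
    return pd.DataFrame(rows)
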