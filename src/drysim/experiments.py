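"""Reference experiment, sensitivity grid and reporting helpers."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import economics, energy_feed as ef, ghg, herd_engine as he
from .config import ScenarioConfig

__all__ = [
    "ReferenceResult",
    "run_reference",
    "summarize_by_strategy_year",
    "ely_summary",
    "SENSITIVITY_SCENARIOS",
    "run_sensitivity",
    "report",
]


@dataclass
class ReferenceResult:
    """Ledgers and derived tables of one full three-strategy experiment."""

    config: ScenarioConfig
    ledger: pd.DataFrame
    cash: pd.DataFrame
    emissions: pd.DataFrame
    summary: pd.DataFrame
    ely: Optional[pd.DataFrame] = None

    def strategy_year_mean(self, column: str, strategy: int, years) -> float:
        """Mean of a ledger column over herds for given strategy/year labels."""
        df = self.ledger
        sel = df[(df["strategy_dp"] == strategy) & (df["year_label"].isin(list(years)))]
        return float(sel[column].mean())


def _derive(ledger: pd.DataFrame, cfg: ScenarioConfig):
    prices = economics.load_prices()
    factors = ghg.load_emission_factors()
    ration = ef.load_rations()[cfg.ration]
    cash = economics.partial_cash_flow(ledger, prices, cfg.ration)
    emissions = ghg.ghg_per_t_fpcm(ledger, factors, ration,
                                   surplus_calves=cash["surplus_calves"])
    return cash, emissions


def summarize_by_strategy_year(ledger: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD over herds of the main output variables per strategy-year."""
    cols = {
        "milk_kg": "milk",
        "fpcm_kg": "fpcm",
        "calves": "calves",
        "culls": "culls",
        "dry_days": "dry_days_total",
        "ne_mj_winter": "ne_mj_winter",
        "ne_mj_summer": "ne_mj_summer",
    }
    g = ledger.groupby(["strategy_dp", "year_label"])
    out = g[list(cols)].agg(["mean", "std"])
    out.columns = [f"{cols[c]}_{stat}" for c, stat in out.columns]
    return out.reset_index()


def run_reference(cfg: ScenarioConfig, collect_events: bool = False,
                  strategies: tuple = (56, 28, 0)) -> ReferenceResult:
    """Run the experiment and attach cash-flow, GHG and summary tables.

    ``strategies`` restricts the run to a subset of the three DP arms; herd
    indices stay tied to their canonical arm (56 -> 0..n-1, 28 -> n..2n-1,
    0 -> 2n..3n-1) so a subset run reproduces the full run's herds exactly.
    """
    parts, events = [], {}
    for dp in strategies:
        offset = {56: 0, 28: cfg.n_herds, 0: 2 * cfg.n_herds}[dp]
        out = he.run_strategy(cfg, dp, herd_offset=offset,
                              collect_events=collect_events)
        if collect_events:
            led, ev = out
            events.update(ev)
        else:
            led = out
        parts.append(led)
    ledger = pd.concat(parts, ignore_index=True)
    events = events if collect_events else None
    cash, emissions = _derive(ledger, cfg)
    summary = summarize_by_strategy_year(ledger)
    ely = None
    if events is not None:
        params = he._ParamArrays(cfg.milk_shift)
        frames = []
        for idx, evs in events.items():
            df = he.ely_records(evs, params, cfg.horizon_days)
            df.insert(0, "herd", idx)
            frames.append(df)
        ely = pd.concat(frames, ignore_index=True)
    return ReferenceResult(cfg, ledger, cash, emissions, summary, ely)


def ely_summary(ely: pd.DataFrame) -> pd.DataFrame:
    """Mean effective lactation yield, CI and cull day per class/category/fate."""
    g = ely.groupby(["parity_class", "category", "fate"])
    out = g.agg(ely=("ely", "mean"), ci=("ci", "mean"),
                cull_day=("cull_day", "mean"), n=("ely", "size"))
    return out.reset_index()


#: The sensitivity grid: name -> config overrides (applied on top of the
#: reference).  Milk-yield shifts and the equal-CI / equal-fertility-culling
#: scenarios only alter shortened/omitted-DP herds by construction.
SENSITIVITY_SCENARIOS = {
    "p_general_0.12": {"p_general": 0.12},
    "p_general_0.17": {"p_general": 0.17},
    "p_general_0.27": {"p_general": 0.27},
    "equal_fertility_culling": {"equal_fertility_culling": True},
    "equal_ci": {"equal_ci": True},
    "milk_+1": {"milk_shift": 1.0},
    "milk_+2": {"milk_shift": 2.0},
    "milk_-1": {"milk_shift": -1.0},
    "milk_-2": {"milk_shift": -2.0},
}


def run_sensitivity(cfg: ScenarioConfig,
                    reference: Optional[ReferenceResult] = None,
                    scenarios: Optional[dict] = None) -> pd.DataFrame:
    """Delta tables of cash flow and GHG intensity against the reference.

    Every scenario-strategy cell is compared with the mean of the DP-56
    reference herds (22% general culling, no shifts) in the same scenario
    year.  Scenario runs reuse the reference's per-herd child seeds, so the
    comparisons use common random numbers.
    """
    if reference is None:
        reference = run_reference(cfg)
    scenarios = dict(scenarios) if scenarios is not None else dict(SENSITIVITY_SCENARIOS)

    ref_cash = reference.cash.groupby(["year_label"])["cash_flow"].mean()
    ref_ghg = reference.emissions.groupby(["year_label"])[
        "intensity_co2e_per_t_fpcm"].mean()

    rows = []

    def add_rows(name: str, ledger: pd.DataFrame, run_cfg: ScenarioConfig) -> None:
        cash, emissions = _derive(ledger, run_cfg)
        cm = cash.groupby(["strategy_dp", "year_label"])["cash_flow"].mean()
        gm = emissions.groupby(["strategy_dp", "year_label"])[
            "intensity_co2e_per_t_fpcm"].mean()
        for (dp, yl), value in cm.items():
            if yl < 1:
                continue
            ref56 = ref_cash.loc[yl]
            rows.append({
                "scenario": name, "strategy_dp": dp, "year": yl,
                "delta_cash_flow": value - ref56,
                "delta_ghg_intensity": gm.loc[(dp, yl)] - ref_ghg.loc[yl],
            })

    # the reference's own DP-28/DP-0 cells
    add_rows("reference", reference.ledger, cfg)

    for name, overrides in scenarios.items():
        run_cfg = cfg.replace(**overrides)
        # milk shifts and equal-CI/fertility flags do not touch DP-56 herds
        dp56_invariant = set(overrides) <= {"milk_shift", "equal_ci",
                                            "equal_fertility_culling"}
        strategies = (28, 0) if dp56_invariant else (56, 28, 0)
        parts = []
        for dp in strategies:
            offset = {56: 0, 28: cfg.n_herds, 0: 2 * cfg.n_herds}[dp]
            parts.append(he.run_strategy(run_cfg, dp, herd_offset=offset))
        add_rows(name, pd.concat(parts, ignore_index=True), run_cfg)

    return pd.DataFrame(rows)


def report(result: ReferenceResult, outdir: str | Path,
           sensitivity: Optional[pd.DataFrame] = None,
           figures: bool = False) -> dict:
    """Write tidy CSVs (and optional box-plot figures) plus a run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}

    def save(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        written[name] = str(path)

    save(result.ledger, "herd_year_ledger.csv")
    save(result.cash, "cash_flow_components.csv")
    save(result.emissions, "ghg_components.csv")
    save(result.summary, "summary_by_strategy_year.csv")
    if result.ely is not None:
        save(ely_summary(result.ely), "effective_lactation_yield.csv")
    if sensitivity is not None:
        save(sensitivity, "sensitivity_deltas.csv")

    if figures:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(9, 4))
        df = result.ledger[result.ledger["year_label"] >= 0]
        labels, data = [], []
        for yl in sorted(df["year_label"].unique()):
            for dp in (56, 28, 0):
                sel = df[(df["year_label"] == yl) & (df["strategy_dp"] == dp)]
                data.append(sel["milk_kg"].to_numpy() / 1000.0)
                labels.append(f"y{yl}\n{dp}d")
        ax.boxplot(data, tick_labels=labels)
        ax.set_ylabel("milk (t/herd/year)")
        ax.set_title("Herd milk production by dry-period strategy")
        fig.tight_layout()
        fig.savefig(outdir / "milk_by_strategy_year.png", dpi=120)
        plt.close(fig)
        written["milk_by_strategy_year.png"] = str(outdir / "milk_by_strategy_year.png")

    manifest = {"config": result.config.to_dict(), "files": sorted(written)}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    written["manifest.json"] = str(outdir / "manifest.json")
    return written
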