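"""Scenario configuration for herd simulation experiments."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["ScenarioConfig"]

VALID_DP = (56, 28, 0)
VALID_RATIONS = ("average", "reduced_concentrate")


@dataclass(frozen=True)
class ScenarioConfig:
    """Settings of one simulation scenario.

    The reference experiment uses the defaults: 50 herds of 100 cows per
    dry-period strategy, 5 warm-up years under a 56-day DP, one baseline year
    (reported as year 0), 5 scenario years, a general-culling probability of
    0.22 per lactation and the average Dutch ration.

    Sensitivity levers
    ------------------
    ``p_general``
        Probability of general culling per lactation (0.12/0.17/0.22/0.27
        span overall culling rates of roughly 20-35%).
    ``milk_shift``
        kg/day added to the level (``a``) and average daily yield (``ady``)
        of the shortened- and omitted-DP curves, i.e. a lesser (+) or
        greater (-) milk reduction relative to the conventional DP.
    ``equal_ci`` / ``equal_fertility_culling``
        Use the conventional-DP calving-interval distributions or
        fertility-culling probabilities for every DP category.
    """

    strategy_dp: int = 56
    n_herds: int = 50
    n_places: int = 100
    warmup_years: int = 5
    scenario_years: int = 5
    p_general: float = 0.22
    milk_shift: float = 0.0
    equal_ci: bool = False
    equal_fertility_culling: bool = False
    ration: str = "average"
    rpl_sd: float = 0.1
    seed: int = 2017

    def __post_init__(self) -> None:
        if self.strategy_dp not in VALID_DP:
            raise ValueError(f"strategy_dp must be one of {VALID_DP}")
        if self.ration not in VALID_RATIONS:
            raise ValueError(f"ration must be one of {VALID_RATIONS}")
        if self.n_herds < 1 or self.scenario_years < 1:
            raise ValueError("need at least one herd and one scenario year")
        if not 0.0 <= self.p_general < 1.0:
            raise ValueError("p_general must be a probability")

    @property
    def total_years(self) -> int:
        """Warm-up + baseline year + scenario years."""
        return self.warmup_years + 1 + self.scenario_years

    @property
    def horizon_days(self) -> int:
        return self.total_years * 365

    @property
    def switch_day(self) -> int:
        """First (0-based) absolute day on which the new DP strategy applies."""
        return (self.warmup_years + 1) * 365

    def year_label(self, year_index: int) -> int:
        """Map an internal 0-based calendar year to the reported scale.

        The baseline year is 0 and scenario years are 1..n; warm-up years get
        negative labels.
        """
        return year_index - self.warmup_years

    def replace(self, **kwargs) -> "ScenarioConfig":
        d = asdict(self)
        d.update(kwargs)
        return ScenarioConfig(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
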