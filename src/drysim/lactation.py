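"""Deterministic lactation-curve mathematics.

Daily milk yield of an individual cow follows a Wilmink curve

    MP(t) = a + b*t + c*exp(-k*t) + RPL * ADY,

where ``t`` is days in milk (DIM), ``a``..``k`` are curve coefficients fitted
per parity class (1, 2, >2) and dry-period (DP) category, ``ADY`` is the
average daily 305-d yield of that class, and ``RPL`` is the cow's relative
production level (drawn once per cow from N(0, 0.1), shifting her whole
productive life up or down by up to roughly +/-20%).

The DP categories distinguish a conventional 56-day DP, a shortened 28-day
DP, and an omitted DP, the latter split by whether the *previous* lactation
already had no DP (milk losses shrink once no-DP is applied repeatedly).
First-parity cows have no preceding DP, so a single "heifer" curve applies.

All milk totals use the closed-form antiderivative of MP, so integration is
exact and additive over adjacent intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "LactationParams",
    "CowLactationSpec",
    "load_curve_table",
    "parity_class",
    "dp_category",
    "daily_milk",
    "milk_antiderivative",
    "cumulative_milk",
    "fpcm",
    "fpcm_factor",
    "peak_dim",
    "spontaneous_dryoff_day",
    "fertility_cull_day",
    "effective_lactation_yield",
]

#: Hard cap on root searches along the descending limb (days in milk).
#: Observed calving intervals never approach this.
MAX_DIM = 600.0

#: FPCM standard: 1 kg of milk at 4.00% fat and 3.32% protein = 1 kg FPCM.
_FPCM_BASE, _FPCM_FAT, _FPCM_PROTEIN = 0.337, 0.116, 0.06

#: Default fertility-culling milk threshold (kg/day): a cow that failed to
#: conceive is removed once her daily yield drops below this level.
FERTILITY_CULL_THRESHOLD = 15.0

PARITY_CLASSES = ("1", "2", "gt2")
DP_CATEGORIES = ("heifer", "std56", "short28", "no0_after56", "no0_after0")


@dataclass(frozen=True)
class LactationParams:
    """Curve coefficients and milk composition for one parity class x DP category."""

    parity_class: str
    dp_category: str
    ady: float  # kg/day, average daily 305-d yield
    a: float  # kg/day
    b: float  # kg/day per DIM (persistency; negative)
    c: float  # kg/day (early-lactation dip; negative)
    k: float  # 1/day
    fat_pct: float
    protein_pct: float
    lactose_pct: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b < 0 and self.c < 0 and self.k > 0):
            raise ValueError(
                f"implausible curve coefficients for "
                f"({self.parity_class}, {self.dp_category})"
            )


@dataclass(frozen=True)
class CowLactationSpec:
    """One cow-lactation: curve, production level, and assigned fate.

    ``planned_ci`` is present for healthy and general-culled lactations (both
    get a calving interval assigned); fertility-culled cows never conceive,
    so no interval exists for them.
    """

    params: LactationParams
    rpl: float
    fate: str  # 'healthy' | 'fertility_cull' | 'general_cull'
    planned_ci: Optional[int] = None
    next_dp_length: Optional[int] = None

    def __post_init__(self) -> None:
        has_ci = self.planned_ci is not None
        if self.fate == "fertility_cull" and has_ci:
            raise ValueError("fertility-culled lactations carry no calving interval")
        if self.fate in ("healthy", "general_cull") and not has_ci:
            raise ValueError(f"{self.fate} lactation requires a calving interval")


_CURVE_CACHE: dict[str, dict] = {}


def load_curve_table() -> dict[tuple[str, str], LactationParams]:
    """Load the 8 fitted lactation-curve rows shipped with the package.

    Returns a dict keyed by ``(parity_class, dp_category)``.  Parity class 2
    has a single no-DP curve; :func:`get_params` maps both no-DP categories
    onto it.
    """
    if "table" not in _CURVE_CACHE:
        with resources.files("drysim.data").joinpath("lactation_curves.csv").open() as fh:
            df = pd.read_csv(fh)
        table = {
            (r.parity_class if isinstance(r.parity_class, str) else str(r.parity_class),
             r.dp_category): LactationParams(
                parity_class=str(r.parity_class),
                dp_category=r.dp_category,
                ady=r.ady, a=r.a, b=r.b, c=r.c, k=r.k,
                fat_pct=r.fat_pct, protein_pct=r.protein_pct,
                lactose_pct=r.lactose_pct,
            )
            for r in df.itertuples()
        }
        if len(table) != 8:
            raise ValueError("expected exactly 8 lactation-curve rows")
        _CURVE_CACHE["table"] = table
    return _CURVE_CACHE["table"]


def parity_class(parity: int) -> str:
    """Map a parity number onto the curve parity classes 1 / 2 / >2."""
    if parity < 1:
        raise ValueError("parity must be >= 1")
    return "1" if parity == 1 else ("2" if parity == 2 else "gt2")


def dp_category(parity: int, strategy_dp: int, prev_dp: Optional[int]) -> str:
    """Resolve the DP category of a lactation.

    Parameters
    ----------
    parity:
        Parity of the lactation (1 = heifer).
    strategy_dp:
        Length (days) of the dry period immediately preceding this lactation:
        56, 28 or 0.
    prev_dp:
        Length of the dry period preceding the *previous* lactation, used to
        split the no-DP curves into first-time (after a conventional DP) and
        repeated (after no DP) omission.  Ignored unless ``strategy_dp`` is 0.
    """
    if strategy_dp not in (56, 28, 0):
        raise ValueError(f"invalid dry-period length {strategy_dp!r}")
    if parity == 1:
        return "heifer"
    if strategy_dp == 56:
        return "std56"
    if strategy_dp == 28:
        return "short28"
    return "no0_after0" if prev_dp == 0 else "no0_after56"


def get_params(table: dict, parity: int, category: str) -> LactationParams:
    """Look up curve parameters, folding parity-2 no-DP categories together."""
    pclass = parity_class(parity)
    if pclass == "1":
        return table[("1", "heifer")]
    if pclass == "2" and category == "no0_after0":
        category = "no0_after56"  # parity 2 has a single no-DP curve
    return table[(pclass, category)]


# ---------------------------------------------------------------------------
# curve evaluation
# ---------------------------------------------------------------------------

def daily_milk(params: LactationParams, rpl: float, dim):
    """Daily milk yield (kg/day) at ``dim`` days in milk.

    May become negative late in lactation; callers clamp through the dry-off
    logic rather than here.
    """
    dim = np.asarray(dim, dtype=float)
    if np.any(dim < 0):
        raise ValueError("days in milk must be >= 0")
    out = params.a + params.b * dim + params.c * np.exp(-params.k * dim) + rpl * params.ady
    return float(out) if out.ndim == 0 else out


def milk_antiderivative(params: LactationParams, rpl: float, t):
    """Closed-form antiderivative of the daily-milk function at time ``t``."""
    t = np.asarray(t, dtype=float)
    out = (
        (params.a + rpl * params.ady) * t
        + 0.5 * params.b * t * t
        - (params.c / params.k) * np.exp(-params.k * t)
    )
    return float(out) if out.ndim == 0 else out


def cumulative_milk(params: LactationParams, rpl: float, t0: float, t1: float) -> float:
    """Milk (kg) produced between DIM ``t0`` and ``t1`` (exact closed form)."""
    if t1 < t0:
        raise ValueError("t1 must be >= t0")
    if t0 < 0:
        raise ValueError("t0 must be >= 0")
    return milk_antiderivative(params, rpl, t1) - milk_antiderivative(params, rpl, t0)


def fpcm(milk: float, fat_pct: float, protein_pct: float):
    """Fat-and-protein-corrected milk (kg): milk * (0.337 + 0.116 fat% + 0.06 protein%)."""
    return milk * (_FPCM_BASE + _FPCM_FAT * fat_pct + _FPCM_PROTEIN * protein_pct)


def fpcm_factor(params: LactationParams) -> float:
    """FPCM per kg of milk for the composition of one curve category."""
    return _FPCM_BASE + _FPCM_FAT * params.fat_pct + _FPCM_PROTEIN * params.protein_pct


def peak_dim(params: LactationParams) -> float:
    """DIM of the lactation peak (independent of RPL, which only shifts level)."""
    return math.log(params.c * params.k / params.b) / params.k


def _descending_crossing(params: LactationParams, rpl: float, level: float) -> Optional[float]:
    """Smallest DIM past the peak where daily milk drops to ``level``.

    Newton iteration started from the linear part of the curve (the
    exponential term is negligible there); falls back to bisection when the
    start is too close to the peak.  Returns ``None`` if the curve stays
    above ``level`` until :data:`MAX_DIM`, and the peak DIM when the curve
    never exceeds ``level`` at all (degenerate low-RPL cow).
    """
    pk = peak_dim(params)
    a_eff = params.a + rpl * params.ady
    f = lambda d: a_eff + params.b * d + params.c * math.exp(-params.k * d) - level
    if f(pk) <= 0.0:
        return pk  # sentinel: curve never exceeds level
    if f(MAX_DIM) > 0.0:
        return None
    d = (a_eff - level) / (-params.b)  # exp term dropped
    if d < pk + 5.0:
        lo, hi = pk, MAX_DIM
        while hi - lo > 0.25:
            mid = 0.5 * (lo + hi)
            if f(mid) > 0.0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)
    for _ in range(4):  # Newton; converges to << 0.5 day
        d -= f(d) / (params.b - params.c * params.k * math.exp(-params.k * d))
    return min(max(d, pk), MAX_DIM)


def spontaneous_dryoff_day(
    params: LactationParams, rpl: float, planned_dryoff_dim: float
) -> Optional[float]:
    """DIM at which milk reaches 0 kg, if before the planned dry-off.

    With an omitted DP the planned dry-off coincides with the next calving;
    low-producing cows can run dry spontaneously before that, which is the
    only source of dry days under the no-DP strategy.
    """
    if planned_dryoff_dim <= 0:
        raise ValueError("planned dry-off must be a positive DIM")
    crossing = _descending_crossing(params, rpl, 0.0)
    if crossing is not None and crossing < planned_dryoff_dim:
        return crossing
    return None


def fertility_cull_day(
    params: LactationParams, rpl: float, threshold: float = FERTILITY_CULL_THRESHOLD
) -> float:
    """DIM at which a non-conceiving cow is culled (milk < ``threshold`` kg/day)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    crossing = _descending_crossing(params, rpl, threshold)
    if crossing is None:
        return MAX_DIM
    pk = peak_dim(params)
    if crossing <= pk + 1e-9 and daily_milk(params, rpl, pk) < threshold:
        warnings.warn(
            "lactation curve never exceeds the culling threshold; "
            "culling at the lactation peak",
            stacklevel=2,
        )
        return pk
    return crossing


def effective_lactation_yield(total_fpcm: float, window_days: float) -> float:
    """FPCM per day over a lactation's effective window.

    The window runs from 60 days before calving until 60 days before the next
    calving (healthy cows) or until culling.  Pre-calving milk produced in
    the tail of the previous lactation is part of ``total_fpcm``; cows with
    a shortened or omitted DP bank considerable milk there, which is why
    culling hurts conventional-DP herds more.
    """
    if window_days <= 0:
        raise ValueError("effective lactation window must have positive length")
    return total_fpcm / window_days
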