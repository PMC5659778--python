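# drysim — model description and methods

This document specifies the simulation model implemented in `drysim`: its
state variables, stochastic processes, parameterisation, numerical choices,
and limitations. All parameter values quoted here ship with the package in
`src/drysim/data/` and are the single source used at runtime.

## 1. Overview

`drysim` is a dynamic, stochastic, individual-based model of a 100-cow dairy
herd used to compare three dry-period (DP) strategies — the conventional
56-day DP, a shortened 28-day DP, and an omitted DP (0 days) — on:

1. herd milk production, calvings, cullings and dry days per year;
2. the partial cash flow (milk, calf and cull-cow revenues minus feed and
   young-stock costs); and
3. life-cycle greenhouse-gas (GHG) emissions per t fat-and-protein-corrected
   milk (FPCM).

The experimental protocol runs every herd for 5 warm-up years under the
56-day DP (erasing initialisation detail), records the 6th year as the
baseline ("year 0"), then applies the herd's assigned strategy for 5 more
years ("years 1–5"). The reference experiment simulates 50 independent herds
per strategy; between-herd variation is the reported measure of Monte-Carlo
uncertainty. Calendar years are 365 days; no leap days.

## 2. Herd and cow places

A herd is 100 *cow places*, each always occupied by exactly one cow, so herd
size is constant by construction. The initial herd has a fixed parity mix of
30/21/15/10/24 cows in parities 1, 2, 3, 4 and >4 (">4" instantiated as
parity 5), all calving on day 0 after a conventional DP. After warm-up the
simulated parity composition equilibrates near that mix (checked in the test
suite).

Each cow carries a relative production level (RPL) drawn once from
N(0, 0.1) when she enters the herd and kept for all her lactations; it scales
her milk level by `RPL × ADY` (see §3).

## 3. Lactation curves

Daily milk yield at `t` days in milk (DIM) follows a Wilmink curve

    MP(t) = a + b·t + c·e^(−k·t) + RPL·ADY

with `c = −16.1` and `k = 0.06` for all categories, and `a`, `b`, `ADY`
(average daily yield over 305 d) fitted per parity class × DP category
(`data/lactation_curves.csv`):

| parity class | DP category | ADY | a | b | fat % | protein % | lactose % |
|---|---|---|---|---|---|---|---|
| 1 | heifer (no prior DP) | 23.9 | 31.6 | −0.0447 | 4.48 | 3.55 | 4.62 |
| 2 | 56 d | 28.9 | 40.6 | −0.0708 | 4.50 | 3.59 | 4.53 |
| 2 | 28 d | 25.9 | 37.6 | −0.0708 | 4.64 | 3.75 | 4.55 |
| 2 | 0 d | 22.1 | 33.8 | −0.0708 | 4.81 | 3.93 | 4.51 |
| >2 | 56 d | 30.5 | 44.1 | −0.0835 | 4.51 | 3.51 | 4.48 |
| >2 | 28 d | 27.7 | 41.3 | −0.0835 | 4.49 | 3.62 | 4.48 |
| >2 | 0 d, after a 56/28-d DP | 24.4 | 38.0 | −0.0835 | 4.60 | 3.71 | 4.41 |
| >2 | 0 d, repeated | 27.0 | 40.6 | −0.0835 | 4.53 | 3.62 | 4.41 |

The DP category of a lactation is the DP *preceding* it; omitted-DP curves
are split by whether the previous lactation also had no DP (milk losses
shrink on repeated omission). Parity-2 cows have a single no-DP curve.
First-parity cows always use the heifer curve.

The tabulated ADY is consistent with the curve: the test suite checks
`∫₀³⁰⁵ MP(t) dt / 305 = ADY` to < 0.05 kg/d for all 8 rows.

FPCM uses the standard correction `FPCM = milk × (0.337 + 0.116·fat% +
0.06·protein%)`; each category's milk carries its own composition, which also
feeds the milk pricing (§7) so that, e.g., the fat/protein-rich milk of
omitted-DP cows is worth more per kg.

## 4. Lactation fates, calving intervals and culling

At the start of each lactation a fate is drawn:

* **fertility culling** with probability per parity class × preceding DP
  (`data/calving_intervals.csv`): parity 1: 0.080; parity 2: 0.075 / 0.052 /
  0.039 for DP 56/28/0; parity >2: 0.078 / 0.074 / 0.037. The cow never
  conceives and is removed when her daily milk drops below 15 kg/d (found by
  root-finding on the descending limb of her curve, capped at 600 DIM).
* **general culling** with probability 0.22, constant across parities and
  DPs (total culling ≈ 30 %/yr at DP 56). The cull day is
  `round(CI × Beta(1.3, 5))` (median fraction 0.17), at least day 1.
* **healthy** otherwise: the cow completes the lactation and calves again
  after her calving interval (CI).

Healthy and general-culled lactations draw a CI from a parity class × DP
distribution with printed quantiles (median, P5, P95), truncated at 518 d
(insemination stops ~34 weeks after calving):

| parity class | DP | median | P5 | P95 |
|---|---|---|---|---|
| 1 | (any) | 374 | 327 | 477 |
| 2 | 56 | 381 | 330 | 487 |
| 2 | 28 | 365 | 325 | 482 |
| 2 | 0 | 359 | 316 | 464 |
| >2 | 56 | 385 | 333 | 489 |
| >2 | 28 | 378 | 328 | 480 |
| >2 | 0 | 370 | 321 | 473 |

Each cell is modelled as a **shifted (3-parameter) log-normal** truncated at
518 d; the shift, log-mean and log-SD are fitted by least squares so the
truncated distribution's quantiles reproduce all three printed quantiles
(residuals < 0.1 d; a guard raises if > 2 d). A 2-parameter log-normal
cannot match these triples (the printed P95s are less right-skewed than a
log-normal through the median and P5 allows). Sampling inverts the truncated
CDF, which is equivalent to resampling draws above the cap.

A culled cow's place is taken the next day by a first-parity heifer with a
fresh RPL whose entry calving starts a new lactation; every lactation start
counts one calf born.

## 5. Dry-off rules and the strategy switch

A healthy cow is dried off `DP` days before her next calving. The DP that
ends a lactation follows the strategy in force on the day her *conventional*
(56-d) dry-off would occur: until the switch day that is 56 days; from the
switch day it is the herd's assigned strategy. Hence a cow already dry on
the switch day finishes her 56-d DP, while a cow still milking whose
conventional dry-off falls after the switch milks on to `CI − 28` (DP28) or
straight to the next calving (DP0). This produces the characteristic
transition: year 1 gains tail milk from prolonged lactations, year 2 takes
the full yield penalty of the first post-switch lactations.

Under an omitted DP a cow may still *run dry spontaneously* if her curve
reaches 0 kg/d before the next calving; this is the only source of dry days
under DP0 (≈ 1 d/cow/yr at equilibrium).

## 6. Energy requirements and feed

Net energy (NE) is computed per occupied cow-day with the Dutch VEM system
(1,000 VEM = 6.9 MJ NE):

* maintenance: `42.4 VEM × BW^0.75`, +6.7 % on grazing days;
* milk: `442 VEM per kg FPCM` produced that day;
* growth: 660 VEM/d (parity 1) and 330 VEM/d (parity 2);
* gestation: 450/850/1,500/2,700 VEM/d in the 4th/3rd/2nd/last 30-day month
  before the next calving (not for non-conceiving cows).

Body weight runs linearly from 540 kg (first calving) via 595 kg (second) to
a constant 650 kg (third on), interpolated over the cow's CI.

The year has a contiguous 170-day summer and 195 days of winter. Lactating
cows graze in summer (maintenance uplift; 1/3 of excretion deposited on
pasture); dry cows stay indoors. NE divides by the ration's energy density —
6.5 MJ/kg DM (winter: grass silage, maize silage, wet by-products,
concentrates) and 6.8 MJ/kg DM (summer: ~39 % fresh grass) — to give feed
dry-matter intake per season (`data/rations.csv`; an optional
reduced-concentrate ration is included).

Nitrogen excretion is the balance `N_in − N_milk − N_growth − N_gestation`
with feed N from composition-weighted crude protein (g CP/kg DM per
ingredient, `data/emission_factors.yaml`), milk N = protein/6.38, growth N =
26.7 g/kg gain, and a gestation N schedule mirroring the energy tiers.
Manure volatile solids are `DM × (1 − 0.77) × (1 − 0.08)` (digestibility
0.77, ash 0.08).

## 7. Partial cash flow

Per herd-year (`data/prices.yaml`, EUR):

* **milk revenue**: each curve category's milk priced on its own solids at
  576.48 / 288.25 / 57.65 € per 100 kg protein/fat/lactose (≈ €35.32 per
  100 kg at average composition — asserted to the cent in the tests);
* **calf revenue**: half of calves are female; 113.4 % of the culled-cow
  count of female calves is retained for rearing; 7 % of surplus calves die;
  the rest sell at €51 (female) / €109 (male);
* **cull-cow revenue**: live weight × 60 % dressing × €2.32/kg meat
  (= €904.80 at 650 kg);
* **feed cost**: seasonal DM × €202.30 (winter) / €167.80 (summer) per t DM
  (reduced-concentrate ration: €202.00 / €167.00);
* **young-stock cost**: €969 per replacement heifer entering.

The decomposition `cash = milk + calves + culls − feed − rearing` is exact
(tested to machine precision). Veterinary costs, labour, insemination and
discounting are outside the partial budget's scope.

## 8. Greenhouse-gas accounting

Per herd-year, in kg CO2e (GWP-100: CO2 1, biogenic CH4 28, N2O 265):

* **feed production + enteric fermentation**: per t DM and season, from the
  ration table (average ration: 468+574 winter, 470+585 summer);
* **manure**: CH4 = VS × 0.027336 (stable slurry, from B0 0.24 m³/kg VS ×
  0.67 kg/m³ × MCF 17 %) or × 0.001608 (pasture, MCF 1 %); direct N2O-N =
  0.2 % (stable) / 2 % (pasture) of excreted N; indirect N2O-N via NH3/NOx
  volatilisation (14 % stable / 7 % pasture, EF 1 %) and nitrate leaching
  (13 % pasture, EF 0.75 %); N2O-N × 44/28;
* **young-stock rearing**: 4,905 kg CO2e per replacement heifer entering;
* **meat credit** (system expansion): −2,795 kg CO2e per culled cow. A
  per-surplus-calf veal credit is configurable and ships as 0.

Intensity = total ÷ herd FPCM tonnes. The component decomposition is exact
(tested). With these factors the 56-day reference strategy computes to
≈ 949 kg CO2e/t FPCM; switching to a 28- or 0-day DP raises intensity by
≈ +7 kg CO2e/t FPCM (5-year mean, 50 herds, default seed), because lower
milk and the extra maintenance of longer-milking, lower-yield cows outweigh
the avoided dry-cow days and cullings.

## 9. Sensitivity analysis

`experiments.run_sensitivity` varies, relative to the DP56 reference at 22 %
general culling:

* general culling probability: 0.12 / 0.17 / 0.27 (all three strategies);
* milk penalty of short/no DP: ±1 and ±2 kg/d on `a` and `ADY` of the
  shortened/omitted-DP curves only;
* `equal_ci`: all categories use the conventional-DP CI distributions;
* `equal_fertility_culling`: all categories use conventional-DP fertility
  culling probabilities.

Scenario herds reuse the reference herds' per-herd seeds (common random
numbers), and deltas are taken against the same-year DP56 reference mean.

## 10. Numerical and software choices

* **Exact milk integration.** Yearly milk is the closed-form antiderivative
  of the Wilmink curve evaluated per day
  (`F(t) = (a+RPL·ADY)t + b t²/2 − (c/k)e^(−kt)`), so totals are exactly
  additive no matter how lactations split across calendar years (tested to
  1e−9 relative).
* **Event-level simulation, day-level accounting.** Lactations are simulated
  as events (fast Python loop, ~165k events per reference run); the yearly
  ledger then expands events to cow-days in vectorised NumPy. A brute-force
  per-day Python oracle reproduces the vectorised ledger to 1e−9 in the test
  suite.
* **Reproducibility.** Herd `i` uses `SeedSequence(master, spawn_key=(i,))`
  with the PCG64 generator: runs are bit-reproducible for a given seed and
  adding herds or strategies never reshuffles existing draws.
* **Root finding.** Fertility-cull and spontaneous dry-off days use Newton
  iteration on the descending limb (bisection fallback near the peak),
  validated against `scipy.optimize.brentq` in the tests.
* Standard numerics come from `numpy`/`scipy`; tabular output uses
  `pandas`; configuration and the CLI use `pyyaml` and `click`.

## 11. Limitations

* Cow places are never empty and herd size is fixed; replacement supply is
  assumed unlimited and instantaneous.
* Milk yield, CI and fertility-culling differences are the only modelled
  responses to DP length; health effects (mastitis, metabolic disease) enter
  only implicitly through them.
* Prices and emission factors are fixed over the 11 simulated years; no
  discounting, inflation, or milk-quota/price dynamics.
* The summer block is a fixed 170-day window; calving is not seasonal.
* Simulated per-cow NE (~119 MJ/d winter, ~121 MJ/d summer at DP 56) sits a
  few MJ below some published herd averages because the model uses the
  standard VEM milk coefficient (442 VEM/kg FPCM) without a feed-waste or
  ration-imbalance margin; all coefficients are exposed via
  `EnergyConstants` for recalibration.
* Fertility culling removes a cow at a deterministic milk threshold; in
  practice the decision also weighs pregnancy diagnostics, season and price.
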