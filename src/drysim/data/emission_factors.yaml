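# Life-cycle emission factors for the milk greenhouse-gas accounting.
#
# Feed-production and enteric factors travel with the ration table
# (rations.csv, kg CO2e per t DM).  The factors below cover manure
# management, young-stock rearing and the meat system-expansion credits.
#
# Manure factors follow Dutch national-inventory / IPCC 2006 conventions for
# dairy cattle with liquid slurry storage (cool climate):
#   CH4 (kg per kg volatile solids) = B0 (0.24 m3 CH4/kg VS) x 0.67 kg/m3 x MCF,
#   with MCF 17% for slurry stored in the stable and 1% on pasture.
#   Direct N2O-N fractions: 0.002 of N stored as slurry, 0.02 of N on pasture.
#   Indirect N2O from volatilised N (EF4 = 0.010) and leached N (EF5 = 0.0075).
rearing_kg_co2e_per_heifer: 4905.0
meat_credit_kg_co2e_per_cull_cow: 2795.0
# Net credit for a surplus calf leaving to the veal chain (rearing emissions
# minus substituted meat); the source chain parameters are external, so the
# default is a neutral 0 and the value is swappable here.
veal_credit_kg_co2e_per_surplus_calf: 0.0
manure:
  ch4_kg_per_kg_vs_stable: 0.027336   # 0.24 * 0.67 * 0.17
  ch4_kg_per_kg_vs_pasture: 0.001608  # 0.24 * 0.67 * 0.01
  n2o_n_frac_stable: 0.002
  n2o_n_frac_pasture: 0.02
  frac_n_volatilized_stable: 0.14
  frac_n_volatilized_pasture: 0.07
  frac_n_leached_stable: 0.0
  frac_n_leached_pasture: 0.13
  ef4_volatilization: 0.010
  ef5_leaching: 0.0075
# Share of excretion deposited on pasture by a grazing (lactating, summer)
# cow: 8 h grazing per day -> 1/3 on pasture, 2/3 in the stable.
pasture_excretion_share: 0.3333333333333333
# Volatile solids excretion: feed DM x (1 - digestibility) x (1 - ash).
digestibility: 0.77
ash_fraction: 0.08
# Crude protein (g per kg DM) per ration ingredient, used for N intake;
# standard Dutch feed-table values.
crude_protein_g_per_kg_dm:
  grass: 210.0
  grass_silage: 170.0
  maize_silage: 75.0
  wet_byproducts: 200.0
  concentrate: 180.0
  protein_concentrate: 320.0
# N retention coefficients: body N per kg weight gain and per-day gestation
# retention over the last four months of pregnancy (kg N/day).
n_per_kg_gain: 0.0267
n_gestation_kg_per_day: [0.0015, 0.003, 0.006, 0.010]
gwp:
  co2: 1.0
  ch4_biogenic: 28.0
  ch4_fossil: 30.0
  n2o: 265.0
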