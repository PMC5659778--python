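# Costs and revenues used for the partial cash-flow calculation.
# Milk solids are paid per 100 kg of each solid (protein:fat:lactose value 10:5:1);
# with average Dutch solids (3.47% protein, 4.41% fat, 4.51% lactose) this comes
# to 35.32 EUR per 100 kg milk.
milk_solids_eur_per_100kg:
  protein: 576.48
  fat: 288.25
  lactose: 57.65
calf_eur_per_head:
  female: 51.00
  male: 109.00
cull_meat_eur_per_kg: 2.32
dressing_fraction: 0.60
replacement_heifer_eur: 969.00
feed_eur_per_t_dm:
  average:
    winter: 202.30
    summer: 167.80
  reduced_concentrate:
    winter: 202.00
    summer: 167.00
# Female calves retained for replacement = 113.4% of culled cows (13.4%
# mortality during rearing); 7% of surplus calves die on farm before sale.
replacement_rearing_ratio: 1.134
surplus_calf_mortality: 0.07
sex_ratio_female: 0.5
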