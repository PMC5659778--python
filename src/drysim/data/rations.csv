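ration,season,grass,grass_silage,maize_silage,wet_byproducts,concentrate,protein_concentrate,ne_mj_per_kg_dm,ghg_feed_production,ghg_enteric
average,winter,0.0,55.1,13.7,4.8,19.7,6.8,6.5,468,574
average,summer,39.0,25.2,10.9,3.8,21.1,0.0,6.8,470,585
reduced_concentrate,winter,0.0,55.9,13.9,4.9,17.4,7.9,6.5,463,572
reduced_concentrate,summer,39.5,25.6,11.0,3.8,19.6,0.5,6.8,466,584
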