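variable,vial_size,mean,min,max
price_per_dose_usd,10,0.246,,
price_per_dose_usd,5,0.450,0.405,0.495
price_per_dose_usd,2,,,
price_per_dose_usd,1,0.943,,
empty_vial_mass_g,10,3.522,3.169,3.874
empty_vial_mass_g,5,2.517,2.265,2.768
empty_vial_mass_g,2,,,
empty_vial_mass_g,1,1.713,1.542,1.885
reconstitution_syringe_mass_g,,6.625,5.967,7.293
injection_syringe_mass_g,,6.625,5.967,7.293
waste_disposal_cost_per_kg_usd,,6.850,2.066,10.830
waste_disposal_cost_per_g_usd,,0.0069,0.0021,0.0108
injection_syringe_cost_usd,,0.070,,
reconstitution_syringe_cost_usd,,0.060,,
discount_rate_per_year,,0.03,,
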