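antigen_id,schedule,schedule_ages_weeks,doses_per_person,doses_per_vial,packed_volume_per_dose_cm3,diluent_volume_per_dose_cm3,route,storage_class,formulation,open_vial_lifetime_days,price_per_dose_usd,shelf_life_days,in_schedule
BCG,Birth,0,1,20,1.2,0.7,intradermal,refrigerator,lyophilized,,,730,1
DTP-HepB-Hib,"6, 10, 14 weeks",6;10;14,3,1,16.8,0.0,intramuscular,refrigerator,liquid,28,,730,1
YF,9 months,39,1,10,2.5,6.0,subcutaneous,refrigerator,lyophilized,,,730,1
OPV,"Birth, 6, 10, 14 weeks",0;6;10;14,4,20,1.0,0.0,oral,freezer,liquid,28,,730,1
TT,"1st contact, 4 weeks, 6 months, 1 year",0;4;26;52;104,5,10,3.0,0.0,intramuscular,refrigerator,liquid,28,,730,1
M,9 months,39,1,10,2.6,0.5,subcutaneous,refrigerator,lyophilized,,0.246,730,1
M,9 months,39,1,5,5.2,0.5,subcutaneous,refrigerator,lyophilized,,0.450,730,0
M,9 months,39,1,2,13.1,0.5,subcutaneous,refrigerator,lyophilized,,,730,0
M,9 months,39,1,1,26.1,0.5,subcutaneous,refrigerator,lyophilized,,0.943,730,0
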