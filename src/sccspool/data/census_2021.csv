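# 2021 Canadian census population counts used by the surveillance scenarios.
# Strata: "total" = whole population; "18-39" = adults aged 18-39.
# Territory totals (Yukon, Northwest Territories, Nunavut) are derived from
# the 2021 census and are required to sum to 118,160, the national total
# minus the ten provincial totals.
jurisdiction,stratum,population
Ontario,total,14223942
Quebec,total,8501833
British Columbia,total,5000879
Alberta,total,4262635
Manitoba,total,1342153
Saskatchewan,total,1132505
Nova Scotia,total,969383
New Brunswick,total,775610
Newfoundland and Labrador,total,510550
Prince Edward Island,total,154331
Yukon,total,40232
Northwest Territories,total,41070
Nunavut,total,36858
Canada,total,36991981
Ontario,18-39,4517570
Quebec,18-39,2337880
British Columbia,18-39,1568044
Alberta,18-39,1395268
Manitoba,18-39,429186
Saskatchewan,18-39,351071
Nova Scotia,18-39,273295
New Brunswick,18-39,199309
Newfoundland and Labrador,18-39,126163
Prince Edward Island,18-39,47631
Canada,18-39,11287640
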