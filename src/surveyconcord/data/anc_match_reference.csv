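source_kind,source_name,country,geo_path,geo_level_type,year_raw,season,indicator_id,n,estimate,sd,cohort
reference,DHS,Ethiopia,Ethiopia>Amhara+Tigray+Oromia+Benishangul-Gumuz+SNNP,region,2016,unknown,anc3plus,4017,50.0,,
reference,DHS,India,India>Jharkhand,state,2005/06,unknown,anc3plus,618,35.9,,eficor
reference,DHS,India,India>Jharkhand,state,2005/06,unknown,anc3plus,320,36.6,,intrahealth
reference,DHS,India,India>Uttar Pradesh,state,2005/06,unknown,anc3plus,1307,25.6,,intrahealth
reference,DHS,Pakistan,Pakistan>Khyber Pakhtunkhwa,province,2012/13,unknown,anc3plus,1529,37.3,,
reference,DHS,Tanzania,Tanzania>Kigoma,region,2015/16,unknown,anc3plus,278,69.6,,
reference,MICS,Vietnam,Vietnam>North Central and Central Coastal area,region,2013/14,unknown,anc3plus,300,92.8,,
reference,MICS,Vietnam,Vietnam>Northern Midlands - Mountainous area,region,2013/14,unknown,anc3plus,230,72.2,,
reference,MICS,Vietnam,Vietnam>Central Highlands,region,2013/14,unknown,anc3plus,109,68.5,,
reference,MICS,Vietnam,Vietnam>North Central and Central Coastal area+Northern Midlands - Mountainous area+Central Highlands,region,2013/14,unknown,anc3plus,640,81.2,,
reference,MICS,Vietnam,Vietnam>Red River Delta,region,2013/14,unknown,anc3plus,343,92.6,,
reference,MICS,Vietnam,Vietnam>Northern Midlands - Mountainous area+Red River Delta,region,2013/14,unknown,anc3plus,573,84.4,,
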