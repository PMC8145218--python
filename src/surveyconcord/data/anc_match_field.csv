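source_kind,source_name,country,geo_path,geo_level_type,year_raw,season,indicator_id,n,estimate,sd,cohort
field,NIMS,Ethiopia,Ethiopia>Amhara+Tigray+Oromia+Benishangul-Gumuz+SNNP,region,2017/18,unknown,anc3plus,409,77.0,,
field,Eficor,India,India>Jharkhand>Pakur,district,2012,unknown,anc3plus,300,29.3,,eficor
field,IntraHealth,India,India>Jharkhand>Jharkhand,district,2010,unknown,anc3plus,5203,47.0,,intrahealth
field,IntraHealth,India,India>Uttar Pradesh>Uttar Pradesh,district,2010,unknown,anc3plus,8860,50.0,,intrahealth
field,Red Cross,Pakistan,Pakistan>Khyber Pakhtunkhwa>Battagram,district,2012,unknown,anc3plus,583,22.4,,
field,Red Cross,Pakistan,Pakistan>Khyber Pakhtunkhwa>Swat,district,2012,unknown,anc3plus,583,36.3,,
field,World Vision,Tanzania,Tanzania>Kigoma,region,2017,unknown,anc3plus,485,67.7,,
field,CARE,Vietnam,Vietnam>North Central and Central Coastal area>Nghe An>Que Phong,district,2015,unknown,anc3plus,196,77.6,,
field,CARE,Vietnam,Vietnam>Northern Midlands - Mountainous area>Cao Bang>Bao Lac,district,2015,unknown,anc3plus,198,72.2,,
field,CARE,Vietnam,Vietnam>Central Highlands>Kon Tum>Tu Mo Rong,district,2015,unknown,anc3plus,200,71.0,,
field,CARE,Vietnam,Vietnam>North Central and Central Coastal area+Northern Midlands - Mountainous area+Central Highlands>Nghe An+Cao Bang+Kon Tum,province,2015,unknown,anc3plus,594,73.6,,
field,Oxfam,Vietnam,Vietnam>Northern Midlands - Mountainous area>Hoa Binh>Da Bac+Hoa Binh,district,2014,unknown,anc3plus,472,94.7,,
field,Oxfam,Vietnam,Vietnam>Red River Delta>Hung Yen>Phu Cu+Hung Yen,district,2014,unknown,anc3plus,743,98.6,,
field,Oxfam,Vietnam,Vietnam>Northern Midlands - Mountainous area>Lang Son>Binh Gia+Lang Son,district,2014,unknown,anc3plus,767,93.9,,
field,Oxfam,Vietnam,Vietnam>Northern Midlands - Mountainous area+Red River Delta>Hoa Binh+Hung Yen+Lang Son,province,2014,unknown,anc3plus,1982,95.9,,
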