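source_kind,source_name,country,geo_path,geo_level_type,year_raw,season,indicator_id,n,estimate,sd,cohort
reference,DHS,Zambia,Zambia>Central,province,2013/14,unknown,anc3plus,789,89.2,,
reference,DHS,Zambia,Zambia>Copperbelt,province,2013/14,unknown,anc3plus,853,91.3,,
reference,DHS,Zambia,Zambia>Eastern,province,2013/14,unknown,anc3plus,1136,89.1,,
reference,DHS,Zambia,Zambia>Luapula,province,2013/14,unknown,anc3plus,988,88.2,,
reference,DHS,Zambia,Zambia>Lusaka,province,2013/14,unknown,anc3plus,904,88.5,,
reference,DHS,Zambia,Zambia>Muchinga,province,2013/14,unknown,anc3plus,850,86.7,,
reference,DHS,Zambia,Zambia>North Western,province,2013/14,unknown,anc3plus,927,86.1,,
reference,DHS,Zambia,Zambia>Northern,province,2013/14,unknown,anc3plus,981,85.4,,
reference,DHS,Zambia,Zambia>Southern,province,2013/14,unknown,anc3plus,1036,89.9,,
reference,DHS,Zambia,Zambia>Western,province,2013/14,unknown,anc3plus,793,85.2,,
reference,DHS,Zambia,Zambia,country,2013/14,unknown,anc3plus,9257,88.5,,
reference,DHS,Zambia,Zambia>Central,province,2018,unknown,anc3plus,746,89.0,,
reference,DHS,Zambia,Zambia>Copperbelt,province,2018,unknown,anc3plus,730,91.4,,
reference,DHS,Zambia,Zambia>Eastern,province,2018,unknown,anc3plus,875,93.6,,
reference,DHS,Zambia,Zambia>Luapula,province,2018,unknown,anc3plus,817,91.9,,
reference,DHS,Zambia,Zambia>Lusaka,province,2018,unknown,anc3plus,818,89.3,,
reference,DHS,Zambia,Zambia>Muchinga,province,2018,unknown,anc3plus,661,91.2,,
reference,DHS,Zambia,Zambia>North Western,province,2018,unknown,anc3plus,608,92.6,,
reference,DHS,Zambia,Zambia>Northern,province,2018,unknown,anc3plus,692,90.6,,
reference,DHS,Zambia,Zambia>Southern,province,2018,unknown,anc3plus,746,94.5,,
reference,DHS,Zambia,Zambia>Western,province,2018,unknown,anc3plus,612,90.4,,
reference,DHS,Zambia,Zambia,country,2018,unknown,anc3plus,7305,91.5,,
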