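indicator_id,subgroup_id,group_id
anc3plus,Woman received antenatal care (ANC),Maternal health
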