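category,sampled,duplicates,unverifiable,accepted
renal_insufficiency,27,0,5,16
qtc_prolongation,66,0,3,48
restricted_indication_dosing,66,0,6,44
ddi_override,141,46,11,81
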