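category,sampled,duplicates,unverifiable,accepted
renal_insufficiency,61,10,6,31
qtc_prolongation,78,4,11,34
restricted_indication_dosing,51,3,5,21
ddi_override,110,25,7,43
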