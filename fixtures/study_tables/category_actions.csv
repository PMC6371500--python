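category,checked,notes,notes_plus_phone
renal_insufficiency,9381,444,81
qtc_prolongation,4223,608,139
restricted_indication_dosing,5276,448,142
ddi_override,18902,939,259
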