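quantity,count
alerts_checked,39481
alerts_with_sequential,92050
four_category_checked,37782
notes,2568
notes_with_sequential,24943
phone_calls,637
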