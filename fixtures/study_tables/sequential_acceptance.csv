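quantity,count
actions,341
iv_stopped,64
not_accepted,165
switched,112
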