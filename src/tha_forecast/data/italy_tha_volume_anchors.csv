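year,count
2001,68270
2023,122777
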