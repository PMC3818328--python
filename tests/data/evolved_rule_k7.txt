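k=7
11111111111111111111111011101110111111111110101011111000110000001110111010100000101100000000000011101000000000000000000000000000
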