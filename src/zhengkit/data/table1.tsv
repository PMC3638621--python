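dataset	positive	negative	total	ratio	features
Wind-phlegm collateral obstruction syndrome	120	46	166	2.61 : 1	102
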