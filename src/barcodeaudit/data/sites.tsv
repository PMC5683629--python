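locality	n_specimens	n_coi	n_16s
LMR study site (Season 1)	79	79	79
LMR study site (Season 2)	97	93	95
Gabon (Estuaire)	33	31	33
Gabon (Ogooue-Maritime)	57	56	57
Republic of Congo (Kouilou)	7	7	7
Republic of Congo (Lekoumou)	123	117	116
Republic of Congo (Likouala)	73	72	70
Republic of Congo (Pool)	71	69	71
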