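genus	dry_field	dry_barcode	wet_field	wet_barcode	combined_field	combined_barcode
Alexteroon	0	0	1	0	1	0
Amietophrynus	1	1	0	0	1	1
Amnirana	0	0	1	1	1	1
Arthroleptis	8	0	5	6	10	6
Cardioglossa	1	0	0	0	1	0
Hemisus	1	1	0	0	1	1
Hoplobatrachus	1	1	0	0	1	1
Hyperolius	6	3	7	6	10	6
Leptopelis	1	1	2	2	2	2
Nectophryne	0	0	2	1	2	1
Phrynobatrachus	8	2	2	3	8	3
Ptychadena	7	4	3	3	8	4
Xenopus	1	1	1	1	2	2
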