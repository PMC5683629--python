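family	species	lmr	go	rc	bin	abgd_group	n_no_coi
Dermophiidae	Geotrypetes seraphini	0	0	1	ACM4617	85	0
Arthroleptidae	Arthroleptis adelphus	0	0	1	ACM4198	2	0
Arthroleptidae	Arthroleptis adelphus	7	0	0	ACM4199	1	0
Arthroleptidae	Arthroleptis perreti	1	0	0	ACM4527	4	0
Arthroleptidae	Arthroleptis cf. poecilonotus	2	0	9	ACM4055	3	0
Arthroleptidae	Arthroleptis sylvaticus	2	0	10	ACM4448	5	0
Arthroleptidae	Arthroleptis taeniatus	5	0	0	ACM4581	8	0
Arthroleptidae	Arthroleptis sp. A	3	0	0	ACM4312	7	0
Arthroleptidae	Arthroleptis sp. B	0	0	3	ACM4462	6	0
Arthroleptidae	Astylosternus batesi	0	0	6	ACM4639	53	0
Arthroleptidae	Cardioglossa leucomystax	0	0	3	ACM4070	11	0
Arthroleptidae	Cardioglossa gracilis	0	0	1	ACM4413	9	0
Arthroleptidae	Cardioglossa gratiosa	0	0	1	ACM4021	10	0
Arthroleptidae	Leptopelis aubryi	8	5	3	ACM4513	12	1
Arthroleptidae	Leptopelis aubryioides	0	0	2	ACM4562	18	0
Arthroleptidae	Leptopelis boulengeri	0	0	1	ACM4141	15	0
Arthroleptidae	Leptopelis sp. A	0	0	2	ACM4288	16	0
Arthroleptidae	Leptopelis brevirostris	1	0	0	ACM4142	13	0
Arthroleptidae	Leptopelis brevirostris	0	0	1	ACM4258	14	0
Arthroleptidae	Leptopelis cf. macrotis	0	0	1	ACM4257	19	0
Arthroleptidae	Leptopelis ocellatus	0	0	2	ACM4119	17	0
Arthroleptidae	Scotobleps gabonicus	0	0	1	ACM3974	73	0
Bufonidae	Amietophrynus camerunensis	0	0	19	ACM4516	36	3
Bufonidae	Amietophrynus funereus	0	0	1	ACM4379	39	0
Bufonidae	Amietophrynus gracilipes	0	0	18	ACM4666	38	0
Bufonidae	Amietophrynus gutturalis	0	0	5	ABX1848	37	0
Bufonidae	Amietophrynus pusilla	0	0	32	ABX1889	42	8
Bufonidae	Amietophrynus regularis	1	5	12	ACM4600	41	0
Bufonidae	Amietophrynus tuberosus	0	0	5	ACM4608	40	0
Bufonidae	Nectophryne afra	2	0	0	ACM4101	35	0
Bufonidae	Nectophryne afra	1	0	0	ACM4102	35	0
Conrauidae	Conraua crassipes	0	0	3	ACM4265	78	0
Dicroglossidae	Hoplobatrachus occipitalis	2	4	9	ABX2327	79	0
Hemisotidae	Hemisus perreti	3	1	0	ACM4439	84	0
Hemisotidae	Hemisus guieensis	0	0	4	ACM4440	83	0
Hyperoliidae	Afrixalus dorsalis	0	7	0	ACM4276	32	0
Hyperoliidae	Afrixalus dorsalis	0	1	0	ACM4277	33	0
Hyperoliidae	Afrixalus fulvovittatus	0	0	10	ACM3990	31	0
Hyperoliidae	Afrixalus osorioi	0	0	1	ACM4091	30	0
Hyperoliidae	Afrixalus osorioi	0	0	1	ACM3992	29	0
Hyperoliidae	Cryptothylax greshoffii	0	0	6	ACM4279	34	0
Hyperoliidae	Hyperolius adspersus	15	9	0	ACM4236	20	0
Hyperoliidae	Hyperolius adspersus	0	0	1	ACM3931	20	0
Hyperoliidae	Hyperolius adspersus	0	1	0	ACM4235	20	0
Hyperoliidae	Hyperolius olivaceus	0	5	0	ACM4149	22	0
Hyperoliidae	Hyperolius olivaceus	0	0	5	ACM4150	22	0
Hyperoliidae	Hyperolius olivaceus	8	7	0	ACM4237	22	0
Hyperoliidae	Hyperolius dartevellei	0	0	4	ACM4221	21	0
Hyperoliidae	Hyperolius ocellatus	1	0	0	ACM4613	24	0
Hyperoliidae	Hyperolius pardalis	0	0	1	ACM4378	26	0
Hyperoliidae	Hyperolius phantasticus	5	7	0	ACM4699	25	0
Hyperoliidae	Hyperolius platyceps	0	1	0	ACM3935	23	0
Hyperoliidae	Hyperolius platyceps	4	0	0	ACM3936	23	0
Hyperoliidae	Hyperolius tuberculatus	3	10	0	ACM4028	27	0
Hyperoliidae	Phlyctimantis leonardi	0	3	0	ACM4536	28	0
Hyperoliidae	Phlyctimantis leonardi	0	7	1	ACY0609	28	0
Phrynobatrachidae	Phrynobatrachus africanus	0	0	2	ACM4519	59	0
Phrynobatrachidae	Phrynobatrachus africanus	1	0	0	ACM4520	57	0
Phrynobatrachidae	Phrynobatrachus africanus	0	0	1	ACM4521	58	0
Phrynobatrachidae	Phrynobatrachus africanus	0	0	1	ACM4518	60	0
Phrynobatrachidae	Phrynobatrachus auritus	40	0	0	ACM3966	54	0
Phrynobatrachidae	Phrynobatrachus auritus	0	0	4	ACM3967	54	0
Phrynobatrachidae	Phrynobatrachus auritus	0	0	1	ACM4483	55	0
Phrynobatrachidae	Phrynobatrachus batesii	0	0	1	ACM3923	61	0
Phrynobatrachidae	Phrynobatrachus cf. hylaios	0	0	7	ACM4501	66	0
Phrynobatrachidae	Phrynobatrachus horsti	0	0	1	ACM3921	63	0
Phrynobatrachidae	Phrynobatrachus ruthbeateae	0	0	1	ACM3922	62	0
Phrynobatrachidae	Phrynobatrachus sp. A	21	1	0	ACM4053	56	0
Phrynobatrachidae	Phrynobatrachus sp. B	0	0	2	ACM4606	65	0
Phrynobatrachidae	Phrynobatrachus sp. C	0	0	1	ACM4544	64	0
Pipidae	Hymenochirus curtipes	0	0	5	ACM4325	74	0
Pipidae	Hymenochirus sp.	0	0	1	ACM4340	75	0
Pipidae	Xenopus andrei	1	0	2	AAH9248	67	0
Pipidae	Xenopus pygmaeus	0	0	8	AAW7585	68	0
Pipidae	Xenopus boumbaensis	0	0	1	AAH7184	69	0
Pipidae	Xenopus epitropicalis	0	0	3	AAJ6803	70	0
Pipidae	Xenopus mellotropicalis	7	4	0	AAH0940	72	0
Pipidae	Xenopus mellotropicalis	0	0	7	AAH0942	71	0
Ptychadenidae	Ptychadena mascareniensis	0	0	7	ACH6774	77	0
Ptychadenidae	Ptychadena porosissima	16	2	0	ACM4178	43	3
Ptychadenidae	Ptychadena taenioscelis	6	0	3	ACM4023	76	2
Ptychadenidae	Ptychadena uzungwensis	0	0	1	ACM4112	44	0
Ptychadenidae	Ptychadena sp. A	4	0	0	ACM4315	46	0
Ptychadenidae	Ptychadena sp. B	0	0	5	ACM4111	47	0
Ptychadenidae	Ptychadena sp. C	3	1	0	ACM4022	45	0
Ptychadenidae	Ptychadena sp. C	0	4	0	ACM4572	45	0
Pyxicephalidae	Aubria masako	0	0	3	ACM3984	82	0
Ranidae	Amnirana albolabris	4	0	0	ACM3918	48	0
Ranidae	Amnirana albolabris	0	0	1	ACM4391	50	0
Ranidae	Amnirana albolabris	0	0	9	ACM4408	49	0
Ranidae	Amnirana cf. amnicola	0	0	3	ACM4594	51	0
Ranidae	Amnirana lepus	0	0	7	ACM4529	52	0
Rhacophoridae	Chiromantis rufescens	0	0	1	ACM4211	81	0
Rhacophoridae	Chiromantis rufescens	0	5	0	ACM4212	80	1
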