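species	strain	ncbi_accession	coverage_x	gc_percent	freq_variant_branches_k41	freq_repeat_branches_k41
D. asahinai	E-12502 (TKNK40)	VNJZ00000000	28	40.74	5.988E-04	4.636E-04
D. auraria	14028-0471.01	VNJW00000000	39	40.32	4.143E-04	4.930E-04
D. cf. bakoue	Sao Tome Light	VNJL00000000	59	41.98	2.850E-03	4.005E-04
D. birchii	14028-0521.00	VNKA00000000	36	39.89	1.639E-04	2.991E-04
D. bocki	E-12901 (IR2-37)	VNJY00000000	41	40.32	1.961E-04	2.103E-04
D. bunnanda	14028-0721.00	VNKE00000000	33	40.01	5.872E-04	2.895E-04
D. burlai	14028-0781.00	VNJT00000000	45	40.51	3.317E-03	3.401E-04
D. jambulina	14028-0671.01	VNJX00000000	32	40.61	1.230E-03	2.458E-04
D. kanapiae	14028-0541.00	VNJM00000000	38	39.80	1.479E-04	1.175E-04
D. lacteicornis	E-14104 (ISGB1)	VNKF00000000	25	40.26	NA	NA
D. leontia	RGN 210-13	VNKB00000000	37	40.24	3.179E-03	2.686E-04
D. mayri	14028-0591.01	VNJN00000000	34	38.40	9.486E-04	6.182E-04
D. nikananu	14028-0601.01	VNJV00000000	40	40.36	3.686E-03	5.446E-04
D. pectinifera	14028-0731.00	VNKC00000000	22	38.05	NA	NA
D. punjabiensis	14028-0531.01 or MYS-170-D	VNJR00000000	47	39.39	2.047E-03	2.967E-04
D. rufa	E-14802 (EHO91)	VNKH00000000	29	40.55	3.982E-04	4.826E-04
D. seguyi	14028-0671.02	VNJU00000000	38	39.11	1.145E-03	4.656E-04
D. serrata	14028-0681.02	VNKD00000000	31	38.61	1.098E-03	3.301E-04
D. tani	14020-0011.00	VNJO00000000	40	40.02	1.221E-03	3.405E-04
D. triauraria	14028-0691.01	VNKG00000000	28	39.95	3.047E-03	6.126E-04
D. truncata	RGN23	VNJQ00000000	51	37.89	2.813E-04	3.785E-04
D. vulcana	14028-0711.00	VNJP00000000	29	41.70	2.531E-04	3.151E-04
D. watanabei	14028-0531.02	VNJS00000000	38	38.99	3.715E-03	2.936E-04
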