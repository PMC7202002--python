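species	est_genome_size_bp	total_scaffold_length_bp	scaffold_ng50_bp	longest_scaffold_bp	contig_ng50_bp	longest_contig_bp	total_gap_length_bp
D. kanapiae	155490160	152203088	389587	2274126	301459	2274126	205953
D. birchii	169148727	156593892	211718	1501252	164580	1183551	81207
D. truncata	190688284	167897087	95737	830117	73889	827712	375696
D. bocki	155095574	151202254	78068	785450	65314	785450	69231
D. bunnanda	181250127	151823105	76713	1142480	65403	1127760	152423
D. punjabiensis	197448094	192339030	72420	1226934	64043	1083757	153372
D. jambulina	179468675	163991206	71637	873064	61348	756687	61365
D. vulcana	209187412	187578810	65096	530507	51774	472464	116296
D. seguyi	206814592	178856532	63109	891413	54123	891413	233653
D. mayri	223398425	167807061	62249	2219437	43922	1355909	364662
D. asahinai	216977949	189050820	59266	1052132	50528	904342	75577
D. serrata	184673878	159679625	54224	1091401	43626	718797	79019
D. lacteicornis	203475870	182681050	53799	1044495	44105	766914	60537
D. pectinifera	220219034	149209000	52632	528734	41478	467725	58142
D. tani	194820185	180972673	48517	921527	44341	780901	135927
D. rufa	210769271	186167886	43287	498065	38201	498065	80447
D. watanabei	182199997	196825890	40952	1045963	36818	656929	135921
D. auraria	220036088	197420731	38365	491046	35679	491046	130216
D. cf. bakoue	219308053	187248584	28924	1045797	27520	598596	58713
D. leontia	162918854	164601511	26461	331217	23897	301031	91716
D. burlai	198129694	175666184	24417	628960	23536	628960	153793
D. nikananu	217706973	190505469	23001	626542	21180	574375	226904
D. triauraria	217036792	197369186	17513	590840	16493	576941	156570
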