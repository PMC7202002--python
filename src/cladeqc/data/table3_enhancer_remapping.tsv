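species	attempted_remappings	successful_remappings	pct_successful_remappings	reciprocal_best_hits	pct_successful_rbh
D. asahinai	3457	3450	99.8	3361	97.4
D. auraria	3457	3448	99.7	3347	97.1
D. cf. bakoue	3457	3451	99.8	3275	94.9
D. birchii	3457	3449	99.8	3385	98.1
D. bocki	3457	3449	99.8	3377	97.9
D. bunnanda	3457	3447	99.7	3359	97.4
D. burlai	3457	3450	99.8	3272	94.8
D. jambulina	3457	3450	99.8	3327	96.4
D. kanapiae	3457	3449	99.8	3406	98.8
D. kikkawai	3457	3449	99.8	3377	97.9
D. lacteicornis	3457	3451	99.8	3375	97.8
D. leontia	3457	3444	99.6	3247	94.3
D. mayri	3457	3449	99.8	3384	98.1
D. nikananu	3457	3451	99.8	3221	93.3
D. pectinifera	3457	3449	99.8	3383	98.1
D. punjabiensis	3457	3449	99.8	3266	94.7
D. rufa	3457	3452	99.9	3368	97.6
D. seguyi	3457	3444	99.6	3334	96.8
D. serrata	3457	3447	99.7	3350	97.2
D. tani	3457	3451	99.8	3301	95.7
D. triauraria	3457	3448	99.7	3258	94.5
D. truncata	3457	3449	99.8	3366	97.6
D. vulcana	3457	3448	99.7	3358	97.4
D. watanabei	3457	3449	99.8	3147	91.2
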