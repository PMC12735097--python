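name	kegg_id	species_bias	peaks
betaine	C00719	A_lixula	3.263:0.75:0.003;3.903:0.25:0.003
taurine	C00245	A_lixula	3.423:0.52:0.003;3.273:0.48:0.003
sarcosine	C00213	A_lixula	2.733:0.6:0.003;3.613:0.4:0.003
trimethylamine	C00565	A_lixula	2.883:1.0:0.003
trimethylamine N-oxide	C01104	A_lixula	3.268:1.0:0.003
carnitine	C00318	A_lixula	3.227:0.6:0.003;2.433:0.4:0.003
creatine	C00300	A_lixula	3.043:0.6:0.003;3.933:0.4:0.003
malonate	C00383	A_lixula	3.113:1.0:0.003
methylmalonate	C02170	A_lixula	1.263:0.7:0.003;3.163:0.3:0.003
uridine	C00299	A_lixula	5.913:0.5:0.003;7.883:0.5:0.003
xanthine	C00385	A_lixula	7.933:1.0:0.003
lysine	C00047	P_lividus	1.723:0.55:0.004;1.887:0.45:0.004
glycine	C00037	P_lividus	3.563:1.0:0.003
glutamine	C00064	P_lividus	2.137:0.5:0.004;2.463:0.5:0.004
formaldehyde	C00067	P_lividus	8.333:1.0:0.003
methanol	C00132	P_lividus	3.363:1.0:0.003
3-carboxypropyl-trimethylammonium		P_lividus	3.087:0.5:0.003;2.333:0.3:0.003;3.663:0.2:0.003
kynurenine	C00328	shared	7.473:0.5:0.004;7.733:0.5:0.004
fatty acids		shared	0.903:0.6:0.030;1.313:0.4:0.045
alanine	C00041	shared	1.483:1.0:0.003
lactate	C00186	shared	1.333:0.7:0.003;4.123:0.3:0.003
acetate	C00033	shared	1.923:1.0:0.003
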