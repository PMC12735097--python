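name	kegg_id
betaine	C00719
glycine betaine	C00719
trimethylglycine	C00719
sarcosine	C00213
n-methylglycine	C00213
glycine	C00037
taurine	C00245
hypotaurine	C00519
trimethylamine	C00565
tma	C00565
trimethylamine n-oxide	C01104
trimethylamine-n-oxide	C01104
tmao	C01104
carnitine	C00318
l-carnitine	C00318
creatine	C00300
malonate	C00383
malonic acid	C00383
methylmalonate	C02170
methylmalonic acid	C02170
uridine	C00299
xanthine	C00385
lysine	C00047
l-lysine	C00047
glutamine	C00064
l-glutamine	C00064
glutamate	C00025
l-glutamate	C00025
formaldehyde	C00067
methanol	C00132
kynurenine	C00328
l-kynurenine	C00328
alanine	C00041
l-alanine	C00041
lactate	C00186
lactic acid	C00186
acetate	C00033
acetic acid	C00033
serine	C00065
l-serine	C00065
threonine	C00188
l-threonine	C00188
choline	C00114
glutathione	C00051
uracil	C00106
hypoxanthine	C00262
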