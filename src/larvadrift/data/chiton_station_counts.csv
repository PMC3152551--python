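species,n_stations_new_caledonia,n_stations_vanuatu,n_stations_solomon_islands,depth_min_m,depth_max_m
Ferreiraella plana,1,8,1,560,1040
Ferreiraella xylophaga karenae,0,3,2,475,798
Leptochiton boucheti,0,6,1,504,900
Leptochiton deforgesi,0,2,7,520,977
Leptochiton habei,0,1,3,395,780
Leptochiton juvenis,0,8,0,488,800
Leptochiton n. sp. 1,0,0,3,977,1218
Leptochiton n. sp. 2,0,4,0,630,705
Leptochiton n. sp. 3,0,2,1,800,854
Leptochiton n. sp. 4,0,1,4,358,623
Leptochiton n. sp. 5,0,8,0,492,777
Leptochiton vaubani,0,3,12,236,1118
Leptochiton saitoi,15,1,2,210,1118
Leptochiton thandari,0,5,7,236,1060
Leptochiton vanbellei,1,11,5,454,1620
Leptochiton vietnamensis,2,1,4,316,1218
Nierstraszella andamanica,0,4,25,200,1060
Nierstraszella lineata,0,23,25,200,1060
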