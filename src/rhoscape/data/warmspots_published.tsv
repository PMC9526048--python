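population	arm	start	end	genes	divergent
Cold	2L	12637749	12638263	Ref2	C vs T, W vs T
Cold	2L	14821519	14822266	Intergenic	C vs T
Cold	2R	16113560	16115635	Asph	C vs W, W vs T
Cold	3R	25531288	25533084	Msi	C vs W, C vs T
Cold	3R	21649086	21650209	E2f1	C vs W, C vs T, W vs T
Cold	3R	8839809	8841479	pyd	C vs T, W vs T
Cold	X	3652923	3655159	AstA-R1	C vs T, W vs T
Cold	X	14851589	14858386	CG9521, Flo2, CG9519, CG32593, CR46391	C vs T
Cold	X	22766036	22766595	CR44997	C vs W, C vs T, W vs T
Warm	2R	19119344	19119925	5-HT1A	None
Warm	2R	25256320	25262697	Intergenic	C vs W, W vs T
Warm	2R	21485446	21486594	Sara	C vs T, W vs T
Warm	3L	1900669	1901939	Hip1	None
Warm	3L	12770565	12771232	dsb	None
Warm	3L	4534477	4537466	CG11353	C vs W
Warm	3R	18001031	18001641	Ugt303B3, Intergenic	C vs W
Warm	3R	23533398	23534851	cpo	W vs T
Warm	X	122027	123171	CR40469, Intergenic	C vs W, W vs T
Warm	X	7111274	7114094	Intergenic	C vs W, W vs T
Warm	X	9102582	9104257	CG7766, Bx42, Intergenic	W vs T
Temp	2L	11974677	11975569	Intergenic	None
Temp	2L	10013333	10015593	CG13131	None
Temp	2L	14221991	14223009	Dyrk2	None
Temp	2L	8806997	8807987	Intergenic	None
Temp	2R	25266512	25267975	Intergenic	C vs W, W vs T
Temp	2R	25267975	25274221	Intergenic	C vs W, W vs T
Temp	2R	18628050	18629052	Eip55E	None
Temp	3L	11366585	11367305	Intergenic	W vs T
Temp	3R	23163052	23163810	Intergenic	C vs T, W vs T
Temp	X	9185553	9192553	Mei-P26, Intergenic, CG12115, CG12057	C vs W, W vs T
Temp	X	12107507	12109867	CR43960	C vs T, W vs T
Temp	X	17812622	17813175	OdsH	C vs T
Temp	X	20118472	20119565	Intergenic	C vs T
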