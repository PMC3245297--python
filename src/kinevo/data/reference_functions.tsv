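function_name	abbreviation	ec_number	substrate	product	reference_protein_ids	cluster_ids	pdb_ids
L-ribulokinase	AraB	2.7.1.16	L-ribulose	L-Ribulose-5P	P94524,C4B4W2,P08204,P06188,Q9WYC0	AraB_Clust11,AraB_Clust222,AraB_Clust228,AraB_Clust94	3QDK
Erythritol kinase	EryA	2.7.1.27	Erythritol	D-Erythritol-4P	Q9ZB32	EryA_Clust85
L-fuculokinase	FucK	2.7.1.51	L-fuculose	L-Fuculose-1P	P11553,Q04I07	FucK_Clust100,FucK_Clust124
Glycerol kinase	GlpK	2.7.1.30	D-Glycerol	D-Glycerol-1P	P18157,O34154,P0A6F3,P44400,Q9WX53,O66131,Q9NJP9,Q9X1E4	GlpK_Clust115,GlpK_Clust22,GlpK_Clust265,GlpK_Clust309,GlpK_Clust76	1BO5,1BOT,1BU6,1BWF,1GLA,1GLB,1GLC,1GLD,1GLE,1GLF,1GLJ,1GLL,1R59,1XUP,2DPN,2W40,2W41,2ZF5,3D7E,3EZW,3FLC,3G25,3GE1,3H3N,3H3O,3H45,3H46
Gluconokinase	GntK	2.7.1.12	D-gluconate	6P-D-Gluconate	P12011,Q9WYS4	GntK_Clust13,GntK_Clust218	3GBT,3LL3
L-xylulose kinase	LyxK	2.7.1.53	L-xylulose	L-Xylulose-5P	P37677	LyxK_Clust48
D-ribulokinase	RbtK	2.7.1.47	D-ribulose	D-Ribulose-5P	O52716	RbtK_Clust25
Rhamnulokinase	RhaB	2.7.1.5	L-rhamnulose	L-Rhamnulose-1P	P32171,P27030,Q9X0G2	RhaB_Clust137,RhaB_Clust95	2CGJ,2CGK,2CGL,2UYT
Xylulose kinase	XylB	2.7.1.17	D-xylulose	D-Xylulose-5P	Q4JHR4,P09099,P29444,P35850,P21939,Q9P938,P27156,Q9WXX1	XylB_Clust152,XylB_Clust252,XylB_Clust29,XylB_Clust342,XylB_Clust66,XylB_Clust87,XylB_Clust9	3I8B,2ITM,2NLX,3IFR
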