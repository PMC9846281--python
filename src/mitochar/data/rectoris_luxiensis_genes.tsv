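name	cls	from	to	strand	anticodon
tRNA-Phe	tRNA	1	69	H	GAA
12S-rRNA	rRNA	70	1022	H
tRNA-Val	tRNA	1025	1096	H	TAC
16S-rRNA	rRNA	1117	2756	H
tRNA-Leu	tRNA	2781	2856	H	TAA
ND1	PCG	2858	3832	H
tRNA-Ile	tRNA	3837	3908	H	GAT
tRNA-Gln	tRNA	3907	3977	L	TTG
tRNA-Met	tRNA	3979	4047	H	CAT
ND2	PCG	4048	5094	H
tRNA-Trp	tRNA	5093	5163	H	TCA
tRNA-Ala	tRNA	5166	5234	L	TGC
tRNA-Asn	tRNA	5236	5308	L	GTT
NCR	noncoding	5311	5342	H
tRNA-Cys	tRNA	5342	5407	L	GCA
tRNA-Tyr	tRNA	5409	5479	L	GTA
COX1	PCG	5481	7031	H
tRNA-Ser	tRNA	7032	7102	L	TGA
tRNA-Asp	tRNA	7106	7177	H	GTC
COX2	PCG	7191	7881	H
tRNA-Lys	tRNA	7882	7957	H	TTT
ATP8	PCG	7959	8123	H
ATP6	PCG	8117	8800	H
COX3	PCG	8800	9585	H
tRNA-Gly	tRNA	9585	9656	H	TCC
ND3	PCG	9657	10007	H
tRNA-Arg	tRNA	10006	10075	H	TCG
ND4L	PCG	10076	10372	H
ND4	PCG	10366	11743	H
tRNA-His	tRNA	11744	11812	H	GTG
tRNA-Ser	tRNA	11813	11881	H	GCT
tRNA-Leu	tRNA	11883	11955	H	TAG
ND5	PCG	11959	13782	H
ND6	PCG	13779	14300	L
tRNA-Glu	tRNA	14301	14369	L	TTC
CYTB	PCG	14374	15514	H
tRNA-Thr	tRNA	15515	15586	H	TGT
tRNA-Pro	tRNA	15586	15655	L	TGG
D-LOOP	noncoding	15672	16592	H
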