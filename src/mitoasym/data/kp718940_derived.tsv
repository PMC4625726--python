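name	length_nt	aa_length	intergenic_gap
tRNA-Phe	69		0
12S rRNA	947		0
tRNA-Val	68		0
16S rRNA	1631		0
tRNA-Leu(1)	74		0
ND1	975	324	64
tRNA-Ile	68		6
tRNA-Gln	71		-1
tRNA-Met	69		-1
ND2	1045	348	0
tRNA-Trp	68		0
tRNA-Ala	70		-2
tRNA-Asn	73		12
tRNA-Cys	57		36
tRNA-Tyr	66		-1
COI	1557	518	1
tRNA-Ser(1)	71		3
tRNA-Asp	69		3
COII	691	230	1
tRNA-Lys	72		0
ATPase8	168	55	1
ATPase6	683	227	-10
COIII	786	261	0
tRNA-Gly	68		150
ND3	349	116	115
tRNA-Arg	69		0
ND4L	297	98	0
ND4	1390	463	-7
tRNA-His	69		0
tRNA-Ser(2)	67		0
tRNA-Leu(2)	72		-1
ND5	1845	614	0
ND6	522	173	-4
tRNA-Glu	68		0
Cytb	1149	382	4
tRNA-Thr	70		1
tRNA-Pro	70		-1
Control region	1349		0
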