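position	gene	ref	alt	ts_tv	codon_index	ref_codon	alt_codon	aa_change	effect	AUS4_alt	AUS4_total	AUS5_alt	AUS5_total	AUS7_alt	AUS7_total	self_consistent
4105	ND2	C	A	Tv	22	TCG	TAG	Ser to STOP	nonsense	2	167					1
5690	COI	T	A	Tv	75	ATT	AAA	Ile to Met	non-synonymous	2	74					0
6245	COI	C	A	Tv	260	TAC	TAA	Tyr to STOP	nonsense	2	153	3	171			1
7561	COII	G	T	Tv	131	GGC	GTC	Gly to Val	non-synonymous			2	109			1
10220	ND3	A	G	Ts	109	CAA	CAG	Gln to Gln	synonymous			2	151			1
11804	ND4	G	T	Tv	401	GGG	GGT	Gly to Gly	synonymous			2	151			1
12505	ND5	T	C	Ts	103	TCT	CCT	Ser to Pro	non-synonymous			2	191			1
12764	ND5	C	T	Ts	189	GCC	GCT	Ala to Ala	synonymous			2	108			0
12962	ND5	G	T	Tv	255	AGC	ATC	Ser to Ile	non-synonymous	2	85					1
15735	Cytb	T	C	Ts	368	TTT	CTT	Phe to Leu	non-synonymous	44	93	35	90	15	53	1
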