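name	start	end	strand	feature_type	start_codon	stop_codon
tRNA-Phe	1	69	H	tRNA
12S rRNA	70	1016	H	rRNA
tRNA-Val	1017	1084	H	tRNA
16S rRNA	1085	2715	H	rRNA
tRNA-Leu(1)	2716	2789	H	tRNA
ND1	2854	3828	H	CDS	ATG	TAA
tRNA-Ile	3835	3902	H	tRNA
tRNA-Gln	3902	3972	L	tRNA
tRNA-Met	3972	4040	H	tRNA
ND2	4041	5085	H	CDS	ATG	T--
tRNA-Trp	5086	5153	H	tRNA
tRNA-Ala	5152	5221	L	tRNA
tRNA-Asn	5234	5306	L	tRNA
tRNA-Cys	5343	5399	L	tRNA
tRNA-Tyr	5399	5464	L	tRNA
COI	5466	7022	H	CDS	GTG	TAA
tRNA-Ser(1)	7026	7096	L	tRNA
tRNA-Asp	7100	7168	H	tRNA
COII	7170	7860	H	CDS	ATG	T--
tRNA-Lys	7861	7932	H	tRNA
ATPase8	7934	8101	H	CDS	ATG	TAA
ATPase6	8092	8774	H	CDS	ATG	TA-
COIII	8775	9560	H	CDS	ATG	TAA
tRNA-Gly	9711	9778	H	tRNA
ND3	9894	10242	H	CDS	ATG	T--
tRNA-Arg	10243	10311	H	tRNA
ND4L	10312	10608	H	CDS	ATG	TAA
ND4	10602	11991	H	CDS	ATG	T--
tRNA-His	11992	12060	H	tRNA
tRNA-Ser(2)	12061	12127	H	tRNA
tRNA-Leu(2)	12127	12198	H	tRNA
ND5	12199	14043	H	CDS	ATG	TAA
ND6	14040	14561	L	CDS	ATG	TAG
tRNA-Glu	14562	14629	L	tRNA
Cytb	14634	15782	H	CDS	ATG	TAA
tRNA-Thr	15784	15853	H	tRNA
tRNA-Pro	15853	15922	L	tRNA
Control region	15923	17271	H	CR
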