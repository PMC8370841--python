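gene	rsid	category	ref	alt	star_allele
CYP2C19	rs12248560	pk_enzyme	C	T	*17
CYP2C19	rs28399504	pk_enzyme	A	G	*4
CYP2C19	rs41291556	pk_enzyme	T	C	*8
CYP2C19	rs4244285	pk_enzyme	G	A	*2
CYP2C19	rs4986893	pk_enzyme	G	A	*3
CYP2C19	rs56337013	pk_enzyme	C	T	*5
CYP2C19	rs72552267	pk_enzyme	G	A	*6
CYP2C19	rs72558186	pk_enzyme	T	A	*7
CYP2C9	rs9332239	pk_enzyme	C	T
CYP2C9	rs9332131	pk_enzyme	A	G
CYP2C9	rs7900194	pk_enzyme	G	A
CYP2C9	rs72558190	pk_enzyme	G	A
CYP2C9	rs72558189	pk_enzyme	G	T
CYP2C9	rs28371686	pk_enzyme	C	G
CYP2C9	rs1799853	pk_enzyme	C	T
CYP2C9	rs1057910	pk_enzyme	A	C
CYP2C9	rs28371685	pk_enzyme	C	T
CYP2C9	rs56165452	pk_enzyme	T	C
CYP2D6	rs59421388	pk_enzyme	G	A	*29
CYP2D6	rs5030867	pk_enzyme	A	C	*7
CYP2D6	rs5030865	pk_enzyme	G	T	*8
CYP2D6	rs5030656	pk_enzyme	A	G	*9
CYP2D6	rs5030655	pk_enzyme	T	A	*6
CYP2D6	rs3892097	pk_enzyme	C	T	*4
CYP2D6	rs35742686	pk_enzyme	T	C	*3
CYP2D6	rs28371725	pk_enzyme	G	A	*41
CYP2D6	rs5030862	pk_enzyme	G	A	*12
CYP2D6	rs16947	pk_enzyme	G	A	*2
CYP2D6	rs28371735	pk_enzyme	C	T
CYP2D6	rs1065852	pk_enzyme	G	A	*10
CYP2D6	rs5030863	pk_enzyme	G	C	*11
CYP2D6	rs28371706	pk_enzyme	C	T	*17
CYP2D6	rs72549357	pk_enzyme	C	A
CYP2B6	rs2279343	pk_enzyme	A	G
CYP2B6	rs3211371	pk_enzyme	C	T
CYP2B6	rs3745274	pk_enzyme	G	T
CYP2B6	rs8192709	pk_enzyme	C	T
CYP2B6	rs28399499	pk_enzyme	T	C
F5	rs6025	non_scored	G	A
SLCO1B1	rs4149056	transporter	T	C
VKORC1	rs9923231	non_scored	C	T
VKORC1	rs9934438	non_scored	G	A
UNASSIGNED_ROW8	rs2952768	other_pd	C	T
CYP1A2	rs2069514	pk_enzyme	G	A
CYP1A2	rs762551	pk_enzyme	A	C
CYP3A4	rs35599367	pk_enzyme	G	A
CYP3A5	rs776746	pk_enzyme	T	C
APOE	rs7412	non_scored	C	T
ABCB1	rs1045642	transporter	C	T
ABCB1	rs2032583	transporter	T	C
ADRA2A	rs1800544	receptor	C	G
ADRB1	rs1801253	receptor	G	C
ADRB1	rs1801252	receptor	A	G
ADRB2	rs1042713	receptor	G	A
BDNF	rs6265	other_pd	G	A
CACNA1C	rs1006737	other_pd	G	A
CNR1	rs806368	receptor	T	C
CNR1	rs1049353	receptor	G	A
CHRNB2	rs2072661	receptor	G	A
COMT	rs13306278	other_pd	C	T
COMT	rs165599	other_pd	G	A
COMT	rs6269	other_pd	A	G
COMT	rs4680	other_pd	G	A
COQ2	rs4693075	other_pd	C	G
DRD1	rs4532	receptor	T	C
DRD2	rs1799732	receptor	C	T
DRD2	rs1799978	receptor	A	G
DRD2	rs1800497	receptor	G	A
DRD3	rs6280	receptor	T	C
FAAH	rs324420	other_pd	C	A
FKBP5	rs4713916	other_pd	G	A
GNB3	rs5443	other_pd	C	T
GRIA1	rs1994862	receptor	A	G
GRIK4	rs1954787	receptor	T	C
HLA-B	rs2395029	non_scored	T	G
HLA-B	rs2844682	non_scored	C	T
HSPG2	rs2445142	other_pd	G	A
HTR1A	rs6295	receptor	C	G
HTR1A	rs10042486	receptor	C	T
HTR1A	rs1364043	receptor	T	G
HTR2A	rs6313	receptor	C	T
HTR2A	rs7997012	receptor	G	A
HTR2C	rs3813929	receptor	C	T
HTR2C	rs1414334	receptor	C	G
MC4R	rs17782313	receptor	T	C
MTHFR	rs1801133	other_pd	C	T
MTHFR	rs1801131	other_pd	A	C
NEDD4L	rs4149601	other_pd	G	A
OPRD1	rs529520	receptor	T	G
OPRM1	rs2952768	receptor	C	T
OPRM1	rs1799971	receptor	A	G
PRKCA	rs16960228	other_pd	G	A
POLG	rs3087374	other_pd	G	T
RGS4	rs951439	other_pd	C	T
SACM1L	rs2742417	other_pd	C	A
SLC6A4	SLC6A4_5HTTLPR	transporter	L	S
SLC6A4	rs25531	transporter	A	G
SLC6A2	rs2242446	transporter	C	T
SCN1A	rs3812718	other_pd	G	A
SCN2A	rs17183814	other_pd	G	A
TPH1	rs1800532	other_pd	G	T
TPH2	rs1487278	other_pd	C	T
UGT1A4	rs2011425	pk_enzyme	T	G
UGT2B15	rs1902023	pk_enzyme	G	T
UGT2B15	rs2952768	pk_enzyme	C	T
YEATS4	rs7297610	other_pd	C	T
ZNF804A	rs1344706	other_pd	A	C
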