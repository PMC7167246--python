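gene	chrom	gene_start	gene_end	snp	vtype	var_start	var_end	length	also_str	pclass	disorder
KDM4A	1	43650158	43705515	rs2842188	hCONDEL	43656932	43656932	466	0	INTRON
NRXN1	2	49918505	51225575	rs7557525	hCONDEL	50146470	50146470	3405	0	INTRON	Pitt Hopkins like syndrome 2
NRXN1	2	49918505	51225575	rs7557525	hCONDEL	50146625	50146625	958	0	INTRON
NRXN1	2	49918505	51225575	rs7557525	insertion	50827590	50829782	2193	0	NONCODING_EXON
AFF3	2	99545419	100142739	rs71413877	HSD	100080237	100104859	24623	0	INTRON
AFF3	2	99545419	100142739	rs13010010	hCONDEL	99554281	99554281	1250	0	INTRON
THSD7B	2	136765545	137677717	rs2558096	hCONDEL	137333693	137333693	1212	0	INTRON
ARIH2	3	48918821	48986382	rs13096357	insertion	48968205	48968380	176	1	NONCODING_EXON
STAB1	3	52495338	52524495	rs4687625	STR_expansion	52509368	52509454	87	0	NONCODING_EXON
SFMBT1	3	52903572	53046750	rs4687625	hCONDEL	52951656	52951656	4034	0	INTRON
FOXP1	3	70952817	71583993	rs11720523	hCONDEL	71460722	71460722	449	0	INTRON	Mental retardation
FOXP1	3	70952817	71583993	rs11720523	hCONDEL	71162689	71162689	1760	0	INTRON
CADM2	3	84958981	86074429	rs6770622	hCONDEL	85947229	85947229	1042	0	INTRON
PCCB	3	136250306	136337896	rs9853960	exon_gain	136326325	136326385	60	0	CDS_EXON	Propionic acidemia
TFDP2	3	141944428	142149544	rs10804681	hCONDEL	142144111	142144111	2011	0	INTRON
GRID2	4	92303622	93810157	rs1972860	hCONDEL	92649012	92649012	135	0	INTRON	Spinocerebellar ataxia
BANK1	4	101411286	102074812	rs13107325	hCONDEL	101422878	101422878	3650	0	INTRON
BANK1	4	101411286	102074812	rs13107325	hCONDEL	101990081	101990081	4838	0	INTRON
TTC29	4	146706638	146945882	rs6840804	hCONDEL	146796204	146796204	9671	0	INTRON
PDE4D	5	58969038	60522120	rs34426618	insertion	60429841	60432132	2292	0	NONCODING_EXON
PAM	5	102753981	103031105	rs76160968	hCONDEL	102883977	102883977	3868	0	INTRON
FBXL17	5	107859035	108382098	rs1438660	hCONDEL	108119106	108119106	959	0	INTRON
CALN1	7	71779491	72447151	rs56150095	hCONDEL	72221700	72221700	2994	0	INTRON
SND1	7	127652180	128092609	rs4731392	hCONDEL	127808446	127808446	749	0	INTRON
EXOC4	7	133253073	134066589	rs1362739	insertion	133889352	133895456	6105	0	NONCODING_EXON
SGCZ	8	14089864	15238339	rs13253386	hCONDEL	14090971	14090971	277	0	INTRON
TSNARE1	8	142212080	142403240	rs4976976	STR_expansion	142326108	142326158	51	0	NONCODING_EXON
REEP3	10	63521363	63625123	rs2393967	hCONDEL	63593088	63593088	554	0	INTRON
GRIA4	11	105609994	105982092	rs7116046	hCONDEL	105754761	105754761	3804	0	INTRON	Neurodevelopmental disorder
NCAM1	11	112961247	113278436	rs2885208	hCONDEL	113152794	113152794	160	0	INTRON
RERG	12	15107783	15348675	rs55754731	hCONDEL	15107134	15107134	69	0	INTRON
KMT2D	12	49018975	49059774	rs1054442	STR_contraction	49032866	49032866	60	0	CDS_EXON	Kabuki syndrome
PRKD1	14	29576479	30191898	rs971681	hCONDEL	29869703	29869703	1515	0	INTRON	Congenital heart defects and ectodermal dysplasia
FUT8	14	65410592	65744121	14:66113725_C_A	insertion	65457887	65458201	315	0	NONCODING_EXON	Glycosylation disorder
RTF1	15	41408408	41483563	rs75322822	hCONDEL	41430384	41430384	1965	0	INTRON
GNB5	15	52115105	52191369	rs7172979	hCONDEL	52177036	52177036	1472	0	INTRON	Language delay and ADHD/cognitive impairment; Intellectual developmental disorder
GNB5	15	52115105	52191369	rs7172979	insertion	52121612	52121903	292	0	UTR3
SKAP1	17	48133440	48430275	rs12928404	hCONDEL	48286479	48286479	343	0	INTRON
SKAP1	17	48133440	48430275	rs12928404	hCONDEL	48259161	48259161	53	0	INTRON
DCC	18	52340172	53535903	rs71367283	hCONDEL	52358208	52358208	566	0	INTRON	Corpus callosum agenesis
ZNF584	19	58401504	58418327	rs73068339	insertion	58404219	58406377	2159	0	NONCODING_EXON
SLC27A5	19	58479512	58512413	rs73068339	deletion	58490956	58490956	3235	0	NONCODING_EXON
PHF20	20	35771974	35950381	rs78084033	hCONDEL	35797866	35797866	3808	0	INTRON
STAU1	20	49113339	49188367	rs6019535	exon_gain	49179121	49179244	124	0	UTR5
DDX27	20	49219295	49244077	rs6019535	hCONDEL	49221110	49221110	809	0	INTRON
TRIOBP	22	37696988	37776556	rs4396807	insertion	37723443	37724117	675	0	CDS_EXON	Nonsyndromic deafness
EP300	22	41091786	41180079	rs4821995	hCONDEL	41135508	41135508	2279	0	INTRON	Rubinstein-Taybi syndrome 2
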