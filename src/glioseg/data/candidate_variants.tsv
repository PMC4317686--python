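family_id	pos	ref	alt	gene	esp_pct	kg_pct	dbsnp	affected_ratio	unaffected_ratio	cadd_scaled
L	49098662	G	A	SPAG9	0.069	.	rs143491486	2/2	3/4	32.0
C	41143047	G	C	RUNDC1	0.069	0.05	rs61995866	2/2	2/4	28.2
M	40091564	C	G	TTC25	.	.	.	1/1	5/8	25.9
O	34883425	G	A	MYO19	.	.	.	1/1	4/5	19.2
C	39503458	C	T	KRT33A	0.015	.	rs142400197	2/2	1/4	19.2
G	43005646	G	C	KIF18B	0.090	.	rs202002436	2/2	0/4	18.8
B	43006370	C	T	KIF18B	0.008	.	rs201865018	2/2	1/6	18.4
P	40345030	C	A	GHDC	0.038	0.09	rs149568450	2/2	2/4	18.1
J	34859014	C	T	MYO19	.	.	.	2/2	3/8	17.4
P	42750898	A	T	C17orf104	.	0.05	rs192757598	2/2	2/4	16.2
A	41063291	G	A	G6PC	.	.	.	2/2	0/5	14.5
L	37785802	C	A	PPP1R1B	.	.	rs201594054	2/2	2/4	14.1
H	38933291	G	A	KRT27	0.077	.	rs148928902	1/1	2/6	14.0
C	45904542	C	T	MRPL10	0.046	0.05	rs149631185	2/2	3/4	14.0
J	48561815	T	C	RSAD1	.	.	.	2/2	3/8	12.2
S	41338453	G	C	NBR1	0.042	.	rs200709037	2/2	3/6	11.3
B	48141461	G	A	ITGA3	.	0.05	rs201210478	2/2	1/6	10.7
K	39036435	C	T	KRT20	.	.	.	1/1	0/24	10.5
J	39620632	G	A	KRT32	0.008	.	rs147094229	2/2	4/8	7.2
K	55194252	G	A	AKAP1	0.062	.	rs149147838	1/1	1/24	6.7
N	45419305	C	G	EFCAB13	0.038	.	rs138179179	1/1	4/7	5.0
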