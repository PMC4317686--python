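A	A-1	0	0	2	2	1	Oligodendroglioma	48
A	A-2	0	0	1	2	1	Astrocytoma	33
A	A-3	0	0	2	2	0	Ependymoma	20
B	B-1	0	0	2	2	1	Astrocytoma	40
B	B-2	0	0	2	2	1	Oligodendroglioma	30
C	C-1	0	0	1	2	1	Anaplastic Astro	40
C	C-2	0	0	1	2	1	GBM	46
C	C-3	0	0	2	2	0	Astrocytoma	16
D	D-1	0	0	2	2	1	GBM	54
D	D-2	0	0	1	2	0	UNK Glioma	31
D	D-3	0	0	2	2	0	GBM	55
E	E-1	0	0	1	2	1	Anaplastic Astro	39
E	E-2	0	0	2	2	1	Oligodendroglioma	27
F	F-1	0	0	1	2	1	GBM	61
F	F-2	0	0	2	2	1	GBM	52
G	G-2	0	0	1	2	1	Anaplastic Astro	29
G	G-1	G-2	0	1	2	1	Anaplastic Oligo	28
G	G-3	0	0	1	2	0	UNK Glioma	50
H	H-1	0	0	1	2	1	GBM	59
H	H-2	0	0	1	2	0	UNK Glioma	42
I	I-1	0	0	2	2	1	Anaplastic Oligo	58
I	I-2	0	0	1	2	1	Oligodendroglioma	32
J	J-1	0	0	2	2	1	Anaplastic Astro	27
J	J-2	0	0	1	2	1	Oligoastrocytoma	38
K	K-1	0	0	1	2	0	Anaplastic Oligo	65
K	K-2	0	0	2	2	1	GBM	82
K	K-3	0	0	2	2	0	GBM	79
K	K-4	0	0	2	2	0	Anaplastic Astro	81
K	K-5	0	0	2	2	0	UNK Glioma	63
K	K-6	0	0	1	2	0	GBM	61
L	L-1	0	0	2	2	1	Astrocytoma	39
L	L-2	0	0	2	2	1	GBM	66
M	M-1	0	0	2	2	1	GBM	66
M	M-2	0	0	2	2	0	GBM	59
N	N-1	0	0	1	2	1	GBM	66
N	N-2	0	0	1	2	0	GBM	53
O	O-2	0	0	2	2	0	UNK Glioma	27
O	O-1	0	O-2	2	2	1	Astrocytoma	43
O	O-3	0	O-2	1	2	0	GBM	45
P	P-1	0	0	1	2	1	Anaplastic Astro	28
P	P-2	0	0	1	2	1	Oligoastrocytoma	18
Q	Q-1	0	0	2	2	1	GBM	10
Q	Q-2	0	0	2	2	0	GBM	65
R	R-1	0	0	2	2	1	GBM	44
R	R-2	0	0	1	2	0	GBM	22
R	R-3	0	0	2	2	1	Astrocytoma	24
R	R-4	0	0	2	2	0	Astrocytoma	4
R	R-5	0	0	2	2	0	UNK Glioma	11
R	R-6	0	0	2	2	1	Astrocytoma	38
R	R-7	0	0	2	2	0	UNK Glioma	49
R	R-8	0	0	2	2	0	UNK Glioma	46
R	R-9	0	0	1	2	0	UNK Glioma	78
R	R-10	0	0	1	2	0	UNK Glioma	4
S	S-1	0	0	2	2	1	Oligodendroglioma	37
S	S-2	0	0	1	2	1	Ana Oligoastro	41
T	T-1	0	0	2	2	1	GBM	68
T	T-2	0	0	2	2	0	GBM	78
T	T-3	0	0	1	2	0	UNK Glioma	49
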