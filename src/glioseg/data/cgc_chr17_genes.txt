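TAF15
SUZ12
LASP1
CLTC
CDK12
NF1
RARA
BRCA1
DDX5
ETV4
MLLT6
ERBB2
COL1A1
BRIP1
HLF
CD79B
MSI2
PRKAR1A
MSF
ASPSCR1
CANT1
SRSF2
ALO17
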