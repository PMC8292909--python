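gene	log2fc
SRPK1	-0.5
CDCA3	-0.52
CDC20	-0.52
TYMS	-0.52
PEG3	-0.53
TCF3	-0.55
FDX1	-0.56
FAM49A	-0.56
FLI1	-0.57
ATAD2	-0.57
PSRC1	-0.59
PBX1	-0.6
PAPOLA	-0.61
NRG1	-0.62
NKX2.2	-0.67
EPHB3	-0.68
PCCA	-0.73
SALL2	-0.7
OLFM1	-0.76
DAPK2	-0.7
RBBP8	-0.79
FZD1	-0.8
CENPM	-0.81
RCC1	-0.84
DEPDC1	-0.86
LDB2	-0.88
PAXIP1	-1.08
MSC	-1.09
NPY1R	-1.1
EFNB1	-1.1
HIPK1	-1.11
IVNS1ABP	-1.24
GAS1	-1.56
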