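gene	log2fc
SERPINB8	0.72
FUCA1	0.64
NMI	0.60
CPVL	0.56
GSTM1	0.52
RCHY1	0.51
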