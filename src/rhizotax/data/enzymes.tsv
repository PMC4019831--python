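name	recognition	cut_offset
AluI	AGCT	2
MboI	GATC	0
RsaI	GTAC	2
Hin6I	GCGC	1
TaqI	TCGA	1
MspI	CCGG	1
HinfI	GANTC	1
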