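strain	AluI	MboI	RsaI	Hin6I	TaqI	MspI	HinfI	group
AG1	A	A	A	A	A	B	A	I
AG2	A	A	A	C	A	B	A	II
AG3	A	A	A	C	A	B	A	II
AG4	A	A	A	A	C	B	A	III
AG5	A	A	A	A	A	B	A	I
AG6	A	A	A	A	A	B	A	I
AG7	A	A	A	A	A	B	A	I
AG8	A	A	A	C	A	B	A	I
AG9	A	A	A	C	A	B	A	I
AG10	A	A	A	C	B	B	A	IV
AG11	A	A	A	A	B	B	A	V
AG12	A	A	B	A	A	A	E	VI
AG13	A	A	A	B	A	D	B	VII
AG14	A	A	A	B	A	D	B	VII
AG15	A	A	A	B	A	D	B	VII
AG16	A	A	A	A	C	A	B	VIII
AG17	A	A	A	A	A	A	B	IX
AG18	A	A	B	A	A	A	B	X
AG19	A	A	B	C	A	A	B	XI
AG20	A	A	A	A	A	C	A	XII
AG21	A	A	B	A	A	C	A	XIII
AG22	A	A	B	A	A	A	B	X
AG24	A	A	B	A	A	C	A	XIII
AG25	A	A	B	A	B	C	A	XIV
AG26	A	A	B	B	A	D	B	XV
AG27	A	A	B	A	B	C	A	XIV
AG28	A	A	B	A	A	C	A	XIII
AG29	A	A	B	A	A	C	A	XIII
Mesorhizobium albiziae CCBAU61158	A	B	C	B	D	E	F	XVI
Mesorhizobium amorphae ICMP15022	A	A	A	B	A	A	B	XVII
Mesorhizobium caraganae CCBAU11299	A	A	A	A	A	C	C	XVIII
Mesorhizobium ciceri USDA3383	A	A	A	A	A	D	C	XIX
Mesorhizobium chacoense USDA4963	A	A	A	D	A	F	B	XX
Mesorhizobium gobiense CCBAU83330	A	A	D	A	A	G	H	XXI
Mesorhizobium huakuii USDA4779	A	A	A	B	A	A	B	XVII
Mesorhizobium plurifarium USDA3707	A	A	A	A	E	A	D	XXII
Mesorhizobium loti MAFF303099	A	A	A	B	A	A	D	XXIII
Mesorhizobium septentrionale SDW018	A	A	A	A	A	A	B	IX
Mesorhizobium shangrilense CCBAU65327	A	A	A	A	A	A	F	XXIV
Mesorhizobium tianshanense USDA3592	A	A	A	A	A	C	A	XII
Mesorhizobium temperatum LMG23931	A	A	A	B	A	C	C	XXV
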