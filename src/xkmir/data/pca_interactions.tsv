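gene_symbol	region	mfe
AR	FIVE_UTR	-25.7
BCL2	THREE_UTR	-32.9
IGF1R	FIVE_UTR	-30.9
IGF1R	FIVE_UTR	-28.4
PDGFRB	THREE_UTR	-33.4
GSK3B	THREE_UTR	-38.2
PDPK1	THREE_UTR	-28.3
TMPRSS2	THREE_UTR	-37.3
ATF4	FIVE_UTR	-26.8
EP300	CDS	-25.7
AKT3	THREE_UTR	-29.3
FOXO1	THREE_UTR	-30.2
PTEN	FIVE_UTR	-29.4
CHUK	THREE_UTR	-30.8
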