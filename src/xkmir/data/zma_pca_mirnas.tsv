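mirna_id	species	sequence
zma-miR159f-5p	zma	GAGCUCCUCUCAUUCCAAUGA
zma-miR529-5p	zma	AGAAGAGAGAGAGUACAGCCU
zma-miR528b-5p	zma	UGGAAGGGGCAUGCAGAGGAG
zma-miR528a-5p	zma	UGGAAGGGGCAUGCAGAGGAG
zma-miR396c	zma	UUCCACAGGCUUUCUUGAACUG
zma-miR396d	zma	UUCCACAGGCUUUCUUGAACUG
zma-miR167h-3p	zma	GAUCAUGUUGCAGCUUCAC
zma-miR167i-3p	zma	GAUCAUGUUGCAGCUUCAC
zma-miR528a-3p	zma	CCUGUGCCUGCCUCUUCCAUU
zma-miR528b-3p	zma	CCUGUGCCUGCCUCUUCCAUU
zma-miR166l-5p	zma	GAAUGGAGGCUGGUCCAAGA
zma-miR164a-3p	zma	CACGUGUUCUCCUUCUCCAUC
zma-miR156a-3p	zma	GCUCACUUCUCUCUCUGUCAGU
zma-miR167g-3p	zma	GGUCAUGCUGUAGUUUCAUC
zma-miR166m-5p	zma	GGAAUGUUGGCUGGCUCGAGG
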