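name	sequence	declared_length
Sox4-F	CATCAAGCGACCGATGAACG	20
Sox4-R	CTTCTCGCTGTCCTTCAGCA	20
Sox3-F	CCGAGATCAAGACTCCGCAA	20
Sox3-R	GTTCTCCTGGGCCATCTTCC	20
Sox9-F	GGAGAACACCCGACCTCAAG	20
Sox9-R	CGTGGGGTTTGTTCTTGCTG	20
Sox17-F	TAAATCGTGGAAGGCGCTGT	20
Sox17-R	GCCGCTTCACCTGCTTCTTC	20
Sox30-F	CTAGGATTCACCGACCTGCC	20
Sox30-R	TGGTCGTGGCTGATAAACCC	20
beta-actin-F	TGTAACCCAACAAGTGTCTT	20
beta-actin-R	CCACATACTGGCACTTTACT	20
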