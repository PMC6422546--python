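name	sequence	snp	role
*4_F	CACATTTTCTACAACCATGGAGACC	CYP3A4*4	forward
*4_R	TACCTGTCCCCACCAGATTCATTCT	CYP3A4*4	reverse
*18B_F	CCACGAGCAGTGTTCTCTCCTTC	CYP3A4*18B	forward
*18B_R	AATAGAAAGCAGATGAACCAGAGCC	CYP3A4*18B	reverse
*22_F	GCATAGAGTCTGCAGTCAGGCAAT	CYP3A4*22	forward
*22_R	GATGACAGGGTTTGTGACAGGGG	CYP3A4*22	reverse
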