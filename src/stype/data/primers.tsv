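name	si_class	role	sequence	expected_length
KD(I)-F	class_I	forward	GAACTTCCATTGATAGAGTTRG	1200
KD(I)-R	class_I	reverse	TTRGGCTKAGGAATCKCT	1200
KD4	class_II	forward	GAGGGCGAGAAAGATCTTAATT	1000
KD7	class_II	reverse	AAGACGATCATATTACCGAGC	1000
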