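residue_number	ref_aa	alt_aa	allele_frequency	sift_score	pp2_score
393	M	I	0.0015	0.88	0.161
394	R	C		0.91	0.02
400	R	Q	0.0003	0.99	0.999
424	E	D		0.92	0.001
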