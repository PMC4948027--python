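subfamily	gene_a	gene_b	dup_type	ka	ks	kaks	date_mya
A1	PeuHsf-A1a	PeuHsf-A1d	WGD	0.004	0.009	0.389	0.49
A1	PeuHsf-A1c	PeuHsf-A1d	WGD	0.173	0.343	0.503	18.85
A4	PeuHsf-A4a	PeuHsf-A4c	WGD	0.069	0.253	0.274	13.90
A5	PeuHsf-A5b	PeuHsf-A5c	Tandem	0.003	0.009	0.303	0.49
A6	PeuHsf-A6a	PeuHsf-A6b	WGD	0.116	0.204	0.568	11.20
A7	PeuHsf-A7a	PeuHsf-A7b	WGD	0.077	0.279	0.275	15.31
B2	PeuHsf-B2c	PeuHsf-B2d	WGD	0.141	0.362	0.388	19.91
B4	PeuHsf-B4a	PeuHsf-B4c	WGD	0.022	0.325	0.068	17.86
B4	PeuHsf-B4b	PeuHsf-B4d	WGD	0.061	0.316	0.194	17.38
B5	PeuHsf-B5a	PeuHsf-B5b	WGD	0.096	0.335	0.286	18.38
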