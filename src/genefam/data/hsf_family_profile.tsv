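gene	hsf_class	length_aa	ncr	pcr	ncr_pct	pcr_pct
PeuHsf-A1a	A	491	63	41	12.8	8.4
PeuHsf-A1b	A	423	50	38	11.8	9.0
PeuHsf-A1c	A	510	67	45	13.1	8.8
PeuHsf-A1d	A	523	64	41	12.2	7.8
PeuHsf-A2	A	425	65	47	15.3	11.1
PeuHsf-A3	A	522	82	51	15.7	9.8
PeuHsf-A4a	A	404	57	43	14.1	10.6
PeuHsf-A4b	A	444	64	49	14.4	11.0
PeuHsf-A4c	A	427	61	45	14.3	10.5
PeuHsf-A5a	A	485	63	56	13.0	11.5
PeuHsf-A5b	A	489	65	57	13.3	11.7
PeuHsf-A5c	A	737	82	81	11.1	11.0
PeuHsf-A6a	A	358	58	43	16.2	12.0
PeuHsf-A6b	A	331	56	41	15.8	11.5
PeuHsf-A7a	A	355	55	45	15.5	12.7
PeuHsf-A7b	A	359	54	47	15.0	13.1
PeuHsf-A7c	A	359	54	47	15.0	13.1
PeuHsf-A8	A	392	66	37	16.8	9.4
PeuHsf-A9	A	501	76	58	15.2	11.6
PeuHsf-B1	B	288	51	35	17.7	12.2
PeuHsf-B2a	B	294	44	34	15.0	11.6
PeuHsf-B2b	B	340	47	35	13.8	10.3
PeuHsf-B2c	B	287	47	37	16.4	12.9
PeuHsf-B2d	B	294	44	34	15.0	11.6
PeuHsf-B3	B	228	37	38	16.2	16.7
PeuHsf-B4a	B	364	32	34	8.8	9.3
PeuHsf-B4b	B	271	34	31	12.5	11.4
PeuHsf-B4c	B	368	33	34	9.0	9.2
PeuHsf-B4d	B	270	32	32	11.9	11.9
PeuHsf-B5a	B	209	26	33	12.4	15.8
PeuHsf-B5b	B	207	22	30	10.6	14.5
PeuHsf-C1	C	338	40	37	11.8	10.9
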