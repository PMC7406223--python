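ecf_residue	asdi_residue	ecf_region	asdi_region	dca_rank	is_sdp
22	59	s2.1	H4		N
22	60	s2.1	H4		N
22	63	s2.1	H4		N
23	56	s2.1	H4	5	Y
23	60	s2.1	H4	6	N
26	55	s2.1	H4		N
26	56	s2.1	H4		Y
26	59	s2.1	H4		N
27	56	s2.1	H4	1	Y
31	51	s2.1	linker H3-H4	14	N
35	48	s2.1	linker H3-H4		N
47	52	s2.2	linker H3-H4	8	N
47	55	s2.2	H4		N
51	55	s2.2	H4		N
51	58	s2.2	H4		N
51	59	s2.2	H4		N
54	59	s2.2	H4		N
58	63	s2.2	H4		N
131	42	s4.1	H3		N
135	43	s4.1	H3		N
149	11	s4.2	H1	10	Y
150	10	s4.2	H1		N
150	40	s4.2	H3		N
150	43	s4.2	H3		N
151	43	s4.2	H3		N
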