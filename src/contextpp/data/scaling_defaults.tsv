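feature	site_type	p5	p95
3P_score	8mer	1.000	3.500
3P_score	7mer-m8	1.000	3.500
3P_score	7mer-A1	1.000	3.500
3P_score	6mer	1.000	3.500
SPS	8mer	-11.130	-5.520
SPS	7mer-m8	-11.130	-5.490
SPS	7mer-A1	-8.410	-3.330
SPS	6mer	-8.570	-3.330
TA_3UTR	8mer	3.113	3.865
TA_3UTR	7mer-m8	3.067	3.887
TA_3UTR	7mer-A1	3.145	3.887
TA_3UTR	6mer	3.113	3.887
Len_3UTR	8mer	2.392	3.637
Len_3UTR	7mer-m8	2.409	3.615
Len_3UTR	7mer-A1	2.413	3.630
Len_3UTR	6mer	2.405	3.620
Len_ORF	8mer	2.788	3.753
Len_ORF	7mer-m8	2.773	3.729
Len_ORF	7mer-A1	2.773	3.730
Len_ORF	6mer	2.775	3.731
Min_dist	8mer	1.415	3.113
Min_dist	7mer-m8	1.491	3.096
Min_dist	7mer-A1	1.431	3.117
Min_dist	6mer	1.477	3.106
Local_AU	8mer	0.308	0.814
Local_AU	7mer-m8	0.277	0.782
Local_AU	7mer-A1	0.342	0.801
Local_AU	6mer	0.295	0.772
SA	8mer	-4.356	-0.661
SA	7mer-m8	-5.218	-0.725
SA	7mer-A1	-4.230	-0.588
SA	6mer	-5.082	-0.666
P_CT	8mer	0.000	0.816
P_CT	7mer-m8	0.000	0.364
P_CT	7mer-A1	0.000	0.449
P_CT	6mer	0.000	0.193
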