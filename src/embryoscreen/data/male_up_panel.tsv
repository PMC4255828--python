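contig	comparison	length_bp	printed_fold	sample	rpkm
contig_22537	B	1546	-109.63	BJ2	185.79
contig_22537	B	1546	-109.63	BJ3	0.1
contig_22537	B	1546	-109.63	BJ4	3.29
contig_26828	B	407	-90.35	BJ2	145.56
contig_26828	B	407	-90.35	BJ3	0
contig_26828	B	407	-90.35	BJ4	3.22
contig_30721	B	521	-44.23	BJ2	68.22
contig_30721	B	521	-44.23	BJ3	0.39
contig_30721	B	521	-44.23	BJ4	2.7
contig_47470	B	424	-100.05	BJ2	111.08
contig_47470	B	424	-100.05	BJ3	0.12
contig_47470	B	424	-100.05	BJ4	2.1
contig_49000	B	222	-39.38	BJ2	131.19
contig_49000	B	222	-39.38	BJ3	0.96
contig_49000	B	222	-39.38	BJ4	5.71
contig_31948	D	667	-387.12	BJ6	64.8
contig_31948	D	667	-387.12	BJ7	0.1
contig_31948	D	667	-387.12	BJ8	0.23
contig_3465	D	234	-20.53	BJ6	29.21
contig_3465	D	234	-20.53	BJ7	0.57
contig_3465	D	234	-20.53	BJ8	2.28
contig_41160	D	210	-70.11	BJ6	37.85
contig_41160	D	210	-70.11	BJ7	0.33
contig_41160	D	210	-70.11	BJ8	0.75
contig_567	D	220	-23.73	BJ6	33.44
contig_567	D	220	-23.73	BJ7	2.82
contig_567	D	220	-23.73	BJ8	0
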