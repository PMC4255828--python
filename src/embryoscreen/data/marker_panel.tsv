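gene	category	contig	length_bp	BJ5	BJ6	BJ7	BJ8	BJ1	BJ2	BJ3	BJ4
doublesex_F	sex_determination	consensus	1839	0.42	0.19	0.17	0.22	0.55	0.04	0.09	0.03
daughterless	sex_determination	16154	4053	3.03	3.39	9.88	9.94	1.51	4.52	4.26	4.53
deadpan	sex_determination	20953	3365	0.28	0.25	0.26	1.06	0.95	10.92	11.18	24.97
degringolade	sex_determination	2208	1737	111.44	116.21	107.56	104.73	149.23	100.76	93.48	100.61
extra_macrochaetae	sex_determination	10611	1230	0.97	0.44	0.56	2.5	6.82	121.25	123.56	211.04
female_lethal_d	sex_determination	2854	2694	18.97	13.9	12.22	11.07	17.85	40.43	43.89	37.66
fruitless	sex_determination	29049	3175	0.78	0.57	0.74	0.43	0.62	0.19	0.38	0.08
groucho	sex_determination	3466	4604	16.34	7.42	13.32	12.69	13.69	51.44	59.52	94.36
hopscotch	sex_determination	753	4443	53.5	20.8	23.27	19.15	40.31	15	20.17	23.18
Mes-4	sex_determination	5091	5397	57.2	17.96	22.76	16.62	34.22	11.54	18.9	17.46
ovarian_tumor	sex_determination	consensus	5276	31.52	22.68	62.4	46.29	22.6	20.46	26.52	16.5
ovo_variant1	sex_determination	21175	255	3.93	2.97	8.77	14.62	1.44	0.09	0.43	0.23
ovo_variant6	sex_determination	consensus	3076	12.66	11.2	58.05	51.86	5.85	0.83	0.61	0.86
runt	sex_determination	consensus	2399	0.74	0.22	0.13	5.4	11.8	65.22	58.82	36.12
sans_fille	sex_determination	7153	1421	35.59	80.26	75.06	85.98	43.71	65.1	55.76	50.27
scute	sex_determination	consensus	817	0.11	0.15	0.12	0.17	0.07	0.05	0.05	0.08
Sex-lethal	sex_determination	2265	1667	23.93	21.11	23.7	22.69	22.68	38.45	42.67	64.18
sisterless_A	sex_determination	2508	264	71.62	39.09	29.59	38.58	89.42	180.25	216.18	294.05
transformer_F	sex_determination	consensus	3793	27.3	22.76	18.43	18.49	28.18	17.12	17.29	21.22
transformer-2	sex_determination	138	3165	48.16	44.99	41.74	44.01	47.47	37.15	37.52	39.39
nullo	cellularisation	consensus	1332	1.15	2.52	0.13	15.34	8.59	162.77	125.03	45.74
serendipity_alpha	cellularisation	9105	5007	13.31	11.32	10.66	9.64	12.42	4.22	3.5	4.31
slow_as_molasses	cellularisation	3824	5366	2.02	0.76	0.25	13.35	35.87	460.96	425.02	299.29
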