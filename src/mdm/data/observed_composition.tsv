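genome	species	ApA/TpT	ApC/GpT	ApG/CpT	ApT	CpA/TpG	CpC/GpG	CpG	GpA/TpC	GpC	TpA	GC
cattle	Bos taurus	18.66	10.20	14.31	7.47	14.73	10.74	1.05	12.70	4.13	6.01	41.89
dog	Canis lupus familiaris	19.57	9.69	14.13	7.75	13.95	10.84	1.09	12.35	4.11	6.51	41.10
chicken	Gallus gallus	19.01	10.40	14.53	7.14	15.37	9.61	1.14	11.89	4.94	5.98	41.78
chimpanzee	Pan troglodytes	19.55	10.08	13.99	7.71	14.52	10.43	1.01	11.87	4.29	6.55	40.96
zebrafish	Danio rerio	22.12	11.31	11.44	9.26	14.64	6.96	1.79	10.50	3.92	8.06	36.62
human	Homo sapiens	19.63	10.07	13.99	7.74	14.50	10.38	0.98	11.86	4.26	6.59	40.99
mouse	Mus musculus	18.06	10.69	14.74	7.29	14.95	10.54	0.85	12.44	4.13	6.31	41.93
baboon	Papio anubis	19.56	10.16	14.04	7.62	14.48	10.39	1.05	11.94	4.26	6.51	41.00
sheep	Ovis aries	18.65	10.18	14.35	7.44	14.70	10.74	1.08	12.68	4.17	6.01	41.95
pig	Sus scrofa	19.21	10.07	13.90	7.46	14.43	11.09	1.24	11.90	4.42	6.27	41.91
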