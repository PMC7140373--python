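genome	species	P_A	P_C	P_G	P_T	Pp_A	Pp_C	Pp_G	Pp_T
cattle	Bos taurus	0.2804	0.2590	0.2075	0.2531	0.2525	0.2072	0.2588	0.2815
dog	Canis lupus familiaris	0.2654	0.2857	0.2128	0.2361	0.2360	0.2127	0.2856	0.2657
chicken	Gallus gallus	0.3397	0.2284	0.2161	0.2158	0.2157	0.2166	0.2281	0.3396
chimpanzee	Pan troglodytes	0.2683	0.2679	0.2285	0.2353	0.2349	0.2286	0.2675	0.2690
zebrafish	Danio rerio	0.2887	0.2092	0.2523	0.2497	0.2498	0.2527	0.2096	0.2879
human	Homo sapiens	0.2537	0.2818	0.2422	0.2223	0.2218	0.2420	0.2818	0.2544
mouse	Mus musculus	0.2856	0.2606	0.2053	0.2485	0.2483	0.2052	0.2605	0.2860
baboon	Papio anubis	0.2553	0.2837	0.2384	0.2226	0.2224	0.2386	0.2837	0.2554
sheep	Ovis aries	0.2778	0.2598	0.2150	0.2474	0.2466	0.2148	0.2595	0.2790
pig	Sus scrofa	0.2663	0.2838	0.2137	0.2361	0.2356	0.2135	0.2840	0.2668
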