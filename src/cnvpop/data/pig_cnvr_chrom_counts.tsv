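chrom	length_mb	all_total	all_dup	all_del	aq_total	aq_dup	aq_del	ss_total	ss_dup	ss_del
1	274.33	1175	641	446	1157	639	431	457	117	287
2	151.94	1031	557	369	1016	556	357	445	147	225
3	132.85	607	316	243	601	315	238	227	47	153
4	130.91	574	276	249	566	276	242	261	78	154
5	104.53	587	292	235	581	292	230	258	70	155
6	170.84	865	475	308	856	473	304	328	93	195
7	121.84	561	274	208	548	272	199	257	66	136
8	138.97	569	226	302	558	222	296	251	47	186
9	139.51	652	320	252	642	320	244	295	81	175
10	69.36	290	109	176	286	108	174	153	31	118
11	79.17	283	74	198	278	74	193	144	18	120
12	61.6	394	210	140	387	209	136	158	42	95
13	208.34	874	445	361	861	445	348	363	102	226
14	141.76	672	351	259	668	350	257	276	84	154
15	140.41	504	262	217	492	261	208	206	56	132
16	79.94	287	81	204	283	81	200	157	22	133
17	63.49	328	132	167	324	132	163	165	38	108
18	55.98	176	70	100	175	70	99	78	8	65
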