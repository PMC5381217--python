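taxon	input_copies	method	rep1	rep2	rep3	trueness_printed	precision_printed
Clostridium	2500	micPCR	6735	3840	4347	2.0	0.3
Staphylococcus	2500	micPCR	4776	3147	4875	1.7	0.2
Haemophilus	2500	micPCR	4082	3133	2611	1.3	0.2
Moraxella	2500	micPCR	3714	2213	1056	0.9	0.6
Clostridium	250	micPCR	487	631	641	2.3	0.1
Staphylococcus	250	micPCR	486	579	375	1.9	0.2
Haemophilus	250	micPCR	238	225	183	0.9	0.1
Moraxella	250	micPCR	225	363	214	1.1	0.3
Clostridium	25	micPCR	28	31	52	1.5	0.3
Staphylococcus	25	micPCR	57	47	52	2.1	0.1
Haemophilus	25	micPCR	10	9	54	1.0	1.1
Moraxella	25	micPCR	19	5	29	0.7	0.7
Clostridium	2.5	micPCR	0	4	0	0.6	1.6
Staphylococcus	2.5	micPCR	1	15	19	4.6	0.8
Haemophilus	2.5	micPCR	1	0	9	1.3	1.6
Moraxella	2.5	micPCR	1	3	0	0.6	1.1
Clostridium	2500	traditional	953	6638	7340	2.0	0.7
Staphylococcus	2500	traditional	403	3793	4075	1.1	0.7
Haemophilus	2500	traditional	370	2483	2509	0.7	0.7
Moraxella	2500	traditional	36	3034	3604	0.9	0.9
Clostridium	250	traditional	736	513	497	2.3	0.2
Staphylococcus	250	traditional	302	210	284	1.1	0.2
Haemophilus	250	traditional	281	226	261	1.0	0.1
Moraxella	250	traditional	240	188	231	0.9	0.1
Clostridium	25	traditional	119	29	36	2.4	0.8
Staphylococcus	25	traditional	15	27	50	1.2	0.6
Haemophilus	25	traditional	112	28	28	2.3	0.9
Moraxella	25	traditional	116	2	0	1.6	1.7
Clostridium	2.5	traditional	0	11	1	1.7	1.5
Staphylococcus	2.5	traditional	243	6	1	33.3	1.7
Haemophilus	2.5	traditional	0	0	10	1.3	1.7
Moraxella	2.5	traditional	0	7	0	1.0	1.6
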