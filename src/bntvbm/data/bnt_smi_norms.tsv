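item_id	word	smi
1	BED	6.360
3	PENCIL	5.870
5	WHISTLE	4.478
7	COMB	5.923
9	SAW	4.760
11	HELICOPTER	5.179
13	OCTOPUS
15	HANGER	5.292
17	CAMEL	4.522
19	PRETZEL	6.040
21	RACQUET	5.240
23	VOLCANO
25	DART	5.292
27	GLOBE	5.280
29	BEAVER	3.826
31	RHINOCEROS	3.680
33	IGLOO	4.852
35	DOMINOES	5.704
37	ESCALATOR	5.520
39	HAMMOCK	6.167
41	PELICAN	3.667
43	PYRAMID	4.000
45	UNICORN	1.296
47	ACCORDION	5.826
49	ASPARAGUS	5.560
51	LATCH	5.542
53	SCROLL	4.227
55	SPHINX	3.120
57	TRELLIS
59	PROTRACTOR	5.435
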