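item_id	prop_control	prop_mci
1	1.000	1.000
3	1.000	1.000
5	1.000	0.989
7	1.000	1.000
9	1.000	0.994
11	0.990	0.969
15	1.000	1.000
17	1.000	0.986
19	0.959	0.826
21	0.990	0.974
25	0.964	0.914
27	0.975	0.906
29	0.827	0.711
31	0.924	0.814
33	0.980	0.940
35	0.919	0.851
37	0.975	0.911
39	0.964	0.886
41	0.843	0.720
43	0.934	0.857
45	0.807	0.603
47	0.934	0.823
49	0.985	0.906
51	0.624	0.591
53	0.909	0.800
55	0.802	0.603
59	0.523	0.340
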