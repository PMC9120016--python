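letter	theta123	theta234	theta134	cos_tau	sin_tau
0	0.897373	2.086215	1.082768	0.888195	0.011823
1	1.311414	2.303780	2.701010	-0.931742	-0.032345
2	1.349269	2.340276	2.155121	-0.257528	-0.912545
3	1.478271	2.371901	1.735019	0.634648	0.682965
4	1.501028	1.650458	1.185240	0.585872	-0.798376
5	1.643633	1.502356	1.034379	0.686970	-0.711561
6	1.694894	2.535222	1.915684	0.729255	-0.597263
7	1.734684	2.388077	2.345983	-0.401121	0.859933
8	2.060167	2.020359	2.545350	-0.985870	0.010868
9	2.080815	1.149185	1.029541	0.355974	0.812497
10	2.173734	0.853740	1.295896	-0.881028	-0.185153
11	2.206465	2.283270	2.726059	-0.985657	-0.009675
12	2.310323	2.629020	2.677745	-0.605375	-0.757602
13	2.364438	1.559823	1.614547	-0.154429	-0.938253
14	2.446888	2.624186	2.359301	0.617399	0.738592
15	2.453500	1.595305	1.856765	-0.785014	0.528863
16	2.458262	2.617541	2.457426	0.192436	-0.949363
17	2.459258	1.993843	1.667050	0.950073	0.091856
18	2.466579	0.909384	0.724519	0.658559	-0.519445
19	2.542712	1.862081	1.774442	0.249754	0.912630
20	2.552608	2.595534	2.574093	-0.265824	0.926918
21	2.572693	2.614408	2.796481	-0.911725	0.311078
22	2.575198	2.078611	1.914545	0.522597	-0.795924
23	2.591982	2.655108	2.392612	0.925322	-0.225295
24	2.608319	2.029719	2.232579	-0.820808	-0.476845
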