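s	C_mean	C_stderr
0	1.0	1.5443027049183586e-17
1	0.6816895291260107	0.0034370010983671303
2	0.6287624989875799	0.002617768333266291
3	0.5421533103830393	0.003289005051488502
4	0.4595778861835742	0.004307268767999308
5	0.3806254646890568	0.005894762996300542
6	0.2999379150381058	0.006862628743929747
7	0.22142112946897416	0.008149715549866971
8	0.15193081960027802	0.009608136114775219
9	0.08048421573845635	0.010690998962540887
10	0.01789372340734492	0.011610525852372572
11	-0.039562702705053916	0.012315441268732035
12	-0.09182389114966145	0.012578884769381645
13	-0.13890291994881693	0.012458631574795924
14	-0.17911757022923067	0.011952121393744375
15	-0.20945362857705574	0.011258111324675819
16	-0.23645388746844243	0.01003293460288376
17	-0.25359270607893103	0.008636871054488075
18	-0.2615990253067896	0.006926066742711091
19	-0.26197873811614697	0.004968022541193984
20	-0.26012918000966234	0.003556549608277467
21	-0.25117707151507324	0.004015104624974774
22	-0.23903051275397894	0.006283151903199351
23	-0.22185679054600058	0.008989383808138872
24	-0.21127759332773136	0.011841683498211564
25	-0.19671946545018357	0.014343363631780163
26	-0.18705085799299148	0.016650365609777583
27	-0.18040615833525497	0.018709870282012767
28	-0.17307478618770883	0.020202343974457034
29	-0.17614367720293245	0.021238988068042523
30	-0.17434755621280193	0.021685497363553817
31	-0.17434755621280193	0.021685497363553817
32	-0.17614367720293245	0.021238988068042523
33	-0.17307478618770883	0.020202343974457034
34	-0.18040615833525497	0.018709870282012767
35	-0.18705085799299148	0.016650365609777583
36	-0.19671946545018357	0.014343363631780163
37	-0.21127759332773136	0.011841683498211564
38	-0.22185679054600058	0.008989383808138874
39	-0.23903051275397894	0.006283151903199351
40	-0.25117707151507324	0.004015104624974774
41	-0.26012918000966234	0.003556549608277467
42	-0.26197873811614697	0.004968022541193984
43	-0.2615990253067896	0.006926066742711091
44	-0.25359270607893103	0.008636871054488075
45	-0.2364538874684424	0.01003293460288376
46	-0.20945362857705574	0.011258111324675819
47	-0.17911757022923067	0.011952121393744375
48	-0.13890291994881693	0.012458631574795924
49	-0.09182389114966147	0.012578884769381645
50	-0.039562702705053916	0.012315441268732035
51	0.01789372340734492	0.011610525852372572
52	0.08048421573845635	0.010690998962540887
53	0.15193081960027802	0.009608136114775219
54	0.22142112946897416	0.008149715549866971
55	0.2999379150381058	0.006862628743929747
56	0.3806254646890568	0.005894762996300542
57	0.4595778861835742	0.004307268767999308
58	0.5421533103830393	0.003289005051488502
59	0.6287624989875799	0.002617768333266291
60	0.6816895291260107	0.0034370010983671303
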