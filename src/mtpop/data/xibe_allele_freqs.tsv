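position	alleles	freqs
152	T/C	0.78/0.22
709	G/A	0.77/0.23
1541	T/C	0.99/0.01
1719	G/A	0.98/0.02
1811	A/G	0.99/0.01
2706	G/A	0.93/0.07
3010	G/A	0.73/0.27
3348	A	1
3970	C/T	0.85/0.15
4216	T/C	0.99/0.01
4491	G	1
4833	A/G	0.98/0.02
4883	C/T	0.70/0.30
5178	C/A	0.70/0.30
5417	G/A	0.96/0.04
5442	T/C	0.97/0.03
5460	G/A	0.97/0.03
6446	G	1
7028	T/C	0.94/0.06
7196	C/A	0.85/0.15
7600	G/A	0.99/0.01
8020	G/A	0.91/0.09
8414	C/T	0.74/0.26
8584	G/A	0.80/0.20
8684	C	1
8964	C/T	0.94/0.06
9123	G/A	0.98/0.02
9477	G/A	0.99/0.01
9545	A/G	0.91/0.09
9698	T/C	0.99/0.01
9824	T/A/C	0.88/0.07/0.05
10310	G/A	0.86/0.14
10397	A/G	0.96/0.04
10398	G/A	0.64/0.36
10400	T/C	0.55/0.45
10873	C/T	0.55/0.45
11215	C/T	0.97/0.03
11251	A/G	0.99/0.01
11719	A/G	0.94/0.06
12372	G/A	0.93/0.07
12705	T/C	0.64/0.36
12811	T/C	0.98/0.02
13104	A	1
13928	G/C	0.85/0.15
14569	G/A	0.97/0.03
14668	C/T	0.74/0.26
15043	A/G	0.55/0.45
15784	T/C	0.95/0.05
16126	T/C	0.96/0.04
16129	G/A	0.77/0.23
16311	T/C	0.89/0.11
16316	A/G	0.99/0.01
16319	G/A	0.93/0.07
16362	T/C	0.61/0.39
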