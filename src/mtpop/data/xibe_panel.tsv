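position	ref	alts
152	T	C
709	G	A
1541	T	C
1719	G	A
1811	A	G
2706	A	G
3010	G	A
3348	A	.
3970	C	T
4216	T	C
4491	G	.
4833	A	G
4883	C	T
5178	C	A
5417	G	A
5442	T	C
5460	G	A
6446	G	.
7028	C	T
7196	C	A
7600	G	A
8020	G	A
8414	C	T
8584	G	A
8684	C	.
8964	C	T
9123	G	A
9477	G	A
9545	A	G
9698	T	C
9824	T	A/C
10310	G	A
10397	A	G
10398	A	G
10400	C	T
10873	T	C
11215	C	T
11251	A	G
11719	G	A
12372	G	A
12705	C	T
12811	T	C
13104	A	.
13928	G	C
14569	G	A
14668	C	T
15043	G	A
15784	T	C
16126	T	C
16129	G	A
16311	T	C
16316	A	G
16319	G	A
16362	T	C
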