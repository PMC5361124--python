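haplotype_id	count	variants	nine_bp	ca_repeats
1	6	2706G, 7028T, 7196A, 8584A, 9545G, 10398G, 10400T, 10873C, 11719A, 12705T, 15043A	NORM	5
2	5	152C, 709A, 2706G, 3970T, 7028T, 10310A, 11719A, 13928C, 16129A	NORM	4
3	5	2706G, 5417A, 7028T, 11719A, 12372A, 12705T, 16129A	NORM	5
4	4	2706G, 3970T, 7028T, 10310A, 11719A, 13928C, 16311C	NORM	4
5	4	2706G, 3970T, 7028T, 10310A, 11719A, 13928C, 16129A	NORM	4
6	4	2706G, 3970T, 7028T, 10310A, 11719A, 13928C	NORM	5
7	4	152C, 2706G, 3010A, 4883T, 5178A, 7028T, 8020A, 8414T, 8964T, 9824A, 10398G, 10400T, 10873C, 11719A, 12705T, 14668T, 15043A, 16362C	NORM	4
8	4	2706G, 7028T, 7196A, 8584A, 9545G, 10398G, 10400T, 10873C, 11719A, 12705T, 15043A, 16129A	NORM	5
9	3	709A, 2706G, 7028T, 8584A, 10398G, 11719A, 16362C	DEL	4
10	3	2706G, 3010A, 4883T, 5178A, 7028T, 8020A, 8414T, 8964T, 9824A, 10398G, 10400T, 10873C, 11719A, 12705T, 14668T, 15043A, 16362C	NORM	4
11	3	2706G, 4883T, 5178A, 7028T, 10397G, 10398G, 10400T, 10873C, 11719A, 12705T, 15043A, 16362C	NORM	4
12	3	2706G, 5460A, 7028T, 9824C, 10398G, 10400T, 10873C, 11719A, 12705T, 12811C, 15043A, 16129A	NORM	5
13	3	2706G, 5442C, 7028T, 9824C, 10398G, 10400T, 10873C, 11719A, 12705T, 15043A, 16319A	NORM	4
14	3	rCRS	NORM	5
15	2	709A, 2706G, 7028T, 9123A, 11719A	DEL	4
16	2	2706G, 7028T, 11719A, 16129A, 16311C	DEL	4
17	2	709A, 2706G, 4216C, 7028T, 11251G, 11719A, 16126C	NORM	5
18	2	16126C	NORM	5
19	2	152C, 16362C	NORM	4
20	2	1541C, 2706G, 3970T, 7028T, 11719A, 13928C	NORM	5
21	2	152C, 1719A, 2706G, 3010A, 4883T, 5178A, 7028T, 8414T, 10398G, 10400T, 10873C, 11719A, 12705T, 14668T, 15043A, 16311C, 16362C	NORM	5
22	2	152C, 709A, 2706G, 7028T, 7196A, 8584A, 10398G, 10400T, 10873C, 11719A, 12705T, 15043A, 15784C	NORM	5
23	2	709A, 2706G, 7028T, 10398G, 10400T, 10873C, 11719A, 12705T, 16311C	NORM	5
24	2	152C, 2706G, 7028T, 7196A, 8584A, 10398G, 10400T, 10873C, 11719A, 12705T, 15043A, 15784C, 16129A	NORM	5
25	2	152C, 2706G, 7028T, 7196A, 8584A, 10398G, 10400T, 10873C, 11719A, 12705T, 15043A, 15784C	NORM	5
26	2	152C, 2706G, 7028T, 7196A, 8584A, 9545G, 10398G, 10400T, 10873C, 11719A, 12705T, 15043A	NORM	5
27	1	709A, 2706G, 7028T, 10310A, 11719A	DEL	5
28	1	2706G, 7028T, 9123A, 11719A	DEL	4
29	1	2706G, 7028T, 11719A	DEL	5
30	1	3010A	NORM	5
31	1	1811G, 2706G, 7028T, 11719A, 12372A	NORM	5
32	1	2706G, 7028T, 9477A, 11719A, 12372A	NORM	8
33	1	152C, 2706G, 3970T, 7028T, 8020A, 10310A, 11719A, 13928C, 16311C	NORM	5
34	1	2706G, 3970T, 7028T, 11719A, 13928C	NORM	5
35	1	2706G, 7028T, 11719A, 12705T, 16126C, 16311C, 16319A	NORM	5
36	1	2706G, 7028T, 11719A, 12705T, 16311C, 16319A	NORM	4
37	1	152C, 7028T, 11719A, 12705T, 16319A, 16362C	NORM	4
38	1	152C, 2706G, 7028T, 11719A, 12705T, 16319A, 16362C	NORM	4
39	1	152C, 2706G, 7028T, 11719A, 12705T, 16319A	NORM	4
40	1	709A, 2706G, 3010A, 4883T, 5178A, 7028T, 8020A, 8414T, 8964T, 9824A, 10398G, 10400T, 10873C, 11719A, 12705T, 14668T, 15043A, 16362C	NORM	4
41	1	152C, 709A, 2706G, 3010A, 4883T, 5178A, 7028T, 8414T, 10398G, 10400T, 10873C, 11719A, 12705T, 14668T, 15043A, 16362C	NORM	5
42	1	152C, 2706G, 3010A, 4883T, 5178A, 7028T, 8414T, 10398G, 10400T, 10873C, 11719A, 12705T, 14668T, 15043A, 16311C, 16362C	NORM	5
43	1	2706G, 3010A, 4883T, 5178A, 7028T, 8020A, 8414T, 9824A, 10398G, 10400T, 10873C, 11719A, 12705T, 14668T, 15043A, 16362C	NORM	4
44	1	3010A, 4883T, 5178A, 7028T, 8414T, 10398G, 10400T, 10873C, 11719A, 12705T, 14668T, 15043A, 16362C	NORM	4
45	1	2706G, 3010A, 4883T, 5178A, 7028T, 8414T, 10398G, 10400T, 10873C, 11215T, 11719A, 12705T, 14668T, 15043A, 16362C	NORM	5
46	1	2706G, 3010A, 4883T, 5178A, 7028T, 8414T, 10398G, 10400T, 10873C, 11719A, 12705T, 14668T, 15043A, 16316G, 16362C	NORM	7
47	1	709A, 2706G, 7028T, 7196A, 8584A, 9545G, 10398G, 10400T, 10873C, 11719A, 12705T, 15043A, 16129A	NORM	5
48	1	709A, 2706G, 4883T, 5178A, 7028T, 10397G, 10398G, 10400T, 10873C, 11719A, 12705T, 15043A, 16362C	NORM	5
49	1	152C, 709A, 2706G, 7028T, 10398G, 10400T, 10873C, 11719A, 12705T, 15043A, 16311C	NORM	5
50	1	709A, 2706G, 4833G, 5460A, 7028T, 10398G, 10400T, 10873C, 11719A, 12705T, 14569A, 15043A, 16362C	NORM	5
51	1	709A, 2706G, 4833G, 7028T, 7600A, 9477A, 10398G, 10400T, 10873C, 11719A, 12705T, 14569A, 15043A, 16362C	NORM	5
52	1	709A, 2706G, 4833G, 7028T, 7600A, 10398G, 10400T, 10873C, 11719A, 12705T, 14569A, 15043A, 16362C	NORM	5
53	1	709A, 2706G, 7028T, 10398G, 10400T, 10873C, 11719A, 12705T, 14569A, 15043A, 16362C	NORM	6
54	1	152C, 2706G, 7028T, 7196A, 8584A, 10398G, 10400T, 10873C, 11719A, 12705T, 15043A, 15784C, 16126C	NORM	5
55	1	152C, 2706G, 4883T, 5178A, 7028T, 10397G, 10398G, 10400T, 10873C, 11719A, 12705T, 15043A, 16362C	NORM	5
56	1	2706G, 5442C, 7028T, 9824C, 10398G, 10400T, 10873C, 11719A, 12705T, 15043A, 16362C	NORM	4
57	1	2706G, 7028T, 10398G, 10400T, 10873C, 11719A, 12705T, 15043A	NORM	5
58	1	1811G, 2706G, 7028T, 9698C, 10398G, 11719A, 12372A	NORM	4
59	1	1719A, 2706G, 7028T, 10398G, 11719A, 12705T, 15043A, 16129A	NORM	5
60	1	2706G, 5417A, 7028T, 10398G, 11719A, 12372A, 12705T, 16129A	NORM	4
61-a	12	2706G, 3010A, 4883T, 5178A, 7028T, 8414T, 10398G, 10400T, 10873C, 11719A, 12705T, 14668T, 15043A, 16362C	NORM	5
61-b	3	2706G, 3010A, 4883T, 5178A, 7028T, 8414T, 10398G, 10400T, 10873C, 11719A, 12705T, 14668T, 15043A, 16362C	NORM	4
62-a	3	709A, 2706G, 7028T, 8584A, 10398G, 11719A	DEL	4
62-b	2	709A, 2706G, 7028T, 8584A, 10398G, 11719A	DEL	5
63-a	2	2706G, 3010A, 4883T, 5178A, 7028T, 8414T, 10398G, 10400T, 10873C, 11215T, 11719A, 12705T, 14668T, 15043A, 16129A, 16362C	NORM	5
63-b	1	2706G, 3010A, 4883T, 5178A, 7028T, 8414T, 10398G, 10400T, 10873C, 11215T, 11719A, 12705T, 14668T, 15043A, 16129A, 16362C	NORM	6
64-a	1	2706G, 3010A, 4883T, 5178A, 7028T, 8020A, 8414T, 10398G, 10400T, 10873C, 11719A, 12705T, 14668T, 15043A, 16319A, 16362C	NORM	4
64-b	1	2706G, 3010A, 4883T, 5178A, 7028T, 8020A, 8414T, 10398G, 10400T, 10873C, 11719A, 12705T, 14668T, 15043A, 16319A, 16362C	DEL	4
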