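# Pairwise Fst (below the diagonal) and permutation p-values (above the diagonal)
# between the Xibe sample and 18 comparison populations; * marks the diagonal and
# bold (**) marks statistically significant Fst values, stripped on parsing.
# key: 1, Xibe; 2, Guangdong Han; 3, Liaoning Han; 4, Qingdao Han; 5, Wuhan Han; 6, Xinjiang Han; 7, Yuannan Han; 8, Estonian; 9, US_Hispanics; 10, US_African Americans; 11, US_Caucasians; 12, Yanbian Korean; 13, Italians; 14, Yanbian Han; 15, Southern China Han; 16, Daur; 17, Mongolian; 18, Korean; 19, Ewenki
Populations	1	2	3	4	5	6	7	8	9	10	11	12	13	14	15	16	17	18	19
1	*	0.85586	0.16216	0.34234	0.01802	0.44144	0.05405	0.00000	0.00000	0.00000	0.00000	0.61261	0.00000	0.10811	0.00901	0.83784	0.01802	0.08108	0.11712
2	0.01207	*	0.18919	0.20721	0.01802	0.27027	0.18018	0.00000	0.00901	0.00000	0.00000	0.80180	0.00000	0.06306	0.42342	0.58559	0.05405	0.33333	0.25225
3	0.00600	0.01253	*	0.67568	0.17117	0.89189	0.00901	0.00000	0.00000	0.00000	0.00000	0.30631	0.00000	0.29730	0.00000	0.21622	0.08108	0.07207	0.09910
4	0.00370	0.00967	0.00746	*	0.11712	0.90090	0.08108	0.00000	0.00000	0.00000	0.00000	0.32432	0.00000	0.81982	0.00000	0.15315	0.40541	0.13514	0.03604
5	**0.02953**	**0.04150**	0.01163	0.01640	*	0.15315	0.14414	0.00000	0.02703	0.00000	0.00000	0.03604	0.00000	0.01802	0.01802	0.04505	0.00000	0.00000	0.00000
6	0.00276	0.00622	0.01191	0.01465	0.01319	*	0.03604	0.00000	0.01802	0.00000	0.00000	0.43243	0.00000	0.92793	0.00000	0.49550	0.29730	0.32432	0.08108
7	0.01897	0.01111	**0.03971**	0.02478	0.01424	**0.03319**	*	0.00000	0.00000	0.00000	0.00000	0.07207	0.00000	0.00000	0.42342	0.10811	0.00901	0.00000	0.00000
8	**0.10341**	**0.12501**	**0.10719**	**0.16360**	**0.11345**	**0.13883**	**0.13693**	*	0.00000	0.00000	0.19820	0.00000	0.00000	0.00000	0.00000	0.00000	0.00000	0.00000	0.00000
9	**0.04803**	**0.05798**	**0.02868**	**0.04248**	**0.03615**	**0.02548**	**0.09566**	**0.14471**	*	0.00000	0.00000	0.01802	0.00000	0.00901	0.00000	0.00000	0.00000	0.03604	0.00000
10	**0.13039**	**0.15090**	**0.09262**	**0.10634**	**0.09568**	**0.12257**	**0.10556**	**0.15395**	**0.20950**	*	0.00000	0.00000	0.00000	0.00000	0.00000	0.00000	0.00000	0.00000	0.00000
11	**0.07079**	**0.08809**	**0.06769**	**0.10550**	**0.06741**	**0.08927**	**0.08290**	0.00370	**0.11759**	**0.09390**	*	0.00000	0.00000	0.00000	0.00000	0.00000	0.00000	0.00000	0.00000
12	0.00330	0.01551	0.00160	0.00388	**0.02759**	0.00007	0.02820	**0.12204**	**0.02451**	**0.15260**	**0.08956**	*	0.00000	0.11712	0.02703	0.32432	0.00000	0.65766	0.21622
13	**0.14807**	**0.23293**	**0.18028**	**0.23578**	**0.17993**	**0.20826**	**0.21701**	**0.06111**	**0.17269**	**0.27009**	**0.09414**	**0.18389**	*	0.00000	0.00000	0.00000	0.00000	0.00000	0.00000
14	0.01296	0.02628	0.00139	0.01109	**0.03937**	0.01497	**0.06095**	**0.18813**	**0.03761**	**0.14899**	**0.12947**	0.01596	**0.26063**	*	0.00000	0.13514	0.36036	0.17117	0.05405
15	**0.01956**	0.00226	**0.04947**	**0.05078**	**0.03974**	**0.05037**	0.00212	**0.10012**	**0.09713**	**0.14016**	**0.07384**	**0.02067**	**0.15662**	**0.08589**	*	0.05405	0.00000	0.00000	0.00000
16	0.00951	0.00913	0.00820	0.01160	**0.03557**	0.00234	0.02678	**0.09135**	**0.05386**	**0.12811**	**0.05317**	0.00447	**0.17365**	0.01548	0.02512	*	0.04505	0.05405	0.32432
17	**0.02346**	0.02467	0.02216	0.00195	**0.05666**	0.00363	**0.04190**	**0.22266**	**0.08261**	**0.15873**	**0.15665**	**0.03069**	**0.28530**	0.00153	**0.07600**	**0.03095**	*	0.04505	0.00000
18	0.01369	0.00114	0.01694	0.01092	**0.06220**	0.00609	**0.06427**	**0.19184**	**0.02947**	**0.20906**	**0.14997**	0.00629	**0.25551**	0.00986	**0.06233**	0.02596	**0.01785**	*	0.19820
19	0.01050	0.00383	0.01526	**0.03582**	**0.07232**	0.01602	**0.07454**	**0.10011**	**0.04560**	**0.18122**	**0.07716**	0.00712	**0.17245**	0.03326	**0.05567**	0.00152	**0.04837**	0.01241	*
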