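# class: Obese young males
locus	normal	mutant	haplogroup
2626	T	C	M7a1a
2772	C	T	M7a1a
4386	T	C	M7a1a
4958	A	G	M7a1a
6455	C	T	M7a1a
12771	G	A	M7a1a
16209	T	C	M7a1a
16324	T	C	M7a1a
150	C	T	M7b2
199	T	C	M7b2
4048	G	A	M7b2
4071	C	T	M7b2
4164	A	G	M7b2
5351	A	G	M7b2
5460	G	A	M7b2
6455	C	T	M7b2
6680	T	C	M7b2
7684	T	C	M7b2
7853	G	A	M7b2
10345	T	C	M7b2
12405	C	T	M7b2
12811	T	C	M7b2
16129	G	A	M7b2
16297	T	C	M7b2
16298	T	C	M7b2
16519	T	C	M7b2
194	C	T	D4b2b
1382	A	C	D4b2b
3010	G	A	D4b2b
4883	C	T	D4b2b
5178	C	A	D4b2b
8020	G	A	D4b2b
8964	C	T	D4b2b
9296	C	T	D4b2b
9824	T	A	D4b2b
14668	C	T	D4b2b
16362	T	C	D4b2b
16519	T	C	D4b2b
709	G	A	B4c1
1119	T	C	B4c1
3497	C	T	B4c1
12705	C	T	B4c1
15346	G	A	B4c1
16217	T	C	B4c1
16223	C	T	B4c1
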