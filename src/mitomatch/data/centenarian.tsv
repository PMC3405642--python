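# class: Centenarians
locus	normal	mutant	haplogroup
150	C	T	M7b2
204	T	C	M7b2
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
199	T	C	D4b2a
1382	A	C	D4b2a
3010	G	A	D4b2a
4883	C	T	D4b2a
5178	C	A	D4b2a
8020	G	A	D4b2a
8251	G	A	D4b2a
8414	C	T	D4b2a
8964	C	T	D4b2a
9824	T	A	D4b2a
9824	T	C	D4b2a
10104	C	T	D4b2a
14668	C	T	D4b2a
16362	T	C	D4b2a
16519	T	C	D4b2a
709	G	A	B5b
1598	G	A	B5b
8584	G	A	B5b
8829	C	T	B5b
9950	T	C	B5b
12361	A	G	B5b
12705	C	T	B5b
15223	C	T	B5b
15508	C	T	B5b
15662	A	G	B5b
15851	A	G	B5b
15927	G	A	B5b
16140	T	C	B5b
16223	C	T	B5b
16243	T	C	B5b
16519	T	C	B5b
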