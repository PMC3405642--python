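# class: Non-obese young males
locus	normal	mutant	haplogroup
194	C	T	D4b2b
1382	A	C	D4b2b
4883	C	T	D4b2b
5178	C	A	D4b2b
8020	G	A	D4b2b
8964	C	T	D4b2b
9296	C	T	D4b2b
9824	T	A	D4b2b
14668	C	T	D4b2b
16362	T	C	D4b2b
16519	T	C	D4b2b
3010	G	A	D4g
4343	A	G	D4g
4883	C	T	D4g
5178	C	A	D4g
8414	C	T	D4g
8701	A	G	D4g
13104	A	G	D4g
14668	C	T	D4g
15518	C	T	D4g
16278	C	T	D4g
16362	T	C	D4g
16519	T	C	D4g
827	A	G	B4b/d/e
12705	C	T	B4b/d/e
15535	C	T	B4b/d/e
16217	T	C	B4b/d/e
16223	C	T	B4b/d/e
16519	T	C	B4b/d/e
150	C	T	N9a
5231	G	A	N9a
5417	G	A	N9a
12358	A	G	N9a
12372	G	A	N9a
16257	C	A	N9a
16261	C	T	N9a
16519	T	C	N9a
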