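# class: T2D patients
locus	normal	mutant	haplogroup
4715	A	G	M8a
6179	G	A	M8a
7196	C	A	M8a
8584	G	A	M8a
8684	C	T	M8a
14470	T	C	M8a
15487	A	T	M8a
16298	T	C	M8a
16319	G	A	M8a
16519	T	C	M8a
194	C	T	D4b2b
1382	A	C	D4b2b
3010	G	A	D4b2b
4883	C	T	D4b2b
5178	C	A	D4b2b
8020	G	A	D4b2b
8414	C	T	D4b2b
8964	C	T	D4b2b
9296	C	T	D4b2b
9824	T	A	D4b2b
14605	A	G	D4b2b
14668	C	T	D4b2b
16519	T	C	D4b2b
204	T	C	B5b
709	G	A	B5b
1598	G	A	B5b
8584	G	A	B5b
8829	C	T	B5b
9950	T	C	B5b
12361	A	G	B5b
15223	C	T	B5b
15508	C	T	B5b
15662	A	G	B5b
15851	A	G	B5b
15927	G	A	B5b
16140	T	C	B5b
16243	T	C	B5b
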