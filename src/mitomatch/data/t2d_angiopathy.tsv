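# class: T2D patients with angiopathy
locus	normal	mutant	haplogroup
709	G	A	G2a
4833	A	G	G2a
5108	T	C	G2a
5601	C	T	G2a
7600	G	A	G2a
9377	A	G	G2a
9575	G	A	G2a
13563	A	G	G2a
14569	G	A	G2a
16278	C	T	G2a
16362	T	C	G2a
16519	T	C	G2a
3010	G	A	D4b1
4883	C	T	D4b1
5178	C	A	D4b1
8020	G	A	D4b1
8414	C	T	D4b1
10181	C	T	D4b1
14668	C	T	D4b1
15440	T	C	D4b1
15951	A	G	D4b1
16319	G	A	D4b1
16362	T	C	D4b1
16519	T	C	D4b1
150	C	T	N9a2
5231	G	A	N9a2
5417	G	A	N9a2
12358	A	G	N9a2
12372	G	A	N9a2
16172	T	C	N9a2
16257	C	A	N9a2
16261	C	T	N9a2
16519	T	C	N9a2
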