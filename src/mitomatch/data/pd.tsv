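# class: PD patients
locus	normal	mutant	haplogroup
2626	T	C	M7a1a
2772	C	T	M7a1a
4386	T	C	M7a1a
4958	A	G	M7a1a
11017	T	C	M7a1a
11084	A	G	M7a1a
12771	G	A	M7a1a
14364	G	A	M7a1a
16324	T	C	M7a1a
16519	T	C	M7a1a
150	C	T	G1a
7867	C	T	G1a
8020	G	A	G1a
15323	G	A	G1a
16209	T	C	G1a
204	T	C	B5b
709	G	A	B5b
1598	G	A	B5b
8584	G	A	B5b
9950	T	C	B5b
12358	A	G	B5b
12361	A	G	B5b
15223	C	T	B5b
15851	A	G	B5b
15927	G	A	B5b
16140	T	C	B5b
16243	T	C	B5b
150	C	T	N9a
5231	G	A	N9a
5417	G	A	N9a
12372	G	A	N9a
16257	C	A	N9a
16261	C	T	N9a
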