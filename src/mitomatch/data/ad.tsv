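# class: AD patients
locus	normal	mutant	haplogroup
709	G	A	G2a
4833	A	G	G2a
5108	T	C	G2a
5601	C	T	G2a
7600	G	A	G2a
9377	A	G	G2a
9575	G	A	G2a
13563	A	G	G2a
14200	T	C	G2a
14569	G	A	G2a
16278	C	T	G2a
16362	T	C	G2a
16519	T	C	G2a
5147	G	A	N9b1
5417	G	A	N9b1
10607	C	T	N9b1
11016	G	A	N9b1
13183	A	G	N9b1
14893	A	G	N9b1
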