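# class: Semi-supercentenarians
locus	normal	mutant	haplogroup
195	T	C	M1
16249	T	C	M1
16311	T	C	M1
709	G	A	B4c1a
1119	T	C	B4c1a
1621	T	C	B4c1a
3497	C	T	B4c1a
10310	G	A	B4c1a
12705	C	T	B4c1a
15346	G	A	B4c1a
16217	T	C	B4c1a
16223	C	T	B4c1a
16311	T	C	B4c1a
16519	T	C	B4c1a
150	C	T	B4c1b1
1119	T	C	B4c1b1
1621	T	C	B4c1b1
3497	C	T	B4c1b1
12705	C	T	B4c1b1
16140	T	C	B4c1b1
16217	T	C	B4c1b1
16223	C	T	B4c1b1
16274	G	A	B4c1b1
16519	T	C	B4c1b1
150	C	T	B4c1c1
195	T	C	B4c1c1
1119	T	C	B4c1c1
1621	T	C	B4c1c1
10398	A	G	B4c1c1
12705	C	T	B4c1c1
16217	T	C	B4c1c1
16223	C	T	B4c1c1
16519	T	C	B4c1c1
3970	C	T	F1
6392	T	C	F1
6962	G	A	F1
10310	G	A	F1
10609	G	A	F1
12406	G	A	F1
12705	C	T	F1
12802	C	T	F1
13928	G	C	F1
16223	C	T	F1
16519	T	C	F1
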