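position	base	A	C	G	T
0	A	1	0	0	0
0	C	0	1	0	0
0	G	0	0	1	0
0	T	0	0	0	1
1	A	1	0	0	0
1	C	0	1	0	0
1	G	0	0	1	0
1	T	0	0	0	1
2	A	1	0	0	0
2	C	0	1	0	0
2	G	0	0	1	0
2	T	0	0	0	1
3	A	1	0	0	0
3	C	0	1	0	0
3	G	0	0	1	0
3	T	0	0	0	1
4	A	1	0	0	0
4	C	0	1	0	0
4	G	0	0	1	0
4	T	0	0	0	1
5	A	1	0	0	0
5	C	0	1	0	0
5	G	0	0	1	0
5	T	0	0	0	1
6	A	1	0	0	0
6	C	0	1	0	0
6	G	0	0	1	0
6	T	0	0	0	1
7	A	1	0	0	0
7	C	0	1	0	0
7	G	0	0	1	0
7	T	0	0	0	1
8	A	1	0	0	0
8	C	0	1	0	0
8	G	0	0	1	0
8	T	0	0	0	1
9	A	1	0	0	0
9	C	0	1	0	0
9	G	0	0	1	0
9	T	0	0	0	1
10	A	0.9618	0.0253	0.0019	0.011
10	C	0.002	0.9932	0.0008	0.004
10	G	0.0012	0.003	0.976	0.0198
10	T	0.0009	0.0018	0.0013	0.996
11	A	1	0	0	0
11	C	0	1	0	0
11	G	0	0	1	0
11	T	0	0	0	1
12	A	1	0	0	0
12	C	0	1	0	0
12	G	0	0	1	0
12	T	0	0	0	1
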