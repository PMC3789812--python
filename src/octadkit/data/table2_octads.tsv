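ascus	spore	viable	mat1	ade6	ura4	mrc1
1	A	1	M	-	-	-
1	B	1	M	-	-	-
1	C	1	P	+	+	-
1	D	1	M	-	+	+
1	E	1	P	+	+	-
1	F	1	M	-	+	+
1	G	1	P	+	-	+
1	H	1	P	+	-	+
2	A	1	P	+	+	+
2	B	1	P	+	-	-
2	C	1	P	+	+	+
2	D	1	P	+	-	-
2	E	0	M	-	+	-
2	F	1	M	-	-	+
2	G	1	M	-	-	+
2	H	1	M	-	+	-
3	A	1	M	-	+	-
3	B	0	M	-	+	-
3	C	1	M	-	-	-
3	D	1	P	+	-	+
3	E	1	M	-	-	-
3	F	1	P	+	-	+
3	G	1	P	+	+	+
3	H	1	P	+	+	+
4	A	1	M	+	+	-
4	B	1	M	+	-	+
4	C	1	M	+	+	-
4	D	1	P	-	-	+
4	E	1	M	+	-	+
4	F	1	P	-	-	+
4	G	1	P	-	+	-
4	H	1	P	-	+	-
5	A	1	M	+	+	+
5	B	1	P	-	+	+
5	C	0	M	+	+	+
5	D	1	M	+	-	-
5	E	1	P	-	+	+
5	F	1	P	-	-	-
5	G	1	M	+	-	-
5	H	1	P	-	-	-
6	A	1	P	-	-	+
6	B	1	P	-	-	+
6	C	1	P	-	-	+
6	D	1	P	-	-	+
6	E	1	M	+	+	-
6	F	1	M	+	+	-
6	G	1	M	+	+	-
6	H	1	M	+	+	-
7	A	1	M	+	-	+
7	B	1	M	+	-	+
7	C	1	M	+	-	+
7	D	1	M	+	-	+
7	E	1	P	-	+	-
7	F	1	P	-	+	-
7	G	1	P	-	+	-
7	H	1	P	-	+	-
8	A	1	P	-	+	-
8	B	1	M	+	-	+
8	C	0	P	-	+	+
8	D	1	M	+	-	-
8	E	1	P	-	+	+
8	F	1	M	+	-	-
8	G	1	M	+	-	+
8	H	1	P	-	+	-
9	A	1	P	-	+	-
9	B	1	P	-	+	-
9	C	1	P	-	+	+
9	D	1	P	-	+	+
9	E	1	M	+	-	+
9	F	1	M	+	-	-
9	G	1	M	+	-	+
9	H	1	M	+	-	-
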