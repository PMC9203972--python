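rank	count	seq	family
1	9295	TCCGATGTAGT	mRNA fragment
2	8150	AGGCTTGTAGCTC	tRNA-Ile
3	7776	TCCGATGTAGTGTA	mRNA fragment
4	7729	GCGGATTTAGTTA	mRNA fragment
5	6509	AGGCTTGTAGCTT	tRNA-Ile
6	5062	AGGCTTGTAGCTA	tRNA-Ile
7	3918	ATTCGGGTCTTGTA	mRNA fragment
8	3632	TTCGGGTCTTGTA	mRNA fragment
9	3429	TAAGGAGTGTGTA	mRNA fragment
10	3428	CTTGTGGCGTA	mRNA fragment
11	3372	TCCGATGTAGC	mRNA fragment
12	3017	TCCGATGTAG	mRNA fragment
13	2810	TCCGATGTAGTGT	mRNA fragment
14	2733	CATTCGGGTCTTGTA	mRNA fragment
15	2693	AATTCCTAGTA	mRNA fragment
16	2611	GGGGCTATAGCTC	tRNA-Ala
17	2605	TTGGCGGA	No hit
18	2572	TCCGATGTAA	mRNA fragment
19	2560	TCCGATGTAGA	mRNA fragment
20	2498	CTAAGGAGTGTGTA	No hit
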