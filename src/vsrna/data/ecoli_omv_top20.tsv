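rank	count	seq	family
1	78450	AGGCTTGTAGCTC	tRNA-Ile
2	73912	AGGCTTGTAGCTT	tRNA-Ile
3	23705	AGGCTTGTAGCTA	tRNA-Ile
4	22218	GGGGCTATAGCTC	tRNA-Ala
5	22074	GGGTCTGTAGCTT	23S rRNA
6	21957	GGGTCTGTAGCTC	23S rRNA pseudouridylate synthase B
7	18375	GGGGCTATAGCTT	tRNA-Ala
8	12052	CCGGGAGGAGCTCT	mRNA fragment
9	8594	ACTAGGGATCGGGTG	mRNA fragment
10	7661	CTCTTGTAGACCGTT	mRNA fragment
11	7024	GGGTCTGTAGCTA	23S rRNA pseudouridylate synthase B
12	6184	CGGCACGTAGCGT	tRNA-Pro
13	6044	GGGGCTATAGCTA	tRNA-Ala
14	5508	CTAGGGATCGGGTG	mRNA fragment
15	5280	CGAGACCTTAACCT	mRNA fragment
16	4318	ACCAGGAGTGGAGCT	mRNA fragment
17	4301	AGGCTTGTAGCT	tRNA-Ile
18	4278	CGGCACGTAGCGC	tRNA-Pro
19	4023	CCGGGAGGAGCTCA	mRNA fragment
20	3202	GCTGGCTCCGG	rRNA small subunit methyltranserase D
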