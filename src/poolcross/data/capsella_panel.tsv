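amplicon_id	direction	het_base	tail_seq	gene_seq
1	forward		TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG	CCACTCATCCATTCGGAAAT
1	forward	A	TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG	CCACTCATCCATTCGGAAAT
1	reverse		GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG	TTGGGGACAAGGTGCTAATC
1	reverse	A	GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG	TTGGGGACAAGGTGCTAATC
2	forward		TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG	TACCGACCACATAGGCATCA
2	forward	T	TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG	TACCGACCACATAGGCATCA
2	reverse		GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG	AATGGCCGATTCTGCTTTTA
2	reverse	T	GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG	AATGGCCGATTCTGCTTTTA
3	forward		TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG	CAAGCCAAAGTTTGATGCTT
3	forward	A	TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG	CAAGCCAAAGTTTGATGCTT
3	reverse		GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG	ACTCGTCTGCAGTCATGGTG
3	reverse	A	GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG	ACTCGTCTGCAGTCATGGTG
4	forward		TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG	GGAAGCGGATGGTTACAAAA
4	forward	T	TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG	GGAAGCGGATGGTTACAAAA
4	reverse		GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG	AGGCCAAGCTCACTCACATT
4	reverse	T	GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG	AGGCCAAGCTCACTCACATT
5	forward		TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG	TGGGTTCAGATTGAGCGTAA
5	forward	A	TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG	TGGGTTCAGATTGAGCGTAA
5	reverse		GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG	AACTTGATCCTCTTTGGTACTGG
5	reverse	A	GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG	AACTTGATCCTCTTTGGTACTGG
6	forward		TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG	TTCTTTTTCTGAGATTCCATTGCT
6	forward	T	TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG	TTCTTTTTCTGAGATTCCATTGCT
6	reverse		GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG	AGAAGCCTCTCCTGAGAAGTGA
6	reverse	T	GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG	AGAAGCCTCTCCTGAGAAGTGA
7	forward		TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG	TCCAAGATCTGTGCTTGCTG
7	forward	A	TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG	TCCAAGATCTGTGCTTGCTG
7	reverse		GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG	TCAGCTCCGGATGGTTAAAT
7	reverse	A	GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG	TCAGCTCCGGATGGTTAAAT
8	forward		TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG	TTTCAAAAGCTTTGCGTGAG
8	forward	T	TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG	TTTCAAAAGCTTTGCGTGAG
8	reverse		GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG	GATGCTTCACGTTCACACCA
8	reverse	T	GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG	GATGCTTCACGTTCACACCA
9	forward		TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG	GTTCTATCCAAGGGCCATCA
9	forward	A	TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG	GTTCTATCCAAGGGCCATCA
9	reverse		GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG	CCCATGGAAACTCCTTGTTG
9	reverse	A	GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG	CCCATGGAAACTCCTTGTTG
10	forward		TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG	GATCCGTCGGCTCTTCTCTC
10	reverse		GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG	AACCATGCCAATGCTTCATA
11	forward		TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG	GGAGCAAGTCCCAAACAAAG
11	forward	T	TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG	GGAGCAAGTCCCAAACAAAG
11	reverse		GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG	CATTTCAAGCCGCTCTGG
11	reverse	T	GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG	CATTTCAAGCCGCTCTGG
12	forward		TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG	TGCATTCGATCTCGATCTTG
12	forward	A	TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG	TGCATTCGATCTCGATCTTG
12	reverse		GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG	CGGTGGTGAAGACAACAATC
12	reverse	A	GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG	CGGTGGTGAAGACAACAATC
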