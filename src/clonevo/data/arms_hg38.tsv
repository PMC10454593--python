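# Approximate hg38 chromosome arm spans (1-based inclusive), centromere split rounded to 0.1 Mb.
# Acrocentric p-arms (13,14,15,21,22) are retained for completeness.
chrom	start	end	name
chr1	1	123400000	1p
chr1	123400001	248956422	1q
chr2	1	93900000	2p
chr2	93900001	242193529	2q
chr3	1	90900000	3p
chr3	90900001	198295559	3q
chr4	1	50000000	4p
chr4	50000001	190214555	4q
chr5	1	48800000	5p
chr5	48800001	181538259	5q
chr6	1	59800000	6p
chr6	59800001	170805979	6q
chr7	1	60100000	7p
chr7	60100001	159345973	7q
chr8	1	45200000	8p
chr8	45200001	145138636	8q
chr9	1	43000000	9p
chr9	43000001	138394717	9q
chr10	1	39800000	10p
chr10	39800001	133797422	10q
chr11	1	53400000	11p
chr11	53400001	135086622	11q
chr12	1	35500000	12p
chr12	35500001	133275309	12q
chr13	1	17700000	13p
chr13	17700001	114364328	13q
chr14	1	17200000	14p
chr14	17200001	107043718	14q
chr15	1	19000000	15p
chr15	19000001	101991189	15q
chr16	1	36800000	16p
chr16	36800001	90338345	16q
chr17	1	25100000	17p
chr17	25100001	83257441	17q
chr18	1	18500000	18p
chr18	18500001	80373285	18q
chr19	1	26200000	19p
chr19	26200001	58617616	19q
chr20	1	28100000	20p
chr20	28100001	64444167	20q
chr21	1	12000000	21p
chr21	12000001	46709983	21q
chr22	1	15000000	22p
chr22	15000001	50818468	22q
chrX	1	61000000	Xp
chrX	61000001	156040895	Xq
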