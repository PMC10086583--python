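chrom	length	cen_start	cen_end
chr1	248956422	121700000	125100000
chr2	242193529	91800000	96000000
chr3	198295559	87800000	94000000
chr4	190214555	48200000	51800000
chr5	181538259	46100000	50100000
chr6	170805979	58500000	62600000
chr7	159345973	58100000	61500000
chr8	145138636	43200000	47200000
chr9	138394717	42200000	45500000
chr10	133797422	38000000	41600000
chr11	135086622	51000000	55800000
chr12	133275309	34700000	38200000
chr13	114364328	16000000	18900000
chr14	107043718	16100000	18200000
chr15	101991189	17500000	20500000
chr16	90338345	35300000	38400000
chr17	83257441	22700000	27400000
chr18	80373285	15400000	21500000
chr19	58617616	24200000	28100000
chr20	64444167	25700000	30400000
chr21	46709983	10900000	13000000
chr22	50818468	13700000	17400000
chrX	156040895	58100000	63800000
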