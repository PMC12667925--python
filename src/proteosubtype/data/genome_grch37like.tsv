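chrom	length_bp	centromere_start_bp	centromere_end_bp	is_autosome
chr1	249250621	121500000	128900000	1
chr2	243199373	90500000	96800000	1
chr3	198022430	87900000	93900000	1
chr4	191154276	48200000	52700000	1
chr5	180915260	46100000	50700000	1
chr6	171115067	58700000	63300000	1
chr7	159138663	58000000	61700000	1
chr8	146364022	43100000	48100000	1
chr9	141213431	47300000	50700000	1
chr10	135534747	38000000	42300000	1
chr11	135006516	51600000	55700000	1
chr12	133851895	33300000	38200000	1
chr13	115169878	16300000	19500000	1
chr14	107349540	16100000	19100000	1
chr15	102531392	15800000	20700000	1
chr16	90354753	34600000	38600000	1
chr17	81195210	22200000	25800000	1
chr18	78077248	15400000	19000000	1
chr19	59128983	24400000	28600000	1
chr20	63025520	25600000	29400000	1
chr21	48129895	10900000	14300000	1
chr22	51304566	12200000	17900000	1
chrX	155270560	58100000	63000000	0
chrY	59373566	11600000	13400000	0
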