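gene_id	chrom	strand	tss	gene_end
g00001	chr1	+	1208	2208
g00002	chr1	-	3222	2222
g00003	chr1	-	5310	4310
g00004	chr1	+	7495	8495
g00005	chr1	+	9422	10422
g00006	chr1	-	11633	10633
g00007	chr1	+	13679	14679
g00008	chr1	+	15802	16802
g00009	chr1	-	18001	17001
g00010	chr1	-	19915	18915
g00011	chr1	+	22069	23069
g00012	chr1	+	24270	25270
g00013	chr2	+	1088	2088
g00014	chr2	+	3113	4113
g00015	chr2	-	5394	4394
g00016	chr2	+	7385	8385
g00017	chr2	+	9492	10492
g00018	chr2	+	11628	12628
g00019	chr2	-	13629	12629
g00020	chr2	+	15723	16723
g00021	chr2	-	17939	16939
g00022	chr2	-	19919	18919
g00023	chr2	-	22101	21101
g00024	chr2	+	24262	25262
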