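chrom	start_1based	end_1based	locus_name	tag_snp
chr15	30782050	30841010	15q13	rs4779584
chr10	8730000	8810000	10p14	rs10795668
chr11	110640000	110690000	11q23	rs3802842
chr14	53477192	53494200	14q22	rs4444235
chr16	67286613	67396803	16q22	rs9929218
chr19	38203614	38300573	19q13	rs10411210
chr20	6316089	6354440	20p12	rs961253
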