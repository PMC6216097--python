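# Candidate-gene fixture for the chr8 QTL support interval [3.5, 16.7] Mb.
# Gene symbols and evidence flags follow the published evidence lists;
# coordinates are SYNTHETIC placements inside the interval (no per-gene
# coordinates are published); extra rows exercise interval/variant filters.
symbol	chrom	start_mb	end_mb	coding_variant	cis_eqtl	trait_correlated	prior_phenotype
2900016B01Rik	8	3.689	3.989	1	1	1	0
Abhd13	8	4.631	4.931	1	1	0	1
Arhgef10	8	5.574	5.874	1	1	1	1
Arhgef7	8	6.517	6.817	1	0	0	1
Cln8	8	7.46	7.76	1	0	0	1
Col4a1	8	8.403	8.703	1	0	0	1
Col4a2	8	9.346	9.646	1	0	0	1
Csmd1	8	10.289	10.589	1	1	1	1
Dlgap2	8	11.231	11.531	1	1	1	1
Fam155a	8	12.174	12.474	1	0	0	1
Kbtbd11	8	13.117	13.417	1	1	1	0
Myom2	8	14.06	14.36	1	0	1	1
Tfdp1	8	15.003	15.303	1	0	0	1
SynGeneD	8	5.0	5.2	0	0	0	0
SynGeneE	8	1.0	2.9	1	0	0	0
SynGeneF	8	17.0	17.4	1	0	0	0
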