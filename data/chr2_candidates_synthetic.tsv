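# Candidate-gene fixture for the chr2 QTL support interval [179.5, 180.8] Mb.
# Gene symbols and evidence flags follow the published evidence lists;
# coordinates are SYNTHETIC placements inside the interval (no per-gene
# coordinates are published); extra rows exercise interval/variant filters.
symbol	chrom	start_mb	end_mb	coding_variant	cis_eqtl	trait_correlated	prior_phenotype
1600027N09Rik	2	179.514	179.539	1	1	0	0
Adrm1	2	179.587	179.611	1	0	0	1
Bhlhe23	2	179.659	179.683	1	0	0	1
Cdh4	2	179.731	179.756	1	0	0	1
Col9a3	2	179.803	179.828	1	0	0	1
Dido1	2	179.876	179.9	1	1	0	1
Gtpbp5	2	179.948	179.972	1	1	1	0
Lama5	2	180.02	180.044	1	1	0	1
Ntsr1	2	180.092	180.117	1	0	0	1
Ogfr	2	180.164	180.189	1	1	1	0
Osbpl2	2	180.237	180.261	1	1	0	1
Psma7	2	180.309	180.333	1	0	0	1
Slc17a9	2	180.381	180.406	1	0	1	1
Slco4a1	2	180.453	180.478	1	0	1	0
Ss18l1	2	180.526	180.55	1	1	0	1
Taf4	2	180.598	180.622	1	0	0	1
Tcfl5	2	180.67	180.694	1	1	0	0
SynGeneA	2	179.6	179.7	0	0	0	0
SynGeneB	2	178.0	179.0	1	0	0	0
SynGeneC	2	181.2	181.5	1	0	0	0
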