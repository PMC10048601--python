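gene	high_n	moderate_n	polymorphic_region	qtl	protein_function
Solyc01g009580	1	5	p1_3	-	Terminal flower 1
Solyc01g056310	0	2	p1_2	-	Anther-specific LAT51
Solyc01g066680	0	2	p1_5	-	Pollen Ole e 1 allergen and extensin family protein
Solyc01g066770	0	2	p1_5	-	Chaperone protein DnaJ 49
Solyc01g067780	0	14	p1_5	-	DnaJ domain
Solyc01g079610	0	1	p1_5	FLN1.1; qCC-1-4	DnaJ protein ERDJ3B
Solyc01g079640	0	1	p1_5	FLN1.1; qCC-1-4	Pollen-specific LRR extensin-like protein
Solyc01g086740	0	1	p1_5	FLN1.1; qCC-1-4	Chaperone protein DnaJ
Solyc01g088730	0	1	p1_5	FLN1.1; qREC-1-3; qCC-1-5	DnaJ domain-containing protein
Solyc02g088610	0	4	p2_1	Q-fcsa01; Q-fpt01; Q-md01	LeHSP110/ClpB heat shock protein
Solyc02g093600	1	2	-	FLN2.2; Q-flnS01	Class I heat shock protein
Solyc03g122230	0	3	-	Q-flnS02	Pollen receptor-like kinase 3
Solyc04g026280	0	2	p4_1	-	S1 self-incompatibility locus-linked pollen 3.15 protein
Solyc04g076270	0	1	p4_3	-	DnaJ domain-containing protein
Solyc04g077430	0	2	p4_3	-	Chaperone protein DnaJ
Solyc05g050820	0	3	-	FLN5.3	DnaJ homolog
Solyc05g051140	0	3	-	FLN5.3	Protein FLOWERING locus D-like protein
Solyc05g053760	2	0	p5_1	-	Chaperone protein DnaJ
Solyc05g053850	0	5	p5_1	-	Protein FLOWERING LOCUS T
Solyc05g055660	1	1	p5_1	-	Flowering locus T
Solyc07g021000	0	2	p7_1	-	FlowERING LOCUS D
Solyc07g026810	0	2	p7_2	-	Chaperone protein DnaJ
Solyc07g039220	2	12	p7_3	-	DNAJ heat shock N-terminal domain-containing protein
Solyc07g043560	0	2	p7_4	-	Heat shock protein 70 kDa
Solyc07g047690	0	3	p7_4	-	DnaJ domain-containing protein
Solyc07g053615	1	0	p7_4	-	DnaJ like protein
Solyc07g055710	0	1	p7_4	-	Heat stress transcription factor A-5
Solyc07g055720	0	1	p7_4	-	Heat shock protein 20
Solyc07g065970	0	1	p7_4	Q-fo02_03; Q-fo02_04	Chaperone protein DnaJ
Solyc07g066290	0	1	p7_4	Q-fo02_04	Chaperone DnaJ-domain containing protein
Solyc11g005400	0	1	p11_1	-	DnaJ domain
Solyc11g008650	1	1	p11_1	Q-fo01_05; Q_fo02_06	Flowering locus T1
Solyc12g042560	0	1	p12_2	-	Heat shock 70 kDa protein
Solyc12g042830	0	1	p12_2	-	Class I heat shock protein
Solyc12g043120	0	10	p12_2	-	Heat shock protein 70 family
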