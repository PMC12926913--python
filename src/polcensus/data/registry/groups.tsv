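group_id	family_id	domains	motifs	clamp_region	anchor_refs	notes
PolA1	A	FEN-exo,DnaQ-exo,core_A	FEN_AS:required,DEDDy:typical,POL_AS_A:required	.	PolA1_r1,PolA1_r2,PolA1_r3	Pol I orthologs; canonical three-domain architecture
PolA1-like	A	DnaQ-exo,core_A	DEDDy:typical,POL_AS_A:required	.	PolA1-like_r1,PolA1-like_r2,PolA1-like_r3	minor group replacing canonical Pol I; lacks the 5'-3' exonuclease domain
PolA2	A	DnaQ-exo,core_A	DEDDy:inactive,POL_AS_A:required,CLAMP:required	exo_loop	PolA2_r1,PolA2_r2,PolA2_r3	actinobacterial group with vestigial proofreading domain carrying a beta-clamp motif
PolA3	A	DnaQ-exo,core_A	DEDDy:required,POL_AS_A:required	.	PolA3_r1,PolA3_r2,PolA3_r3	phage-related accessory group with intact proofreader
G1	B	DnaQ-exo,core_B	DEDDy:required,POL_AS_B:required,CLAMP:typical	cterm_third	G1_r1,G1_r2,G1_r3	Pol II orthologs; largest B-family group
G2	B	DnaQ-exo,core_B	DEDDy:inactive,POL_AS_B:required	.	G2_r1,G2_r2,G2_r3	PolB2-derived TLS group; proofreading domain inactivated
G3	B	DnaQ-exo,core_B	DEDDy:required,POL_AS_B:required,CLAMP:typical	cterm_third	G3_r1,G3_r2,G3_r3	group related to the N-terminal half of eukaryotic Pol epsilon
G4	B	DnaQ-exo,core_B	DEDDy:typical,POL_AS_B:required	.	G4_r1,G4_r2,G4_r3	minor group
G5	B	DnaQ-exo,core_B	DEDDy:typical,POL_AS_B:required	.	G5_r1,G5_r2,G5_r3	minor group
G6	B	DnaQ-exo,core_B	DEDDy:typical,POL_AS_B:required	.	G6_r1,G6_r2,G6_r3	minor group
G7	B	DnaQ-exo,core_B	DEDDy:typical,POL_AS_B:required	.	G7_r1,G7_r2,G7_r3	minor group
G8	B	DnaQ-exo,core_B	DEDDy:typical,POL_AS_B:required	.	G8_r1,G8_r2,G8_r3	minor group
PolC	C	PHP,DnaQ-exo,core_C,OB	PHP_AS:typical,DEDDh:required,POL_AS_C:required	.	PolC_r1,PolC_r2,PolC_r3	replicative alpha-subunit with embedded DnaQ exonuclease
DnaE1	C	PHP,core_C,OB,CTD	PHP_AS:typical,POL_AS_C:required	.	DnaE1_r1,DnaE1_r2,DnaE1_r3	replicative alpha-subunit; E. coli Pol III type
DnaE3	C	PHP,core_C,OB,CTD	PHP_AS:inactive,POL_AS_C:required	.	DnaE3_r1,DnaE3_r2,DnaE3_r3	replicative alpha-subunit co-occurring with PolC; PHP typically inactive
DnaE2A	C	PHP,core_C,OB	PHP_AS:inactive,POL_AS_C:required	.	DnaE2A_r1,DnaE2A_r2,DnaE2A_r3	error-prone group partnered with ImuA and ImuB
DnaE2B	C	PHP,core_C,OB	PHP_AS:inactive,POL_AS_C:required	.	DnaE2B_r1,DnaE2B_r2,DnaE2B_r3	error-prone group associated with PolY/iPolY and RecA
DnaE2X	C	PHP,core_C,OB	PHP_AS:inactive,POL_AS_C:required	.	DnaE2X_r1,DnaE2X_r2,DnaE2X_r3	small diverse error-prone group; split-ImuB architecture
PolX1	X	8kDa,core_X,PHP	POL_AS_X:required,PHP_AS:required	.	PolX1_r1,PolX1_r2,PolX1_r3	typical bacterial PolX with PHP exonuclease
PolX2	X	core_X,CTD	POL_AS_X:required	.	PolX2_r1,PolX2_r2,PolX2_r3	novel group lacking PHP; extra C-terminal domain
PolX-like	X	PHP	PHP_AS:required	.	PolX-like_r1,PolX-like_r2,PolX-like_r3	close PolX1 homologs lacking the entire polymerase domain
PolY-core	Y	core_Y,LF	POL_AS_Y:required,RecA_NT:partial	.	PolY-core_r1,PolY-core_r2,PolY-core_r3	central group of DinB orthologs; mixed interaction-motif pattern
UmuC	Y	core_Y,LF	POL_AS_Y:required,RecA_NT:required,CLAMP:typical	cterm_third	UmuC_r1,UmuC_r2,UmuC_r3	Pol V catalytic subunit lineage
YqjW	Y	core_Y,LF	POL_AS_Y:required,RecA_NT:required	.	YqjW_r1,YqjW_r2,YqjW_r3	YqjW/UvrX lineage partnered with YqjX-like small subunits
DinP	Y	core_Y,LF	POL_AS_Y:required,RecA_NT:absent	.	DinP_r1,DinP_r2,DinP_r3	actinobacterial group without interaction motifs
DinX	Y	core_Y,LF,Tudor	POL_AS_Y:required,RecA_NT:absent	.	DinX_r1,DinX_r2,DinX_r3	actinobacterial group with C-terminal Tudor domain
scDinB2-like	Y	core_Y,LF	POL_AS_Y:inactive,RecA_NT:required	.	scDinB2-like_r1,scDinB2-like_r2,scDinB2-like_r3	inactive PolY (iPolY) of Streptomyces DinB2 type
gbDinB2-like	Y	core_Y,LF	POL_AS_Y:inactive,RecA_NT:required	.	gbDinB2-like_r1,gbDinB2-like_r2,gbDinB2-like_r3	inactive PolY (iPolY) of G. bemidjiensis DinB2 type
ImuB1	Y	core_Y,LF,ImuB-C	POL_AS_Y:inactive,RecA_NT:required	.	ImuB1_r1,ImuB1_r2,ImuB1_r3	inactive PolY with ImuB-C domain; proteobacterial type
ImuB2	Y	core_Y,LF,ImuB-C	POL_AS_Y:inactive,RecA_NT:required	.	ImuB2_r1,ImuB2_r2,ImuB2_r3	inactive PolY with ImuB-C domain; actinobacterial type
ImuBx	Y	core_Y,LF,ImuB-C	POL_AS_Y:inactive,RecA_NT:required	.	ImuBx_r1,ImuBx_r2,ImuBx_r3	remaining ImuB sequences, closer to ImuB1
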