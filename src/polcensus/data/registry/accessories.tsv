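component_id	domains	motifs	anchor_refs	notes
RecA	RecA-core	.	RecA_acc1,RecA_acc2	RecA recombinase; partner of RecA-NT-bearing PolYs
ImuA	ImuA-core	.	ImuA_acc1,ImuA_acc2	catalytically dead RecA homolog of the ImuA-ImuB-DnaE2 module
UmuD	UmuD	.	UmuD_acc1,UmuD_acc2	Pol V small subunit (UmuD-prime dimer in the complex)
YqjX	YqjX-NT,YqjX-C	.	YqjX_acc1,YqjX_acc2	canonical YqjX/YolD small subunit
YqjX-NTonly	YqjX-NT	.	YqjX-NTonly_acc1,YqjX-NTonly_acc2	small-subunit variant reduced to the N-terminal arm
YhjD	YqjX-NT,CTD	.	YhjD_acc1,YhjD_acc2	small-subunit variant: N-terminal arm fused to an unrelated domain
SRAP	SRAP	.	SRAP_acc1,SRAP_acc2	SOS-response-associated peptidase partner of UmuC-like PolYs
ImuB-C-solo	ImuB-C	.	ImuB-C-solo_acc1,ImuB-C-solo_acc2	standalone ImuB-C beta-barrel protein
soloFEN	FEN-exo	FEN_AS:required	soloFEN_acc1,soloFEN_acc2	standalone FEN-like 5'-3' exonuclease complementing missing Pol I
DnaQ-ecoli-like	DnaQ-exo	DEDDh:required	DnaQ-ecoli-like_acc1,DnaQ-ecoli-like_acc2	validated standalone proofreader; Pol III epsilon-subunit type
DnaQ-myco-like	DnaQ-exo	DEDDh:required	DnaQ-myco-like_acc1,DnaQ-myco-like_acc2	validated standalone proofreader; noncanonical mycobacterial type
DnaQ-treponema-like	DnaQ-exo	DEDDh:required	DnaQ-treponema-like_acc1,DnaQ-treponema-like_acc2	putative standalone proofreader; Treponema type
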