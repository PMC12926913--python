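complex_id	priority	known	components	variant_from	notes
ImuA-ImuB-DnaE2	1	yes	dnaE2(groups=DnaE2A) + polY(groups=ImuB1|ImuB2|ImuBx;recA_NT=yes;active=no) + accessory(ImuA)	.	previously characterized mycobacterial mutasome
UmuC-UmuD2-RecA	2	yes	polY(groups=UmuC;recA_NT=yes;active=yes) + accessory(UmuD) + accessory(RecA)	.	previously characterized Pol V; UmuD-prime enters the complex as a dimer
YqjW-YqjX-RecA	3	no	polY(groups=YqjW;recA_NT=yes;active=yes) + small(YqjX|YqjX-NTonly|YhjD) + accessory(RecA)	small	three small-subunit variants share only the N-terminal arm
DnaE2X-iPolY-ImuBC-RecA	4	no	dnaE2(groups=DnaE2X) + polY(recA_NT=yes;active=no) + accessory(ImuB-C-solo) + accessory(RecA)	.	split-ImuB architecture; putative precursor of the ImuA-ImuB-DnaE2 module
DnaE2B-PolY-ImuBC-RecA	5	no	dnaE2(groups=DnaE2B) + polY(recA_NT=yes;active=yes) + accessory(ImuB-C-solo) + accessory(RecA)	.	active PolY plus a standalone ImuB-C protein
DnaE2B-iPolY-RecA	6	no	dnaE2(groups=DnaE2B) + polY(groups=scDinB2-like|gbDinB2-like;recA_NT=yes;active=no) + accessory(RecA)	polY	two iPolY flavors (scDinB2-like, gbDinB2-like) encoded as variants of one type
DnaE2B-PolY-RecA	7	no	dnaE2(groups=DnaE2B) + polY(recA_NT=yes;active=yes) + accessory(RecA)	.	Bacteroidetes-type association with an active PolY
DnaE2B-ImuBC	8	no	dnaE2(groups=DnaE2B) + accessory(ImuB-C-solo)	.	DnaE2B linked only to a standalone ImuB-C protein
UmuC-SRAP	9	no	polY(groups=UmuC;active=yes) + accessory(SRAP)	.	UmuC-like polymerase with an SRAP-superfamily partner
PolY-ImuBC	10	no	polY(recA_NT=yes;active=yes) + accessory(ImuB-C-solo)	.	DnaE2-independent PolY association with standalone ImuB-C
PolY-RecA	11	no	polY(recA_NT=yes) + accessory(RecA)	.	presumed ancestral dimer; most abundant type; fallback for unpartnered RecA-NT PolYs
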