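family_id	fold_class	group_ids
A	Klenow-fold	PolA1,PolA1-like,PolA2,PolA3
B	Klenow-fold	G1,G2,G3,G4,G5,G6,G7,G8
C	Polbeta-like	PolC,DnaE1,DnaE2A,DnaE2B,DnaE2X,DnaE3
X	Polbeta-like	PolX1,PolX2,PolX-like
Y	Klenow-fold	PolY-core,UmuC,YqjW,DinP,DinX,scDinB2-like,gbDinB2-like,ImuB1,ImuB2,ImuBx
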