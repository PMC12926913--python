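motif_id	mode	alignment_id	columns	pattern	threshold	description
PHP_AS	exact	PHP	10,12,38,40,62,64,66,88,90	H-H-D-H-E-H-CH-D-H	.	PHP 3'-5' exonuclease active site (HHDHEH[C/H]DH)
DEDDh	exact	DnaQ-exo	12,14,55,80,95	D-E-D-D-H	.	DnaQ-type proofreading active site, h variant
DEDDy	exact	DnaQ-exo	12,14,55,80,95	D-E-D-D-Y	.	DnaQ-type proofreading active site, y variant
FEN_AS	exact	FEN-exo	15,30,60,85,100	D-DE-E-D-D	.	5'-3' exonuclease active site (D[D/E]EDD)
POL_AS_A	exact	core_A	60,120,122	D-D-E	.	A-family palm catalytic carboxylates
POL_AS_B	exact	core_B	55,115,117	D-D-E	.	B-family palm catalytic carboxylates
POL_AS_C	exact	core_C	90,92,150	D-D-D	.	C-family (Polbeta-fold) catalytic aspartate triad
POL_AS_X	exact	core_X	50,52,100	D-D-D	.	X-family (Polbeta-fold) catalytic aspartate triad
POL_AS_Y	exact	core_Y	10,105,107	D-D-E	.	Y-family palm catalytic carboxylates
CLAMP	exact	.	.	Q-x-x-L-F	.	beta-clamp binding motif, searched within a group-specified region
RecA_NT	profile	RecA_NT	.	.	0.5	RecA N-terminal oligomerization motif, profile scored
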