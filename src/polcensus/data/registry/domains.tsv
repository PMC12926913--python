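domain_id	reference_alignment	length	min_hit_length	description
core_A	core_A	240	60	A-family (Klenow-fold) polymerase core
core_B	core_B	230	60	B-family (Klenow-fold) polymerase core
core_C	core_C	250	60	C-family (Polbeta-fold) polymerase core
core_X	core_X	160	50	X-family (Polbeta-fold) polymerase core
core_Y	core_Y	200	60	Y-family (Klenow-fold) polymerase core
PHP	PHP	120	40	polymerase and histidinol phosphatase domain; intrinsic 3'-5' exonuclease
DnaQ-exo	DnaQ-exo	110	35	DnaQ-like 3'-5' proofreading exonuclease domain
FEN-exo	FEN-exo	130	40	FEN-like 5'-3' exonuclease domain of Pol I
8kDa	8kDa	70	25	N-terminal lyase domain of PolX
OB	OB	70	25	oligonucleotide-binding domain
CTD	CTD	60	20	C-terminal domain
Tudor	Tudor	60	20	C-terminal Tudor domain of DinX
ImuB-C	ImuB-C	80	30	C-terminal beta-barrel of ImuB mediating DnaE2 binding
LF	LF	70	25	little-finger domain of Y-family polymerases
RecA-core	RecA-core	150	50	RecA recombinase core
ImuA-core	ImuA-core	150	50	ImuA (RecA homolog) core
UmuD	UmuD	90	30	UmuD/UmuD-prime small subunit
YqjX-NT	YqjX-NT	40	15	N-terminal arm shared by YqjX-like small subunits
YqjX-C	YqjX-C	60	20	C-terminal SH3-like barrel of YqjX
SRAP	SRAP	110	35	SOS-response-associated peptidase domain
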