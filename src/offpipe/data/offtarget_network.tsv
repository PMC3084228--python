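source	target	sign	source_kind	target_kind
EGFR	PI3K	activation	off_target	intermediate
IGF1R	PI3K	activation	off_target	intermediate
FGFR	PI3K	activation	off_target	intermediate
EPHB4	PI3K	activation	off_target	intermediate
FAK	PI3K	activation	off_target	intermediate
EGFR	RAS	activation	off_target	intermediate
IGF1R	RAS	activation	off_target	intermediate
ABL	RAS	activation	off_target	intermediate
PI3K	PIP3	activation	intermediate	intermediate
PIP3	PI3K_Akt	activation	intermediate	pathway
PDK1	PI3K_Akt	activation	off_target	pathway
AKT2	PI3K_Akt	activation	off_target	pathway
RAS	MAPK	activation	intermediate	pathway
RAS	JNK	activation	intermediate	pathway
ARK	mTOR	activation	off_target	pathway
PDK1	mTOR	activation	off_target	pathway
PI3K_Akt	NFkB	activation	pathway	pathway
PI3K_Akt	mTOR	activation	pathway	pathway
PI3K_Akt	Glucose_uptake	activation	pathway	pathway
PI3K_Akt	Glycogenolysis	dual	pathway	pathway
AKT2	Glucose_uptake	activation	off_target	pathway
FAK	Focal_adhesion	activation	off_target	pathway
IGF1R	Insulin_signaling	activation	off_target	pathway
PI3K_Akt	cell_survival	activation	pathway	effect
PI3K_Akt	apoptosis	inhibition	pathway	effect
MAPK	cell_proliferation	activation	pathway	effect
JNK	cell_proliferation	activation	pathway	effect
mTOR	cell_proliferation	activation	pathway	effect
NFkB	cell_survival	activation	pathway	effect
CDK2	cell_proliferation	dual	off_target	effect
Insulin_signaling	insulin_resistance	inhibition	pathway	effect
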