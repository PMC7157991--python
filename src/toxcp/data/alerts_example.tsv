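# Curated example structural-alert library (synthetic stand-in for full
# literature alert collections; schema: alert_id, smarts, effect, source).
alert_id	smarts	effect	source
epoxide	[OX2r3]1[#6r3][#6r3]1	DNA alkylation / mutagenicity	textbook toxicophore
aziridine	[NX3r3]1[#6r3][#6r3]1	DNA alkylation / mutagenicity	textbook toxicophore
nitroaromatic	[c][N+](=O)[O-]	mutagenicity via nitroreduction	textbook toxicophore
aromatic_amine	[NX3;H2,H1;!$(NC=O)][c]	mutagenicity after metabolic activation	textbook toxicophore
halogenated_benzene	c1ccccc1[F,Cl,Br,I]	bioaccumulation / hepatotoxicity	textbook toxicophore
thioether	[#6][SX2][#6]	oxidative metabolite liability	textbook toxicophore
michael_acceptor	[CX3]=[CX3][CX3]=[OX1]	protein reactivity (Michael addition)	textbook toxicophore
alkyl_halide	[CX4][Cl,Br,I]	alkylating agent	textbook toxicophore
hydrazine	[NX3][NX3]	carcinogenicity	textbook toxicophore
azo	[#6]N=N[#6]	azo-reduction to aromatic amines	textbook toxicophore
aldehyde	[CX3H1]=[OX1]	protein cross-linking	textbook toxicophore
nitrosamine	[NX3][NX2]=[OX1]	potent carcinogenicity	textbook toxicophore
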