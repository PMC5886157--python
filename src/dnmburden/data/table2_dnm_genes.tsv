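gene	constraint_z	functional_candidate	sle_association	other_aid_association	immune_expression
PRKCD	3.75	B cell signaling and self-antigen induced B cell tolerance induction	Monogenic forms	IBD, UC, CD	Dendritic
DNMT3A	4.31	DNA methyltransferase	Candidate gene study	CD
C1QTNF4	3.17	Pro-inflammatory cytokine			CD34+
SRRM2		Spliceosome-associated pre-mRNA splicing			CD8+
LRP1	10.60	Endo/Phagocytosis of apoptotic cells
HMSD	0.25	Minor histocompatibility antigen			n/a
UBN2	0.01	DNA binding
ANXA3	-0.37			RA
PLD1	-0.73				Lymphoblasts
PNPLA1	0.27
GFPT2	1.59
BICD1	2.12
GJB3	-0.81
MICALL1	0.50
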