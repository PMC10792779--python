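# SYNTHETIC demonstration list of 61 clinically relevant SVs
# (4 prognostic, 20 diagnostic, 37 predictive); gene pairs are
# field-typical but the list itself is an invented stand-in.
gene_a	gene_b	svtype	category
KRAS	KRAS	DEL	prognostic
ERBB2	ERBB2	DEL	prognostic
EML4	EML4	DEL	prognostic
CD74	CD74	DEL	prognostic
ETV6	ETV6	DEL	diagnostic
FGFR1	FGFR1	DUP	diagnostic
FGFR2	KRAS	BND	diagnostic
FGFR3	ETV6	BND	diagnostic
BRAF	KIF5B	BND	diagnostic
BRAF	CCDC6	BND	diagnostic
FGFR1	TPM3	BND	diagnostic
FGFR2	CCDC6	BND	diagnostic
FGFR3	TPM3	BND	diagnostic
NTRK3	NTRK3	DEL	diagnostic
ALK	ALK	DEL	diagnostic
ROS1	ROS1	DEL	diagnostic
RET	RET	DEL	diagnostic
ALK	ALK	INV	diagnostic
ROS1	ROS1	INV	diagnostic
RET	RET	INV	diagnostic
NTRK1	NTRK1	INV	diagnostic
MET	MET	INV	diagnostic
EGFR	EGFR	INV	diagnostic
BRAF	BRAF	INV	diagnostic
EML4	ALK	BND	predictive
KIF5B	ALK	BND	predictive
STRN	ALK	BND	predictive
TPM3	ALK	BND	predictive
CD74	ROS1	BND	predictive
EZR	ROS1	BND	predictive
SLC34A2	ROS1	BND	predictive
SDC4	ROS1	BND	predictive
TPM3	ROS1	BND	predictive
KIF5B	RET	BND	predictive
CCDC6	RET	BND	predictive
NCOA4	RET	BND	predictive
ETV6	NTRK3	BND	predictive
LMNA	NTRK1	BND	predictive
TPM3	NTRK1	BND	predictive
ETV6	NTRK2	BND	predictive
VCL	NTRK2	BND	predictive
MET	MET	DEL	predictive
EGFR	EGFR	DEL	predictive
ERBB2	ERBB2	DUP	predictive
KRAS	KRAS	DUP	predictive
MET	MET	DUP	predictive
EGFR	EGFR	DUP	predictive
KIF5B	MET	BND	predictive
CCDC6	NTRK3	BND	predictive
EML4	RET	BND	predictive
STRN	NTRK3	BND	predictive
SDC4	NTRK1	BND	predictive
SLC34A2	RET	BND	predictive
EZR	NTRK2	BND	predictive
CD74	NTRK1	BND	predictive
VCL	ALK	BND	predictive
LMNA	ROS1	BND	predictive
NCOA4	NTRK3	BND	predictive
BRAF	BRAF	DEL	predictive
FGFR3	FGFR3	DUP	predictive
FGFR2	FGFR2	DEL	predictive
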