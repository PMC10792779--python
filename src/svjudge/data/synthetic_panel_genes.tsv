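# SYNTHETIC demonstration panel: 27 genes with invented coordinates.
gene	chrom	start	end	tier
ALK	chr1	1000000	1200000	C
ROS1	chr2	1000000	1200000	C
RET	chr3	1000000	1200000	C
NTRK1	chr4	1000000	1200000	C
NTRK2	chr5	1000000	1200000	C
NTRK3	chr6	1000000	1200000	C
EGFR	chr7	1000000	1200000	C
MET	chr8	1000000	1200000	C
BRAF	chr9	1000000	1200000	C
ERBB2	chr10	1000000	1200000	C
KRAS	chr11	1000000	1200000	C
FGFR1	chr12	1000000	1200000	C
FGFR2	chr13	1000000	1200000	C
FGFR3	chr14	1000000	1200000	C
CD74	chr15	1000000	1200000	C
EML4	chr16	1000000	1200000	C
KIF5B	chr17	1000000	1200000	C
CCDC6	chr18	1000000	1200000	C
NCOA4	chr19	1000000	1200000	C
SLC34A2	chr20	1000000	1200000	C
EZR	chr21	1000000	1200000	C
ETV6	chr22	1000000	1200000	C
TPM3	chr1	5000000	5200000	C
LMNA	chr2	5000000	5200000	C
STRN	chr3	5000000	5200000	C
SDC4	chr4	5000000	5200000	C
VCL	chr5	5000000	5200000	C
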