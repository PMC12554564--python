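#gene	diplotype	count
#Diplotype distribution observed in the 188-sample validation cohort; used
#as the default sampling frequencies of the synthetic cohort generator and
#as the published input for phenotype roll-up checks.
CYP2C19	*1/*1	73
CYP2C19	*1/*17	50
CYP2C19	*1/*2	35
CYP2C19	*2/*17	13
CYP2C19	*17/*17	8
CYP2C19	*2/*2	5
CYP2C19	*1/*3	1
CYP2C19	*2/*4B	1
CYP2C19	*4A/*17	1
CYP2C19	*8/*17	1
CYP2C9	*1/*1	127
CYP2C9	*1/*2	36
CYP2C9	*1/*3	20
CYP2C9	*2/*3	3
CYP2C9	*2/*2	2
CYP4F2	*1/*1	88
CYP4F2	*1/*3	85
CYP4F2	*3/*3	15
VKORC1	GA	109
VKORC1	GG	61
VKORC1	AA	18
rs12777823	GG	132
rs12777823	GA	53
rs12777823	AA	3
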