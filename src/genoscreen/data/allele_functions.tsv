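#gene	allele	function
#Allele functional assignments per PharmGKB/CPIC/PharmVar annotations.
#VKORC1 c.-1639 and rs12777823 use the warfarin-sensitivity category of
#their A allele rather than a metabolizer function.
CYP2C19	*1	normal
CYP2C19	*2	no_function
CYP2C19	*3	no_function
CYP2C19	*4A	no_function
CYP2C19	*4B	no_function
CYP2C19	*5	no_function
CYP2C19	*6	no_function
CYP2C19	*7	no_function
CYP2C19	*8	no_function
CYP2C19	*9	decreased
CYP2C19	*10	decreased
CYP2C19	*17	increased
CYP2C19	*35	no_function
CYP2C9	*1	normal
CYP2C9	*2	decreased
CYP2C9	*3	no_function
CYP2C9	*5	no_function
CYP2C9	*6	no_function
CYP2C9	*8	decreased
CYP2C9	*11	decreased
CYP4F2	*1	normal
CYP4F2	*3	decreased
VKORC1	G	normal
VKORC1	A	sensitive
rs12777823	G	normal
rs12777823	A	sensitive
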