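#gene	allele	tier	rsid	chrom	pos	ref	alt
#pos is 1-based hg19. One row per defining variant; multi-variant alleles
#(e.g. CYP2C19*4B) span multiple rows. Sourced from PharmVar/CPIC reference
#tables for the assayed allele panel; the default *1 allele has no rows.
CYP2C19	*2	1	rs4244285	chr10	96541616	G	A
CYP2C19	*3	1	rs4986893	chr10	96540410	G	A
CYP2C19	*17	1	rs12248560	chr10	96521657	C	T
CYP2C19	*4A	2	rs28399504	chr10	96522463	A	G
CYP2C19	*4B	2	rs28399504	chr10	96522463	A	G
CYP2C19	*4B	2	rs12248560	chr10	96521657	C	T
CYP2C19	*5	2	rs56337013	chr10	96602623	C	T
CYP2C19	*6	2	rs72552267	chr10	96535173	G	A
CYP2C19	*7	2	rs72558186	chr10	96535246	T	A
CYP2C19	*8	2	rs41291556	chr10	96535210	T	C
CYP2C19	*9	2	rs17884712	chr10	96535166	G	A
CYP2C19	*10	2	rs6413438	chr10	96541615	C	T
CYP2C19	*35	2	rs12769205	chr10	96535085	A	G
CYP2C9	*2	1	rs1799853	chr10	96702047	C	T
CYP2C9	*3	1	rs1057910	chr10	96741053	A	C
CYP2C9	*5	1	rs28371686	chr10	96741058	C	G
CYP2C9	*6	1	rs9332131	chr10	96709038	TA	T
CYP2C9	*8	1	rs7900194	chr10	96702066	G	A
CYP2C9	*11	1	rs28371685	chr10	96740981	C	T
CYP4F2	*3	1	rs2108622	chr19	15990431	C	T
VKORC1	A	1	rs9923231	chr16	31107689	C	T
rs12777823	A	1	rs12777823	chr10	96405502	G	A
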