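gene_id	pathway	sign	reference
GAPDH	AKT	+1	literature
GLUT1	AKT	+1	literature
GYS1	AKT	+1	literature
HK1	AKT	+1	literature
HK2	AKT	+1	literature
G6PC	AKT	-1	literature
PCK1	AKT	-1	literature
ACLY	AKT	+1	literature
ME1	AKT	+1	literature
PFKFB2	AKT	+1	literature
HMGCR	AKT	+1	literature
HMGCS1	AKT	+1	literature
ACC	AKT	+1	literature
SREBF1	AKT	+1	literature
SREBF2	AKT	+1	literature
FASN	AKT	+1	literature
ATIC	AKT	+1	literature
HPRT1	AKT	+1	literature
TALDO1	AKT	+1	literature
TKT	AKT	+1	literature
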