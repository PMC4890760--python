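no	gene_id	gene_name	category	proposed	observed
1	GAPDH	Glyceraldehyde-3-phosphate dehydrogenase	carbohydrate	down_in_M	down_in_M
2	GLUT1	Facilitated glucose transporter	carbohydrate	down_in_M	down_in_E
3	GYS1	Glycogen [starch] synthase, muscle	carbohydrate	down_in_M	down_in_M
4	HK1	Hexokinase-1	carbohydrate	down_in_M	down_in_M
5	HK2	Hexokinase-2	carbohydrate	down_in_M	down_in_M
6	G6PC	Glucose-6-phosphatase	carbohydrate	down_in_E	NA
7	PCK1	Phosphoenolpyruvate carboxykinase 1	carbohydrate	down_in_E	NA
8	ACLY	ATP-citrate synthase	fatty-acid	down_in_M	down_in_M
9	ME1	Malic enzyme	fatty-acid	down_in_M	down_in_M
10	PFKFB2	6-phosphofructo-2-kinase/fructose-2,6-bisphosphatase 2	fatty-acid	down_in_M	NA
11	HMGCR	3-hydroxy-3-methylglutaryl coenzyme A reductase	fatty-acid	down_in_M	down_in_M
12	HMGCS1	Hydroxymethylglutaryl-CoA synthase, cytoplasmic	fatty-acid	down_in_M	down_in_M
13	ACC	Acetyl-CoA carboxylase alpha	fatty-acid	down_in_M	NA
14	SREBF1	Sterol regulatory element-binding protein 1	fatty-acid	down_in_M	down_in_E
15	SREBF2	Sterol regulatory element-binding protein 2	fatty-acid	down_in_M	NA
16	FASN	Fatty acid synthase	fatty-acid	down_in_M	down_in_M
17	ATIC	Bifunctional purine biosynthesis protein PURH	purine-pyrimidine	down_in_M	down_in_M
18	HPRT1	Hypoxanthine-guanine phosphoribosyltransferase	purine-pyrimidine	down_in_M	down_in_M
19	TALDO1	Transaldolase	purine-pyrimidine	down_in_M	down_in_M
20	TKT	Transketolase	purine-pyrimidine	down_in_M	down_in_M
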