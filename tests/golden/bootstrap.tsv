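from	to	strength	direction
APOE	CD33	0.03333333333	1
CD33	APOE	0.03333333333	0
APOE	M1	0.03333333333	1
M1	APOE	0.03333333333	0
APOE	M2	0.03333333333	1
M2	APOE	0.03333333333	0
APOE	M3	0.03333333333	1
M3	APOE	0.03333333333	0
CD33	M1	1	1
M1	CD33	1	0
CD33	M2	0.1666666667	1
M2	CD33	0.1666666667	0
CD33	M3	1	1
M3	CD33	1	0
CD33	M4	0.03333333333	1
M4	CD33	0.03333333333	0
CD33	age	0.9666666667	0
age	CD33	0.9666666667	1
CD33	education	0.1333333333	0
education	CD33	0.1333333333	1
CD33	phenotype	0.06666666667	1
phenotype	CD33	0.06666666667	0
CD33	sex	0.03333333333	0
sex	CD33	0.03333333333	1
M1	M2	1	1
M2	M1	1	0
M1	M3	0.5	0.8666666667
M3	M1	0.5	0.1333333333
M1	age	0.03333333333	0
age	M1	0.03333333333	1
M1	education	0.03333333333	0
education	M1	0.03333333333	1
M1	phenotype	0.06666666667	1
phenotype	M1	0.06666666667	0
M2	M3	0.5666666667	0.8235294118
M3	M2	0.5666666667	0.1764705882
M2	M4	0.03333333333	1
M4	M2	0.03333333333	0
M2	phenotype	1	1
phenotype	M2	1	0
M3	M4	1	1
M4	M3	1	0
M3	education	0.03333333333	0
education	M3	0.03333333333	1
M3	phenotype	0.8	1
phenotype	M3	0.8	0
M4	age	0.2333333333	0
age	M4	0.2333333333	1
M4	education	1	0
education	M4	1	1
M4	phenotype	0.2333333333	1
phenotype	M4	0.2333333333	0
age	phenotype	0.03333333333	1
phenotype	age	0.03333333333	0
education	phenotype	0.8666666667	1
phenotype	education	0.8666666667	0
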