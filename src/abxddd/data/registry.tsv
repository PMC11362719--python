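molecule	atc5	route	ddd_value	ddd_unit	aware	is_fdc	components	ddd_source
amikacin	J01GB06	injectable	1	g	Access	0		who
amoxicillin+clavulanic acid	J01CR02	injectable	3	g	Access	1	amoxicillin;clavulanic acid	who
ampicillin	J01CA01	injectable	6	g	Access	0		who
ampicillin+sulbactam	J01CR01	injectable	6	g	Access	1	ampicillin;sulbactam	who
azithromycin	J01FA10	injectable	0.5	g	Watch	0		who
aztreonam	J01DF01	injectable	4	g	Reserve	0		who
benzylpenicillin	J01CE01	injectable	6	MU	Access	0		who
cefepime	J01DE01	injectable	4	g	Watch	0		who
cefoperazone+sulbactam	J01DD62	injectable	4	g	Watch	1	cefoperazone;sulbactam	who
cefotaxime	J01DD01	injectable	4	g	Watch	0		who
ceftazidime	J01DD02	injectable	4	g	Watch	0		who
ceftriaxone	J01DD04	injectable	2	g	Watch	0		who
ceftriaxone+sulbactam	J01DD54	injectable	2	g	Discouraged	1	ceftriaxone;sulbactam	principal_component
ceftriaxone+tazobactam	J01DD54	injectable	2	g	Discouraged	1	ceftriaxone;tazobactam	principal_component
cefuroxime	J01DC02	injectable	3	g	Watch	0		who
ciprofloxacin	J01MA02	injectable	0.8	g	Watch	0		who
clindamycin	J01FF01	injectable	1.8	g	Access	0		who
cloxacillin	J01CF02	injectable	2	g	Access	0		who
colistin	J01XB01	injectable	9	MU	Reserve	0		who
gentamicin	J01GB03	injectable	240	mg	Access	0		who
imipenem+cilastatin	J01DH51	injectable	2	g	Watch	1	imipenem;cilastatin	who
levofloxacin	J01MA12	injectable	0.5	g	Watch	0		who
linezolid	J01XX08	injectable	1.2	g	Reserve	0		who
meropenem	J01DH02	injectable	3	g	Watch	0		who
ofloxacin	J01MA01	injectable	0.4	g	Watch	0		who
piperacillin+tazobactam	J01CR05	injectable	14	g	Watch	1	piperacillin;tazobactam	who
polymyxin b	J01XB02	injectable	150	mg	Reserve	0		who
streptomycin	J01GA01	injectable	1	g	Access	0		who
teicoplanin	J01XA02	injectable	0.4	g	Watch	0		who
tigecycline	J01AA12	injectable	0.1	g	Reserve	0		who
vancomycin	J01XA01	injectable	2	g	Watch	0		who
amoxicillin	J01CA04	oral	1.5	g	Access	0		who
amoxicillin+clavulanic acid	J01CR02	oral	1.5	g	Access	1	amoxicillin;clavulanic acid	who
azithromycin	J01FA10	oral	0.3	g	Watch	0		who
cefixime	J01DD08	oral	0.4	g	Watch	0		who
cefixime+ofloxacin	J01RA95	oral	0.4	g	Discouraged	1	cefixime;ofloxacin	principal_component
cefuroxime	J01DC02	oral	0.5	g	Watch	0		who
cephalexin	J01DB01	oral	2	g	Access	0		who
ciprofloxacin	J01MA02	oral	1	g	Watch	0		who
clarithromycin	J01FA09	oral	0.5	g	Watch	0		who
cloxacillin	J01CF02	oral	2	g	Access	0		who
doxycycline	J01AA02	oral	0.1	g	Access	0		who
levofloxacin	J01MA12	oral	0.5	g	Watch	0		who
linezolid	J01XX08	oral	1.2	g	Reserve	0		who
norfloxacin	J01MA06	oral	0.8	g	Watch	0		who
ofloxacin	J01MA01	oral	0.4	g	Watch	0		who
ofloxacin+ornidazole	J01RA96	oral	0.4	g	Discouraged	1	ofloxacin;ornidazole	principal_component
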