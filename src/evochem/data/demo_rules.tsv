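rule_id	category	smarts	description
G01	grow	[cH:1]>>[c:1]C	methylation of an aromatic CH
G02	grow	[cH:1]>>[c:1]F	fluorination of an aromatic CH
G03	grow	[cH:1]>>[c:1]O	hydroxylation of an aromatic CH
G04	grow	[cH:1]>>[c:1]N	amination of an aromatic CH
G05	grow	[cH:1]>>[c:1]OC	methoxylation of an aromatic CH
G06	grow	[cH:1]>>[c:1]C#N	cyanation of an aromatic CH
G07	grow	[cH:1]>>[c:1]-c1ccccc1	phenyl growth at an aromatic CH
G08	grow	[cH:1]>>[c:1]-c1ccncc1	4-pyridyl growth at an aromatic CH
G09	grow	[cH:1]>>[c:1]C(N)=O	carboxamide growth at an aromatic CH
G10	grow	[cH:1]>>[c:1]N1CCOCC1	morpholine growth at an aromatic CH
G11	grow	[C^3;!H0:1]>>[C:1]C	methylation of an sp3 CH
G12	grow	[cH:1]>>[c:1]C(=O)O	carboxylic acid growth at an aromatic CH
M01	mutate	[cH:1]>>[n:1]	aromatic CH to aromatic N
M02	mutate	[C^3;H2;D2;!$(C=*):1]>>[O:1]	methylene to ether oxygen
M03	mutate	[C^3;H2;D2;!$(C=*):1]>>[N:1]	methylene to secondary amine
M04	mutate	[n;H0;D2:1]>>[cH:1]	aromatic N back to CH
M05	mutate	[c:1][CH3]>>[c:1]	aryl methyl deletion
M06	mutate	[c:1][CH3]>>[c:1]CC	aryl methyl homologation
M07	mutate	[C^3;H2:1][C^3;H2:2]>>[C:1]=[C:2]	CH2-CH2 dehydrogenation to alkene
M08	mutate	[c:1]F>>[c:1]Cl	aryl fluorine to chlorine
M09	mutate	[cH:1]:[cH:2]>>[c:1]1:[c:2]:c:c:c:c:1	benzo ring fusion at an aromatic CH-CH edge
M10	mutate	[C:1](=[O:2])[OH]>>[C:1](=[O:2])N	carboxylic acid to primary amide
B01	bioisostere	[*:1][CX3](=O)[OX2H1]>>[*:1]c1nnn[nH]1	carboxylic acid to tetrazole
B02	bioisostere	[CX3:1](=[O:2])[OX2][CH3]>>[C:1](=[O:2])[NH1][CH3]	methyl ester to N-methyl amide
B03	bioisostere	[c:1]-c1ccccc1>>[c:1]-c1ccncc1	pendant phenyl to 4-pyridyl
B04	bioisostere	[c:1][OX2H]>>[c:1]N	phenol OH to aniline NH2
B05	bioisostere	[*:1]C(C)(C)C>>[*:1]C(F)(F)F	tert-butyl to trifluoromethyl
B06	bioisostere	[c:1]C#N>>[c:1]c1nnn[nH]1	aryl nitrile to tetrazole
B07	bioisostere	[c:1]Cl>>[c:1]C#N	aryl chloride to nitrile
B08	bioisostere	[c:1][OX2][CH3]>>[c:1][NH][CH3]	aryl methyl ether to N-methyl aniline
R01	reaction	[CX3:1](=[O:2])[OX2H1].[NX3;H2;!$(N=*);!$(NC=O):3]>>[C:1](=[O:2])[NH1:3]	amide coupling of a seed acid with amine blocks
R02	reaction	[NX3;H2;!$(N=*);!$(NC=O):1].[CX3H1:2]=[OX1]>>[NH1:1][CH2:2]	reductive amination of a seed amine with aldehyde blocks
R03	reaction	[c:1][Br].[c:2]B(O)O>>[c:1]-[c:2]	Suzuki coupling of a seed aryl bromide with boronic acid blocks
R04	reaction	[c:1][OX2H].[CX4;!$(C(Br)Br):2][Br]>>[c:1]O[C:2]	Williamson etherification of a seed phenol with alkyl bromide blocks
R05	reaction	[NX3;H2;!$(N=*);!$(NC=O):1].[NX2:2]=C=O>>[NH1:1]C(=O)[NH1:2]	urea formation from a seed amine and isocyanate blocks
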